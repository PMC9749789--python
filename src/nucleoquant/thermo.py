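"""Partition thermodynamics of condensates.

A fluorescently tagged protein partitions between the condensed (dense)
phase and the surrounding dilute phase.  Fluorescence intensity is a
proxy for concentration, so the partition coefficient is

    K = I_dense / I_dilute,

and the free energy of transferring one mole of the protein from the
dilute into the dense phase is

    dG_tr = -R T ln K        (kJ/mol; or -kT ln K per molecule).

K > 1 (favourable partitioning) gives negative dG_tr.  Drug effects are
summarized as ddG_tr, the difference of median per-nucleolus dG_tr
between a treated condition and an untreated reference: a drug that
weakens partitioning (K falls) gives positive ddG_tr, one that
strengthens it gives negative ddG_tr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from nucleoquant.constants import R_GAS, T_CELL
from nucleoquant.segmentation import NucleolusRecord, NucleusRecord


@dataclass
class PartitionEstimate:
    """K and dG_tr for one nucleolus under one condition."""

    K: float
    dG_tr: float  # kJ/mol (or kBT if per_molecule)
    temperature: float
    condition: str = ""
    marker: str = ""


@dataclass
class DeltaDeltaG:
    """Median transfer-energy shift of a condition vs its reference."""

    ddG: float  # kJ/mol (or kBT)
    condition: str
    reference_condition: str
    marker: str
    n_nucleoli: int


@dataclass
class PhaseDiagramPoint:
    """Dense/dilute intensity summary at one dose (phase-diagram axis)."""

    dose: float  # uM
    dilute_median: float
    dilute_dispersion: float
    dense_median: float
    dense_dispersion: float
    marker: str = ""
    n: int = 0


def partition_coefficient(I_dense, I_dilute):
    """Partition coefficient K = I_dense / I_dilute.

    Accepts scalars or arrays; raises if any dilute-phase intensity is
    non-positive (the dilute phase is then unmeasurable and K undefined).
    """
    I_dense = np.asarray(I_dense, dtype=float)
    I_dilute = np.asarray(I_dilute, dtype=float)
    if np.any(I_dilute <= 0):
        raise ValueError("dilute phase unmeasurable: I_dilute must be > 0")
    if np.any(I_dense < 0):
        raise ValueError("I_dense must be >= 0")
    out = I_dense / I_dilute
    return float(out) if out.ndim == 0 else out


def transfer_energy(K, temperature: float = T_CELL, per_molecule: bool = False):
    """Free energy of transfer dG_tr = -R T ln K.

    Returns kJ/mol by default; with ``per_molecule=True`` the energy is in
    units of kBT (i.e. ``-ln K``).  K = 1 gives exactly 0.
    """
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("K must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if per_molecule:
        out = -np.log(K)
    else:
        out = -R_GAS * temperature * np.log(K) / 1000.0
    return float(out) if out.ndim == 0 else out


def estimates_from_records(
    nucleolus_records: list[NucleolusRecord],
    nucleus_records: list[NucleusRecord],
    temperature: float = T_CELL,
    condition: str = "",
    marker: str = "",
    per_molecule: bool = False,
) -> list[PartitionEstimate]:
    """Per-nucleolus partition estimates from segmentation measurements.

    Each nucleolus's dense intensity is divided by the dilute intensity of
    its parent nucleus.  Nucleoli whose parent has no measurable
    nucleoplasm are skipped with a warning.
    """
    dilute = {r.nucleus_id: r.I_dilute for r in nucleus_records}
    out = []
    for rec in nucleolus_records:
        i_dil = dilute.get(rec.nucleus_id, float("nan"))
        if not np.isfinite(i_dil) or i_dil <= 0:
            warnings.warn(
                f"nucleolus {rec.nucleolus_id}: parent nucleus {rec.nucleus_id} "
                "has no measurable dilute phase; skipped",
                stacklevel=2,
            )
            continue
        K = partition_coefficient(rec.I_dense, i_dil)
        out.append(
            PartitionEstimate(
                K=K,
                dG_tr=transfer_energy(K, temperature, per_molecule),
                temperature=temperature,
                condition=condition,
                marker=marker,
            )
        )
    return out


def delta_delta_g(
    treated: list[PartitionEstimate], reference: list[PartitionEstimate]
) -> DeltaDeltaG:
    """ddG_tr = median(dG_tr, treated) - median(dG_tr, reference).

    Both collections must be non-empty and carry the same marker.  The
    per-nucleolus transfer energies are aggregated by median, consistent
    with median-based reporting of the underlying distributions.
    """
    if not treated or not reference:
        raise ValueError("both treated and reference collections must be non-empty")
    markers = {e.marker for e in treated} | {e.marker for e in reference}
    if len(markers) > 1:
        raise ValueError(f"marker mismatch: {sorted(markers)}")
    ddg = float(np.median([e.dG_tr for e in treated]) - np.median([e.dG_tr for e in reference]))
    return DeltaDeltaG(
        ddG=ddg,
        condition=treated[0].condition,
        reference_condition=reference[0].condition,
        marker=treated[0].marker,
        n_nucleoli=len(treated),
    )


def _median_and_dispersion(values: np.ndarray, statistic: str) -> tuple[float, float]:
    med = float(np.median(values))
    dev = np.abs(values - med)
    disp = float(np.median(dev)) if statistic == "mad" else float(np.mean(dev))
    return med, disp


def phase_diagram(
    records_by_dose: dict,
    marker: str = "",
    dispersion: str = "mad",
) -> list[PhaseDiagramPoint]:
    """Summarize dense and dilute intensities per dose.

    ``records_by_dose`` maps dose (uM) to a pair
    ``(nucleolus_records, nucleus_records)``.  Each point carries the
    median and its dispersion for both phases; ``dispersion`` is
    ``"mad"`` (median absolute deviation from the median, default) or
    ``"mean_abs"`` (mean absolute deviation from the median).  Doses with
    no nucleoli are skipped with a warning.
    """
    if dispersion not in ("mad", "mean_abs"):
        raise ValueError(f"unknown dispersion statistic {dispersion!r}")
    points = []
    for dose in sorted(records_by_dose):
        foci, nucs = records_by_dose[dose]
        if not foci:
            warnings.warn(f"dose {dose}: no nucleoli; skipped", stacklevel=2)
            continue
        dense = np.array([r.I_dense for r in foci], dtype=float)
        dilute = np.array(
            [r.I_dilute for r in nucs if np.isfinite(r.I_dilute)], dtype=float
        )
        if dilute.size == 0:
            warnings.warn(f"dose {dose}: no measurable dilute phase; skipped", stacklevel=2)
            continue
        dense_med, dense_disp = _median_and_dispersion(dense, dispersion)
        dil_med, dil_disp = _median_and_dispersion(dilute, dispersion)
        points.append(
            PhaseDiagramPoint(
                dose=float(dose),
                dilute_median=dil_med,
                dilute_dispersion=dil_disp,
                dense_median=dense_med,
                dense_dispersion=dense_disp,
                marker=marker,
                n=len(foci),
            )
        )
    return points


def estimates_to_frame(estimates: list[PartitionEstimate]) -> pd.DataFrame:
    """Tabulate partition estimates for CSV output."""
    return pd.DataFrame(
        [
            {
                "condition": e.condition,
                "marker": e.marker,
                "K": e.K,
                "dG_tr": e.dG_tr,
                "temperature": e.temperature,
            }
            for e in estimates
        ]
    )
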