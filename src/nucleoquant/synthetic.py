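"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be simulated here with the
quantity of interest prescribed exactly, so that each estimator can be
tested for recovery of a known truth:

* two-channel condensate images with a prescribed dense/dilute intensity
  ratio ``K`` (partition-coefficient pipeline),
* thermally fluctuating droplet contours with a prescribed mean-square
  fluctuation ``kB T / gamma`` (flicker spectroscopy),
* Hill-shaped dose-viability data with a prescribed EC50,
* qPCR Ct tables with prescribed fold changes,
* cell-line expression/resistance tables with a prescribed correlation.

All generators are deterministic given a seed: the same seed yields
bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from nucleoquant.constants import K_BOLTZMANN
from nucleoquant.flicker import ContourSeries
from nucleoquant.io import ImageStack

#: Oxaliplatin/cisplatin concentration grid of the viability assay, uM
MTT_CONCENTRATIONS_UM = (0.0, 0.5, 1.0, 2.5, 5.0, 7.5, 10.0, 25.0, 50.0, 75.0, 100.0, 200.0)

#: Ten-point two-fold dilution grid of the rescue assay, topping at 100 uM
RESCUE_CONCENTRATIONS_UM = tuple(100.0 / 2**i for i in range(10))


@dataclass
class SyntheticGroundTruth:
    """The true quantities a simulation was built with.

    Only the fields relevant to a given generator are populated; the rest
    stay ``None``.  ``masks`` holds ground-truth label images for image
    simulations (keys ``"nucleus"``, ``"nucleolus"``, plus a
    ``"parent"`` map from nucleolus label to nucleus label).
    """

    seed: int
    true_K: float | None = None
    true_gamma: float | None = None
    true_u2: float | None = None
    true_ec50: float | None = None
    true_params: dict = field(default_factory=dict)
    true_fold_changes: dict = field(default_factory=dict)
    true_rho: float | None = None
    masks: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# condensate images


def _place_ellipse(rng, shape, a, b, occupied, margin, max_tries=200):
    """Random non-overlapping rotated ellipse; returns (rr, cc, params)."""
    rows, cols = shape
    for _ in range(max_tries):
        r0 = rng.uniform(a + margin, rows - a - margin)
        c0 = rng.uniform(a + margin, cols - a - margin)
        theta = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(r0, c0, a, b, shape=shape, rotation=theta)
        if rr.size == 0:
            continue
        if not occupied[rr, cc].any():
            return rr, cc, (r0, c0, a, b, theta)
    return None


def simulate_condensate_image(
    n_nuclei: int = 4,
    K_true: float = 5.0,
    dilute_level: float = 1000.0,
    noise_sd: float = 0.02,
    shape_eccentricity: float = 0.0,
    seed: int = 0,
    image_shape: tuple = (256, 256),
    pixel_size: float = 0.2,
    nucleus_radius_px: tuple = (26.0, 34.0),
    nucleolus_radius_px: tuple = (6.0, 10.0),
    nucleoli_per_nucleus: tuple = (1, 4),
) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Simulate a two-channel image of nuclei with partitioned nucleoli.

    Channel ``"dna"`` is a uniform nuclear fill (for nucleus segmentation);
    channel ``"marker"`` has nucleoplasmic intensity ``dilute_level`` and
    nucleolar intensity ``K_true * dilute_level`` before noise, so the
    ground-truth partition coefficient of every nucleolus is ``K_true``.
    Noise is additive Gaussian with standard deviation
    ``noise_sd * dilute_level`` (detector-dominated regime), clipped to the
    16-bit range.

    Returns the stack and a :class:`SyntheticGroundTruth` whose ``masks``
    carry nucleus and nucleolus label images plus the parent map.

    Raises
    ------
    RuntimeError
        If the requested number of nuclei cannot be placed without
        overlap.
    ValueError
        On invalid ``K_true``, eccentricity or noise level.
    """
    if K_true <= 0:
        raise ValueError("K_true must be > 0")
    if not 0 <= shape_eccentricity < 1:
        raise ValueError("shape_eccentricity must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    shape = tuple(image_shape)
    axis_ratio = np.sqrt(1.0 - shape_eccentricity**2)  # b/a of nucleoli

    marker = np.zeros(shape, dtype=float)
    dna = np.zeros(shape, dtype=float)
    nuc_labels = np.zeros(shape, dtype=np.int32)
    nucleolus_labels = np.zeros(shape, dtype=np.int32)
    parent: dict[int, int] = {}
    occupied = np.zeros(shape, dtype=bool)

    nucleolus_id = 0
    for nucleus_id in range(1, n_nuclei + 1):
        a = rng.uniform(*nucleus_radius_px)
        b = a * rng.uniform(0.8, 1.0)  # nuclei mildly elliptical
        placed = _place_ellipse(rng, shape, a, b, occupied, margin=4)
        if placed is None:
            raise RuntimeError(
                f"could not place nucleus {nucleus_id} of {n_nuclei} without overlap"
            )
        rr, cc, (r0, c0, _, _, theta) = placed
        occupied[rr, cc] = True
        nuc_labels[rr, cc] = nucleus_id
        dna[rr, cc] = dilute_level
        marker[rr, cc] = dilute_level

        n_foci = int(rng.integers(nucleoli_per_nucleus[0], nucleoli_per_nucleus[1] + 1))
        for _ in range(n_foci):
            na = rng.uniform(*nucleolus_radius_px)
            nb = na * axis_ratio
            for _ in range(100):
                # place inside the nucleus, away from other nucleoli;
                # integer centres keep the rasterization symmetric, so a
                # circular nucleolus has moment eccentricity 0
                cr = round(r0 + rng.uniform(-b + na + 2, b - na - 2))
                cc_ = round(c0 + rng.uniform(-b + na + 2, b - na - 2))
                nth = rng.uniform(0, np.pi)
                nrr, ncc = draw_ellipse(cr, cc_, na, nb, shape=shape, rotation=nth)
                if nrr.size == 0:
                    continue
                inside = nuc_labels[nrr, ncc] == nucleus_id
                # keep a 2-px clearance so neighbouring nucleoli stay
                # separate connected components
                grr, gcc = draw_ellipse(cr, cc_, na + 2, nb + 2, shape=shape, rotation=nth)
                free = nucleolus_labels[grr, gcc] == 0
                if inside.all() and free.all():
                    nucleolus_id += 1
                    nucleolus_labels[nrr, ncc] = nucleolus_id
                    marker[nrr, ncc] = K_true * dilute_level
                    parent[nucleolus_id] = nucleus_id
                    break

    pixels = np.stack([dna, marker])[None]  # (1, 2, R, C)
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd * dilute_level, size=pixels.shape)
    pixels = np.clip(pixels, 0, 2**16 - 1)

    stack = ImageStack(
        pixels=pixels,
        channel_names=["dna", "marker"],
        pixel_size=pixel_size,
        frame_interval=0.0,
        bit_depth=16,
    )
    truth = SyntheticGroundTruth(
        seed=seed,
        true_K=float(K_true),
        masks={"nucleus": nuc_labels, "nucleolus": nucleolus_labels, "parent": parent},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# contour fluctuations


def simulate_contour_series(
    gamma_true: float,
    temperature: float = 310.0,
    R0: float = 2e-6,
    n_frames: int = 100,
    n_angles: int = 256,
    max_mode: int = 20,
    seed: int = 0,
) -> tuple[ContourSeries, SyntheticGroundTruth]:
    """Simulate a thermally fluctuating droplet contour r(theta, t).

    The radius is ``R0`` plus a sum of angular Fourier modes
    ``q = 2 .. max_mode`` whose cosine/sine amplitudes are i.i.d. zero-mean
    Gaussians redrawn each frame (fluctuations white in time).  The target
    mean-square contour fluctuation is set by the flicker relation,

        u2 = kB * temperature / gamma_true,

    and is distributed equally over the modes, so the time- and
    angle-averaged squared deviation from the mean contour equals ``u2``
    in expectation.  Modes 0 and 1 carry no power: the simulated droplet
    neither breathes nor translates, matching what the estimator filters
    out.

    ``gamma_true = inf`` is the rigid limit and produces a flat contour.
    """
    if gamma_true <= 0:
        raise ValueError("gamma_true must be > 0")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if max_mode < 2:
        raise ValueError("max_mode must be >= 2")
    rng = np.random.default_rng(seed)
    u2_target = 0.0 if np.isinf(gamma_true) else K_BOLTZMANN * temperature / gamma_true
    if 0 < u2_target < (1e-6 * R0) ** 2:
        warnings.warn(
            "target mean-square fluctuation is below numerical resolution "
            f"at R0={R0}; contour will be effectively flat",
            stacklevel=2,
        )
    n_modes = max_mode - 1  # q = 2..max_mode
    # per-mode amplitude variance: each mode contributes (a^2+b^2)/2 to the
    # angle-averaged square, with E[a^2] = E[b^2] = sigma^2
    sigma = np.sqrt(u2_target / n_modes) if u2_target > 0 else 0.0
    theta = 2 * np.pi * np.arange(n_angles) / n_angles
    q = np.arange(2, max_mode + 1)
    cosq = np.cos(q[:, None] * theta[None, :])  # (n_modes, n_angles)
    sinq = np.sin(q[:, None] * theta[None, :])
    a = rng.normal(0.0, 1.0, size=(n_frames, n_modes)) * sigma
    b = rng.normal(0.0, 1.0, size=(n_frames, n_modes)) * sigma
    radii = R0 + a @ cosq + b @ sinq  # (n_frames, n_angles)

    series = ContourSeries(
        radii=radii,
        centroids=np.zeros((n_frames, 2)),
        pixel_size=R0 / 50.0,
        frame_interval=0.25,
    )
    truth = SyntheticGroundTruth(
        seed=seed, true_gamma=float(gamma_true), true_u2=float(u2_target)
    )
    return series, truth


# ---------------------------------------------------------------------------
# dose response


def hill_response(c, ec50, i0, imin, n=2.0):
    """Decreasing Hill curve I(c) = Imin + (I0 - Imin)/(1 + (c/EC50)^n)."""
    c = np.asarray(c, dtype=float)
    return imin + (i0 - imin) / (1.0 + (c / ec50) ** n)


def simulate_dose_response(
    EC50_true: float,
    I0: float = 1.0,
    Imin: float = 0.1,
    n: float = 2.0,
    concentrations=MTT_CONCENTRATIONS_UM,
    noise_sd: float = 0.05,
    replicates: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Simulate dose-response readings on a concentration grid.

    The noiseless response follows the decreasing Hill curve; noise is
    multiplicative Gaussian (fractional assay error), applied per
    replicate well.  The default grid and four replicates mirror the
    viability assay design.

    Returns a table with columns ``concentration``, ``replicate``,
    ``response``.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("concentration list is empty")
    if EC50_true <= 0:
        raise ValueError("EC50_true must be > 0")
    if I0 <= Imin:
        raise ValueError("I0 must exceed Imin for an inhibitory curve")
    rng = np.random.default_rng(seed)
    clean = hill_response(conc, EC50_true, I0, Imin, n)
    rows = []
    for rep in range(replicates):
        noisy = clean * (1.0 + rng.normal(0.0, noise_sd, size=conc.shape)) if noise_sd > 0 else clean
        for c, v in zip(conc, noisy):
            rows.append({"concentration": c, "replicate": rep, "response": v})
    table = pd.DataFrame(rows)
    truth = SyntheticGroundTruth(
        seed=seed,
        true_ec50=float(EC50_true),
        true_params={"I0": I0, "Imin": Imin, "n": n},
    )
    return table, truth


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr_table(
    fold_changes: dict,
    ct_ref_base: float = 18.0,
    ct_tgt_base: float = 22.0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    target: str = "45S",
    reference_condition: str = "untreated",
) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Simulate a qPCR Ct table with prescribed fold changes.

    With amplification efficiency 2, an ``f``-fold change of the target
    transcript shifts its Ct by ``-log2(f)`` cycles while the reference
    gene stays put:

        Ct_target(condition) = ct_tgt_base - log2(fold_change) + noise

    The table has one row per (condition, replicate) with columns
    ``condition``, ``target``, ``replicate``, ``ct_target``,
    ``ct_reference``.
    """
    if reference_condition not in fold_changes:
        raise ValueError(f"fold_changes must include the reference condition {reference_condition!r}")
    if abs(fold_changes[reference_condition] - 1.0) > 1e-12:
        raise ValueError("the reference condition must have fold change 1")
    for cond, f in fold_changes.items():
        if f <= 0:
            raise ValueError(f"non-positive fold change {f} for {cond!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, f in fold_changes.items():
        for rep in range(replicates):
            ct_t = ct_tgt_base - np.log2(f)
            ct_r = ct_ref_base
            if noise_sd > 0:
                ct_t += rng.normal(0.0, noise_sd)
                ct_r += rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "condition": cond,
                    "target": target,
                    "replicate": rep,
                    "ct_target": ct_t,
                    "ct_reference": ct_r,
                }
            )
    table = pd.DataFrame(rows)
    truth = SyntheticGroundTruth(seed=seed, true_fold_changes=dict(fold_changes))
    return table, truth


# ---------------------------------------------------------------------------
# expression vs resistance


def simulate_expression_resistance(
    n_lines: int,
    rho_true: float,
    seed: int = 0,
    lineage: str = "ALL",
    transcript: str = "NPM1",
    mean_log2_tpm: float = 6.0,
    sd_log2_tpm: float = 1.5,
    mean_auc: float = 0.9,
    sd_auc: float = 0.15,
) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Simulate a cell-line table of expression vs drug resistance.

    (log2 TPM, AUC) are drawn from a bivariate Gaussian with correlation
    ``rho_true``; the requested correlation therefore holds exactly on the
    log scale, and a ``tpm`` column (``2**log2_tpm``) is provided for
    analyses on the linear scale.  Higher AUC means a more resistant line.

    Columns: ``cell_line``, ``lineage``, ``auc``, ``log2_tpm_<transcript>``,
    ``tpm_<transcript>``.
    """
    if n_lines < 3:
        raise ValueError("need at least 3 cell lines")
    if abs(rho_true) > 1:
        raise ValueError("|rho_true| must be <= 1")
    rng = np.random.default_rng(seed)
    z1 = rng.normal(size=n_lines)
    z2 = rho_true * z1 + np.sqrt(max(0.0, 1.0 - rho_true**2)) * rng.normal(size=n_lines)
    log2_tpm = mean_log2_tpm + sd_log2_tpm * z1
    auc = mean_auc + sd_auc * z2
    table = pd.DataFrame(
        {
            "cell_line": [f"{lineage}_{i:03d}" for i in range(n_lines)],
            "lineage": lineage,
            "auc": auc,
            f"log2_tpm_{transcript}": log2_tpm,
            f"tpm_{transcript}": 2.0**log2_tpm,
        }
    )
    truth = SyntheticGroundTruth(seed=seed, true_rho=float(rho_true))
    return table, truth
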