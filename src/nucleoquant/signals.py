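"""Marker enrichment, nucleolar signal quantification and time-course fits.

Covers three readouts of nucleolar function and organization:

* rim enrichment of a marker (e.g. KI67, which coats the nucleolar
  surface): mean marker intensity in a thin band around each nucleolus
  divided by the mean nucleoplasmic intensity;
* per-area nucleolar and nucleoplasmic signal means (e.g. nascent-RNA
  5-EU labelling or pre-rRNA FISH), deliberately normalized by area so
  that shrinking nucleoli at constant per-pixel signal leave the mean
  unchanged while the total signal falls;
* normalization of time courses to a reference measurement, and fits of
  signal-vs-time with either a straight line or a one-phase association
  y(t) = y0 + (plateau - y0)(1 - exp(-k t)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from skimage import morphology

from nucleoquant.io import ImageStack
from nucleoquant.segmentation import RegionLabelMap, measure_regions


@dataclass
class SignalMeasurement:
    """Pooled nucleolar/nucleoplasmic signal at one condition and time."""

    condition: str
    time: float  # hours
    nucleolar_mean: float  # AU per unit area; NaN when no nucleoli
    nucleoplasmic_mean: float
    total_nucleolar_signal: float  # AU * um^2
    eccentricity_median: float
    n_nucleoli: int


@dataclass
class EnrichmentRecord:
    """Rim enrichment of a marker at one nucleolus."""

    marker: str
    enrichment: float
    eccentricity: float
    area: float  # um^2
    nucleolus_id: int = 0


@dataclass
class AssociationFit:
    """Fitted signal-vs-time model."""

    y0: float
    plateau: float
    k: float  # per hour; 0 for the linear model
    model: str  # "one-phase" | "linear"
    rss: float
    slope: float = 0.0  # linear model only

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        if self.model == "linear":
            return self.y0 + self.slope * t
        return self.y0 + (self.plateau - self.y0) * (1.0 - np.exp(-self.k * t))


def _nucleoplasm_mask(nuclei: RegionLabelMap, nucleoli: RegionLabelMap, erosion_px: int = 2):
    footprint = morphology.disk(erosion_px)
    nuc = nuclei.labels > 0
    eroded = morphology.erosion(nuc, footprint) if erosion_px else nuc
    foci = nucleoli.labels > 0
    dilated = morphology.dilation(foci, footprint) if erosion_px else foci
    return eroded & ~dilated


def rim_enrichment(
    stack: ImageStack,
    marker_channel,
    nucleoli: RegionLabelMap,
    nuclei: RegionLabelMap,
    rim_width: float = 0.5,
    mode: str = "rim",
    frame: int = 0,
) -> list[EnrichmentRecord]:
    """Marker enrichment at each nucleolus.

    ``mode="rim"`` (default) measures the mean marker intensity in a
    morphological boundary band of width ``rim_width`` (um) around the
    nucleolus; ``mode="whole"`` uses the whole nucleolus instead.  Either
    is divided by the mean nucleoplasmic marker intensity of the image.
    Nucleoli whose rim band is empty (e.g. flush against the nucleus
    border) are skipped with a warning.

    The ratio is invariant to global intensity rescaling.
    """
    if rim_width <= 0:
        raise ValueError("rim_width must be > 0")
    if mode not in ("rim", "whole"):
        raise ValueError(f"unknown mode {mode!r}")
    plane = stack.plane(frame, marker_channel).astype(float)
    nucleoplasm = _nucleoplasm_mask(nuclei, nucleoli)
    if not nucleoplasm.any():
        raise ValueError("no nucleoplasm pixels to normalize against")
    denom = float(plane[nucleoplasm].mean())
    if denom <= 0:
        raise ValueError("nucleoplasmic marker intensity is zero; enrichment undefined")
    rim_px = max(1, int(round(rim_width / stack.pixel_size)))
    footprint = morphology.disk(rim_px)
    inside_nucleus = nuclei.labels > 0

    # shape metrics from the condensate mask itself
    from skimage import measure as skmeasure

    props = {p.label: p for p in skmeasure.regionprops(nucleoli.labels)}
    out = []
    for lab, p in props.items():
        mask = nucleoli.labels == lab
        if mode == "whole":
            band = mask
        else:
            band = morphology.dilation(mask, footprint) & ~mask & inside_nucleus
            band &= nucleoli.labels == 0  # exclude neighbouring nucleoli
        if not band.any():
            warnings.warn(f"nucleolus {lab}: empty rim band; skipped", stacklevel=2)
            continue
        out.append(
            EnrichmentRecord(
                marker=str(marker_channel),
                enrichment=float(plane[band].mean()) / denom,
                eccentricity=float(p.eccentricity) if p.area > 1 else 0.0,
                area=float(p.area) * stack.pixel_size**2,
                nucleolus_id=int(lab),
            )
        )
    return out


def nucleolar_signal(
    stack: ImageStack,
    signal_channel,
    nucleoli: RegionLabelMap,
    nuclei: RegionLabelMap,
    condition: str = "",
    time: float = 0.0,
    frame: int = 0,
) -> SignalMeasurement:
    """Pooled per-area nucleolar and nucleoplasmic signal means.

    ``nucleolar_mean`` is the total signal over all nucleolar pixels
    divided by the total nucleolar area — a per-area mean, so it is
    insensitive to how many or how large the nucleoli are at fixed
    per-pixel brightness; ``total_nucleolar_signal`` (AU.um^2) carries
    the size dependence instead.  With no nucleoli the measurement is
    returned with ``n_nucleoli=0`` and NaN means.
    """
    plane = stack.plane(frame, signal_channel).astype(float)
    px_area = stack.pixel_size**2
    foci_mask = nucleoli.labels > 0
    n_foci = len(nucleoli.ids)
    if foci_mask.any():
        total = float(plane[foci_mask].sum()) * px_area
        nucleolar_mean = total / (float(foci_mask.sum()) * px_area)
    else:
        total, nucleolar_mean = 0.0, float("nan")
    nucleoplasm = _nucleoplasm_mask(nuclei, nucleoli)
    nucleoplasmic_mean = float(plane[nucleoplasm].mean()) if nucleoplasm.any() else float("nan")
    if n_foci:
        from skimage import measure as skmeasure

        eccs = [
            p.eccentricity if p.area > 1 else 0.0
            for p in skmeasure.regionprops(nucleoli.labels)
        ]
        ecc_median = float(np.median(eccs))
    else:
        ecc_median = float("nan")
    return SignalMeasurement(
        condition=condition,
        time=time,
        nucleolar_mean=nucleolar_mean,
        nucleoplasmic_mean=nucleoplasmic_mean,
        total_nucleolar_signal=total,
        eccentricity_median=ecc_median,
        n_nucleoli=n_foci,
    )


def normalize_timecourse(
    measurements: list[SignalMeasurement],
    reference_condition: str,
    reference_time: float | None = None,
) -> list[SignalMeasurement]:
    """Normalize a time course to a reference measurement.

    The reference is the measurement with ``reference_condition`` and, if
    ``reference_time`` is None, the earliest time in that condition.
    Nucleolar means are divided by the reference nucleolar mean and
    nucleoplasmic means by the reference nucleoplasmic mean (each
    compartment is scaled by its own baseline).  Input order is
    irrelevant; the input list is not modified.
    """
    candidates = [m for m in measurements if m.condition == reference_condition]
    if reference_time is not None:
        candidates = [m for m in candidates if m.time == reference_time]
    if not candidates:
        raise ValueError(
            f"no reference measurement for condition {reference_condition!r}"
        )
    ref = min(candidates, key=lambda m: m.time)
    if not (ref.nucleolar_mean and np.isfinite(ref.nucleolar_mean)):
        raise ValueError("reference nucleolar mean is zero or undefined")
    if not (ref.nucleoplasmic_mean and np.isfinite(ref.nucleoplasmic_mean)):
        raise ValueError("reference nucleoplasmic mean is zero or undefined")
    out = []
    for m in measurements:
        out.append(
            SignalMeasurement(
                condition=m.condition,
                time=m.time,
                nucleolar_mean=m.nucleolar_mean / ref.nucleolar_mean,
                nucleoplasmic_mean=m.nucleoplasmic_mean / ref.nucleoplasmic_mean,
                total_nucleolar_signal=m.total_nucleolar_signal,
                eccentricity_median=m.eccentricity_median,
                n_nucleoli=m.n_nucleoli,
            )
        )
    return out


def fit_association(times, values, model: str = "one-phase") -> AssociationFit:
    """Fit signal vs time with a line or a one-phase association.

    One-phase: ``y(t) = y0 + (plateau - y0)(1 - exp(-k t))`` by bounded
    least squares (k >= 0), initialized from the linear fit.  Linear:
    ordinary least squares.  The residual sum of squares is reported for
    model comparison.  A rate pinned at the k = 0 boundary is flagged
    with a warning (the data carry no curvature).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if model == "linear":
        if t.size < 2:
            raise ValueError("linear fit needs at least 2 points")
        res = stats.linregress(t, y)
        pred = res.intercept + res.slope * t
        return AssociationFit(
            y0=float(res.intercept),
            plateau=float("nan"),
            k=0.0,
            model="linear",
            rss=float(np.sum((y - pred) ** 2)),
            slope=float(res.slope),
        )
    if model != "one-phase":
        raise ValueError(f"unknown model {model!r}")
    if t.size < 3:
        raise ValueError("one-phase fit needs at least 3 points")

    def curve(t, y0, plateau, k):
        return y0 + (plateau - y0) * (1.0 - np.exp(-k * t))

    lin = stats.linregress(t, y)
    span = float(np.ptp(t)) or 1.0
    k0 = max(1.0 / span, 1e-6)
    p0 = [float(lin.intercept), float(y[np.argmax(t)]), k0]
    try:
        popt, _ = optimize.curve_fit(
            curve,
            t,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"one-phase fit did not converge (p0={p0}): {exc}") from exc
    y0, plateau, k = (float(v) for v in popt)
    scale = float(np.max(np.abs(y))) or 1.0
    if k < 1e-10 or abs(plateau - y0) < 1e-9 * scale:
        # with no amplitude the rate is unidentifiable; report the k=0
        # boundary explicitly rather than whatever value the optimizer held
        warnings.warn("rate pinned at the k=0 boundary: no curvature in data", stacklevel=2)
        k = 0.0
    pred = curve(t, *popt)
    return AssociationFit(
        y0=y0,
        plateau=plateau,
        k=k,
        model="one-phase",
        rss=float(np.sum((y - pred) ** 2)),
    )
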