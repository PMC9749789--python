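"""Dose-response (EC50) analysis of viability and cell-count data.

The MTT viability readout at drug concentration c is the background-
corrected absorbance

    I(c) = Abs570(c) - Abs690(c),

and the dose dependence is fitted with a decreasing Hill curve with
floor, ceiling and a fixed Hill exponent (default n = 2):

    I(c) = I_min + (I_0 - I_min) / (1 + (c / EC50)^n),

where I_0 is the response as c -> 0, I_min the response floor, and EC50
the half-effect concentration.  The same model applies unchanged to
live-cell counts from rescue assays; EC50 shifts between conditions are
summarized as ratios with propagated standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from nucleoquant.synthetic import hill_response


@dataclass
class MTTReading:
    """One well of an MTT assay."""

    concentration: float  # uM
    abs570: float
    abs690: float
    replicate: int = 0

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class DoseResponseCurve:
    """A fitted dose-response curve."""

    concentrations: np.ndarray
    responses: np.ndarray
    ec50: float  # uM
    i_c0: float  # response as c -> 0
    i_cmin: float  # response floor
    n: float  # Hill exponent
    se: dict = field(default_factory=dict)  # standard errors of fitted params
    covariance: np.ndarray | None = None

    def predict(self, c):
        return hill_response(c, self.ec50, self.i_c0, self.i_cmin, self.n)


def mtt_intensity(reading) -> float:
    """MTT intensity I = Abs570 - Abs690 for one reading.

    Negative values on noisy blanks are preserved, not clipped; the
    intensity is linear in the absorbances, so replicate-averaged
    intensity equals the average of per-replicate intensities.
    """
    if isinstance(reading, MTTReading):
        return reading.abs570 - reading.abs690
    abs570, abs690 = reading
    if abs570 is None or abs690 is None or np.isnan(abs570) or np.isnan(abs690):
        raise ValueError("both wavelengths are required")
    return float(abs570 - abs690)


def mtt_intensities(table: pd.DataFrame) -> pd.DataFrame:
    """Per-well intensities from a table with abs570/abs690 columns."""
    missing = {"concentration", "abs570", "abs690"} - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = table.copy()
    out["response"] = out["abs570"] - out["abs690"]
    return out


def fit_ec50(
    concentrations,
    responses,
    n: float = 2.0,
    free_hill: bool = False,
) -> DoseResponseCurve:
    """Least-squares Hill fit of responses vs concentration.

    ``n`` is held fixed (default 2) unless ``free_hill`` is set.
    Initialization: ceiling = max response, floor = min response, EC50 =
    the concentration nearest the half-response; EC50 is bounded in
    (0, 10 x max c].  Concentration 0 enters the model as-is (the curve
    is well defined there).

    Raises
    ------
    ValueError
        If responses show no concentration dependence ("EC50
        unidentifiable") or inputs are degenerate.
    RuntimeError
        On non-convergence, with the initializer in the message.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concentrations and responses must have the same length")
    if not np.isfinite(y).all():
        raise ValueError("responses must be finite")
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.ptp(y) == 0:
        raise ValueError("EC50 unidentifiable: responses are constant")
    # flat beyond noise: per-concentration means indistinguishable
    means = pd.Series(y).groupby(pd.Series(c)).mean()
    spread = float(means.max() - means.min())
    noise = float(pd.Series(y).groupby(pd.Series(c)).std().fillna(0).mean())
    if spread < 2 * noise and spread < 0.05 * abs(float(means.mean()) or 1.0):
        raise ValueError("EC50 unidentifiable: no concentration dependence beyond noise")

    i0_init = float(y.max())
    imin_init = float(y.min())
    half = (i0_init + imin_init) / 2.0
    pos = c[c > 0]
    ec50_init = float(pos[np.argmin(np.abs(y[c > 0] - half))]) if pos.size else 1.0
    ec50_hi = 10.0 * float(c.max()) if c.max() > 0 else np.inf

    if free_hill:
        p0 = [ec50_init, i0_init, imin_init, n]
        lower = [1e-12, -np.inf, -np.inf, 0.1]
        upper = [ec50_hi, np.inf, np.inf, 10.0]
        model = hill_response
    else:
        p0 = [ec50_init, i0_init, imin_init]
        lower = [1e-12, -np.inf, -np.inf]
        upper = [ec50_hi, np.inf, np.inf]

        def model(cc, ec50, i0, imin):
            return hill_response(cc, ec50, i0, imin, n)

    try:
        popt, pcov = optimize.curve_fit(
            model, c, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"EC50 fit did not converge (p0={p0}): {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    names = ["ec50", "i_c0", "i_cmin"] + (["n"] if free_hill else [])
    se = {k: float(v) for k, v in zip(names, perr)}
    return DoseResponseCurve(
        concentrations=c,
        responses=y,
        ec50=float(popt[0]),
        i_c0=float(popt[1]),
        i_cmin=float(popt[2]),
        n=float(popt[3]) if free_hill else float(n),
        se=se,
        covariance=pcov,
    )


def fit_ec50_counts(concentrations, cell_counts, n: float = 2.0, free_hill: bool = False) -> DoseResponseCurve:
    """Hill fit of live-cell counts vs concentration (rescue assays).

    Identical model to :func:`fit_ec50`, applied to counts; counts must
    be non-negative and not all zero.
    """
    counts = np.asarray(cell_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("cell counts must be >= 0")
    if not np.any(counts > 0):
        raise ValueError("all counts are zero: nothing to fit")
    return fit_ec50(concentrations, counts, n=n, free_hill=free_hill)


def ec50_ratio(curve_a: DoseResponseCurve, curve_b: DoseResponseCurve) -> tuple[float, tuple]:
    """Fold change EC50_b / EC50_a with a propagated-SE interval.

    The relative standard error of the ratio combines both fits'
    EC50 standard errors in quadrature; the interval is the ratio
    +/- 1.96 of its standard error.  ``ratio(a, b) == 1 / ratio(b, a)``.
    """
    for curve, name in ((curve_a, "a"), (curve_b, "b")):
        if not np.isfinite(curve.ec50) or curve.ec50 <= 0:
            raise ValueError(f"fit {name} failed or has invalid EC50")
    ratio = curve_b.ec50 / curve_a.ec50
    rel_a = curve_a.se.get("ec50", 0.0) / curve_a.ec50
    rel_b = curve_b.se.get("ec50", 0.0) / curve_b.ec50
    se = ratio * float(np.hypot(rel_a, rel_b))
    return float(ratio), (float(ratio - 1.96 * se), float(ratio + 1.96 * se))
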