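"""qPCR fold changes and cell-line expression-vs-resistance statistics.

Relative transcript quantification uses the classic delta-delta-Ct
scheme with amplification efficiency 2: Ct values of the target gene are
normalized to a reference gene within each condition,

    dCt = mean(Ct_target) - mean(Ct_reference),

the treated condition is compared with the untreated one,

    ddCt = dCt_treated - dCt_untreated,    fold = 2 ** (-ddCt).

Cohort analysis correlates drug resistance (area under the
dose-viability curve, AUC: higher = more resistant) with transcript
expression (TPM) across cell lines: Pearson's rho per transcript, an
ordinary-least-squares trend line and its 90% confidence band, optionally
stratified by cancer lineage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class CtRecord:
    """One qPCR well: target and reference-gene threshold cycles."""

    condition: str
    target: str
    ct_target: float
    ct_reference: float
    replicate: int = 0

    def __post_init__(self):
        for ct in (self.ct_target, self.ct_reference):
            if not 0 < ct < 45:
                raise ValueError(f"Ct value {ct} outside the plausible (0, 45) range")


@dataclass
class FoldChange:
    """Relative expression of a condition vs the untreated reference."""

    condition: str
    target: str
    fold: float
    ddct: float  # cycles


@dataclass
class CorrelationResult:
    """Expression-resistance correlation for one transcript."""

    transcript: str
    rho: float  # Pearson; NaN when undefined
    n: int
    slope: float
    intercept: float
    p_value: float
    ci90: dict = field(default_factory=dict)  # params to evaluate the 90% band
    flagged: bool = False  # True when rho is undefined (constant input)

    def confidence_band(self, x):
        """Evaluate the 90% confidence band of the mean trend at x."""
        x = np.asarray(x, dtype=float)
        p = self.ci90
        mean = self.intercept + self.slope * x
        se = p["resid_std"] * np.sqrt(1.0 / p["n"] + (x - p["x_mean"]) ** 2 / p["sxx"])
        half = p["t_crit"] * se
        return mean - half, mean + half


def _group_dct(records) -> float:
    tgt = np.array([r.ct_target for r in records], dtype=float)
    ref = np.array([r.ct_reference for r in records], dtype=float)
    return float(tgt.mean() - ref.mean())


def delta_delta_ct(treated, untreated) -> FoldChange:
    """Fold change of the treated condition relative to the untreated one.

    Replicates are averaged in Ct space (arithmetic mean of cycles)
    before differencing; fold = 2**(-ddCt) assumes doubling per cycle.
    Pure arithmetic — bit-for-bit reproducible from the table.
    """
    treated, untreated = list(treated), list(untreated)
    if not treated or not untreated:
        raise ValueError("both groups must be non-empty")
    targets = {r.target for r in treated} | {r.target for r in untreated}
    if len(targets) > 1:
        raise ValueError(f"target mismatch: {sorted(targets)}")
    ddct = _group_dct(treated) - _group_dct(untreated)
    return FoldChange(
        condition=treated[0].condition,
        target=treated[0].target,
        fold=float(2.0 ** (-ddct)),
        ddct=float(ddct),
    )


def fold_changes_from_table(
    table: pd.DataFrame, reference_condition: str = "untreated"
) -> list[FoldChange]:
    """Per-condition fold changes from a Ct table.

    The table needs columns ``condition``, ``target``, ``ct_target``,
    ``ct_reference`` (and optionally ``replicate``).
    """
    records = [
        CtRecord(
            condition=row.condition,
            target=row.target,
            ct_target=row.ct_target,
            ct_reference=row.ct_reference,
            replicate=int(getattr(row, "replicate", 0)),
        )
        for row in table.itertuples()
    ]
    by_cond: dict[str, list[CtRecord]] = {}
    for r in records:
        by_cond.setdefault(r.condition, []).append(r)
    if reference_condition not in by_cond:
        raise ValueError(f"reference condition {reference_condition!r} not in table")
    ref = by_cond[reference_condition]
    return [delta_delta_ct(group, ref) for cond, group in by_cond.items()]


def expression_resistance_correlation(
    table: pd.DataFrame,
    transcripts,
    auc_column: str = "auc",
    lineage: str | None = None,
    log2_tpm: bool = False,
    alpha: float = 0.10,
) -> list[CorrelationResult]:
    """Correlate drug resistance with expression across cell lines.

    For each transcript column, computes Pearson's rho between AUC and
    expression and fits an OLS trend (expression on the x axis, AUC on
    the y axis) whose ``(1 - alpha)`` confidence band parameters are
    stored for plotting.  ``log2_tpm=True`` transforms the expression to
    log2(TPM + 1) first.  Transcripts with constant expression (or a
    constant AUC) are flagged with rho = NaN rather than dropped.
    """
    if lineage is not None:
        table = table[table["lineage"] == lineage]
    if len(table) < 3:
        raise ValueError("need at least 3 cell lines after subsetting")
    auc = table[auc_column].to_numpy(dtype=float)
    out = []
    for tr in transcripts:
        col = tr if tr in table.columns else f"tpm_{tr}"
        if col not in table.columns:
            raise ValueError(f"transcript column {tr!r} not in table")
        x = table[col].to_numpy(dtype=float)
        if log2_tpm:
            x = np.log2(x + 1.0)
        if np.ptp(x) == 0 or np.ptp(auc) == 0:
            out.append(
                CorrelationResult(
                    transcript=tr,
                    rho=float("nan"),
                    n=len(x),
                    slope=float("nan"),
                    intercept=float("nan"),
                    p_value=float("nan"),
                    flagged=True,
                )
            )
            continue
        rho, p = stats.pearsonr(x, auc)
        ols = sm.OLS(auc, sm.add_constant(x)).fit()
        n = len(x)
        ci90 = {
            "n": n,
            "x_mean": float(x.mean()),
            "sxx": float(np.sum((x - x.mean()) ** 2)),
            "resid_std": float(np.sqrt(ols.scale)),
            "t_crit": float(stats.t.ppf(1.0 - alpha / 2.0, n - 2)),
            "alpha": alpha,
        }
        out.append(
            CorrelationResult(
                transcript=tr,
                rho=float(rho),
                n=n,
                slope=float(ols.params[1]),
                intercept=float(ols.params[0]),
                p_value=float(p),
                ci90=ci90,
            )
        )
    return out


def stratified_correlation(
    table: pd.DataFrame,
    transcripts,
    lineage_column: str = "lineage",
    min_lines: int = 3,
    **kwargs,
) -> dict:
    """Expression-resistance correlation computed separately per lineage.

    Groups with fewer than ``min_lines`` cell lines are skipped with a
    warning.  Returns ``{lineage: [CorrelationResult, ...]}``.
    """
    out = {}
    for lin, group in table.groupby(lineage_column):
        if len(group) < min_lines:
            warnings.warn(f"lineage {lin!r}: only {len(group)} lines; skipped", stacklevel=2)
            continue
        out[lin] = expression_resistance_correlation(group, transcripts, **kwargs)
    return out


def fisher_z_interval(rho: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValueError("need n >= 4")
    z = np.arctanh(rho)
    se = 1.0 / np.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + confidence / 2.0)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))
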