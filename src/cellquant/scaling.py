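"""Population-level expression statistics.

Covers the ΔCq arithmetic of relative qPCR quantification, condition fold
changes, the log-log regression that measures how expression scales with
cell volume (the "scaling exponent"), linear fits with 95% confidence bands
and slope comparison, and the normality-gated two-group test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ScalingFit",
    "LinearFit",
    "GroupComparison",
    "qpcr_relative_concentration",
    "qpcr_table_relative",
    "fold_change",
    "fit_scaling_exponent",
    "fit_linear_with_ci",
    "compare_groups",
]


@dataclass(frozen=True)
class ScalingFit:
    """Scaling exponent: OLS slope of log(expression) on log(volume)."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    slope_se: float
    n: int


@dataclass(frozen=True)
class LinearFit:
    """An OLS line with t-based pointwise 95% confidence band at the data.

    ``p_slope_difference`` is filled when the fit was compared against a
    second dataset (standard two-regression interaction test).
    """

    slope: float
    intercept: float
    slope_se: float
    ci_low: float
    ci_high: float
    band_lower: np.ndarray
    band_upper: np.ndarray
    n: int
    p_slope_difference: float | None = None


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of the normality-gated two-group comparison."""

    test: Literal["t", "mann-whitney"]
    statistic: float
    p_value: float
    normality_p: tuple[float, float]
    alpha: float


def qpcr_relative_concentration(cq_gene, cq_ref):
    """Relative concentration from quantification cycles.

    log2(relative concentration) = -(Cq_gene - Cq_ref), i.e. the value is
    ``2 ** (cq_ref - cq_gene)``.  Accepts scalars or arrays.
    """
    cq_gene = np.asarray(cq_gene, dtype=float)
    cq_ref = np.asarray(cq_ref, dtype=float)
    if not (np.all(np.isfinite(cq_gene)) and np.all(np.isfinite(cq_ref))):
        raise ValueError("Cq values must be finite")
    out = 2.0 ** (cq_ref - cq_gene)
    return float(out) if out.ndim == 0 else out


def qpcr_table_relative(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative concentrations from a raw Cq table.

    Technical replicates are averaged on the Cq scale first (the standard
    qPCR convention), then converted:  one row per (gene, condition,
    biological replicate) with a ``rel_conc`` column.
    """
    required = {"gene", "condition", "bio_rep", "cq", "cq_ref"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Cq table is missing columns: {sorted(missing)}")
    grouped = (
        table.groupby(["gene", "condition", "bio_rep"], as_index=False)[["cq", "cq_ref"]]
        .mean()
    )
    grouped["rel_conc"] = qpcr_relative_concentration(grouped["cq"], grouped["cq_ref"])
    return grouped.drop(columns=["cq", "cq_ref"])


def fold_change(
    rel_table: pd.DataFrame,
    reference_condition: str,
    value_col: str = "rel_conc",
) -> pd.DataFrame:
    """Per-condition fold changes of relative concentration vs a reference.

    Each biological replicate's value is divided by the mean of the
    reference condition (per gene); the table reports the mean and standard
    error of those per-replicate fold changes.  The reference condition
    itself therefore has fold change 1.0 by construction of its mean.
    """
    if reference_condition not in set(rel_table["condition"]):
        raise ValueError(f"reference condition {reference_condition!r} not present")
    rows = []
    for gene, sub in rel_table.groupby("gene"):
        ref = sub.loc[sub["condition"] == reference_condition, value_col]
        ref_mean = float(ref.mean())
        if ref_mean == 0:
            raise ValueError(f"zero reference mean for gene {gene!r}")
        for cond, csub in sub.groupby("condition"):
            ratios = csub[value_col].to_numpy(dtype=float) / ref_mean
            n = ratios.size
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "fold_change": float(ratios.mean()),
                    "se": float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def fit_scaling_exponent(
    volumes: Sequence[float], values: Sequence[float], alpha: float = 0.05
) -> ScalingFit:
    """Exponent of expression–volume scaling by log-log OLS regression.

    For amounts following c·V^a the slope recovers a; for concentrations of
    a constant-amount gene the slope is -1.  Natural logs are used
    internally; the exponent is base-invariant.
    """
    v = np.asarray(volumes, dtype=float)
    y = np.asarray(values, dtype=float)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("volumes and values must be matching 1D arrays")
    if v.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(v <= 0) or np.any(y <= 0):
        raise ValueError("volumes and values must be positive for log-log fit")
    X = sm.add_constant(np.log(v))
    fit = sm.OLS(np.log(y), X).fit()
    ci = fit.conf_int(alpha=alpha)
    return ScalingFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        slope_se=float(fit.bse[1]),
        n=v.size,
    )


def fit_linear_with_ci(
    x: Sequence[float],
    y: Sequence[float],
    other: tuple[Sequence[float], Sequence[float]] | None = None,
    alpha: float = 0.05,
) -> LinearFit:
    """OLS line with pointwise 95% confidence band at the data points.

    When ``other = (x2, y2)`` is given, the slopes of the two regressions
    are compared with the standard interaction test: a pooled model
    ``y ~ x + group + x:group`` whose interaction-term p-value tests slope
    equality.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=alpha)
    ci = fit.conf_int(alpha=alpha)

    p_diff = None
    if other is not None:
        x2 = np.asarray(other[0], dtype=float)
        y2 = np.asarray(other[1], dtype=float)
        if x2.size < 3:
            raise ValueError("second dataset needs at least 3 points")
        xx = np.concatenate([x, x2])
        yy = np.concatenate([y, y2])
        group = np.concatenate([np.zeros(x.size), np.ones(x2.size)])
        design = np.column_stack([np.ones(xx.size), xx, group, xx * group])
        pooled = sm.OLS(yy, design).fit()
        t_val = pooled.tvalues[3]
        # identical datasets give an exactly-zero interaction; the p-value
        # is then 1 by definition even if the SE is degenerate
        p_diff = 1.0 if pooled.params[3] == 0 else float(pooled.pvalues[3])
        del t_val

    return LinearFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        band_lower=pred["mean_ci_lower"].to_numpy(),
        band_upper=pred["mean_ci_upper"].to_numpy(),
        n=x.size,
        p_slope_difference=p_diff,
    )


def compare_groups(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> GroupComparison:
    """Two-group comparison gated on Shapiro–Wilk normality.

    Both samples are tested for normality at level ``alpha``; if both pass,
    an unpaired two-tailed t-test is used, otherwise a two-sided
    Mann–Whitney U test.  The chosen path is reported alongside the
    normality p-values so the gate is auditable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    p_x = float(stats.shapiro(x).pvalue)
    p_y = float(stats.shapiro(y).pvalue)
    if p_x > alpha and p_y > alpha:
        res = stats.ttest_ind(x, y)
        return GroupComparison(
            test="t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            normality_p=(p_x, p_y),
            alpha=alpha,
        )
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return GroupComparison(
        test="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=(p_x, p_y),
        alpha=alpha,
    )
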