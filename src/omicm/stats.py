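"""Univariate cohort statistics: mean ± SD summaries, unpaired t-tests,
Glass's Δ effect sizes with category labels, and single-cell histograms.

Glass's Δ divides the mean difference by the *reference* group's standard
deviation (n−1 denominator), which matters when variances differ between
conditions; categories follow the conventional thresholds — below 0.2
small, 0.2–0.5 medium, 0.5–0.8 large, 0.8 and above very large — with
half-open intervals at the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectSizeResult",
    "TestResult",
    "glass_delta",
    "effect_category",
    "ttest_unpaired",
    "summarize_groups",
    "variable_histogram",
]

_CATEGORY_EDGES = ((0.2, "small"), (0.5, "medium"), (0.8, "large"))


def effect_category(delta: float) -> str:
    """Map a non-negative Glass's Δ magnitude to its size category."""
    if delta < 0:
        raise ValueError("category is defined on the magnitude, delta >= 0")
    for edge, name in _CATEGORY_EDGES:
        if delta < edge:
            return name
    return "very_large"


@dataclass(frozen=True)
class EffectSizeResult:
    delta: float
    signed_delta: float
    category: str
    reference_group: str
    comparison_group: str
    n_ref: int
    n_cmp: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float
    significant: bool
    alpha: float = 0.05


def glass_delta(
    reference,
    comparison,
    reference_label: str = "reference",
    comparison_label: str = "comparison",
) -> EffectSizeResult:
    """Glass's Δ = (mean(comparison) − mean(reference)) / SD(reference)."""
    ref = np.asarray(reference, dtype=float)
    cmp_ = np.asarray(comparison, dtype=float)
    if ref.size < 2:
        raise ValueError("reference group needs >= 2 values")
    if cmp_.size < 1:
        raise ValueError("comparison group is empty")
    sd_ref = ref.std(ddof=1)
    if sd_ref == 0:
        raise ValueError("reference group has zero standard deviation")
    signed = float((cmp_.mean() - ref.mean()) / sd_ref)
    mag = abs(signed)
    return EffectSizeResult(
        delta=mag,
        signed_delta=signed,
        category=effect_category(mag),
        reference_group=reference_label,
        comparison_group=comparison_label,
        n_ref=int(ref.size),
        n_cmp=int(cmp_.size),
    )


def ttest_unpaired(a, b, equal_var: bool = False, alpha: float = 0.05) -> TestResult:
    """Two-tailed unpaired t-test (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(getattr(res, "df", a.size + b.size - 2))
    p = float(res.pvalue)
    return TestResult(
        statistic=float(res.statistic),
        p_value=p,
        df=df,
        significant=p < alpha,
        alpha=alpha,
    )


def summarize_groups(
    table: pd.DataFrame, variable: str, group_by
) -> pd.DataFrame:
    """Per-group n, mean and sample SD (mean ± SD reporting).

    Singleton groups get ``NaN`` SD (undefined with an n−1 denominator).
    """
    if variable not in table.columns:
        raise KeyError(f"unknown column {variable!r}")
    group_by = [group_by] if isinstance(group_by, str) else list(group_by)
    for col in group_by:
        if col not in table.columns:
            raise KeyError(f"unknown column {col!r}")
    out = (
        table.groupby(group_by, sort=True, observed=True)[variable]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    if (out["n"] == 0).any():
        raise ValueError("empty group encountered")
    return out


def variable_histogram(
    table: pd.DataFrame, variable: str, group_by, n_bins: int = 30
) -> dict:
    """Per-group histogram counts over bin edges shared across groups."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if variable not in table.columns:
        raise KeyError(f"unknown column {variable!r}")
    group_by = [group_by] if isinstance(group_by, str) else list(group_by)
    for col in group_by:
        if col not in table.columns:
            raise KeyError(f"unknown column {col!r}")
    values = table[variable].to_numpy(dtype=float)
    lo, hi = values.min(), values.max()
    if lo == hi:  # all mass in one bin: widen symmetrically
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    counts = {}
    for key, sub in table.groupby(group_by, sort=True, observed=True):
        label = key if len(group_by) > 1 else key[0] if isinstance(key, tuple) else key
        counts[label], _ = np.histogram(sub[variable].to_numpy(dtype=float), bins=edges)
    return {"edges": edges, "counts": counts}
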