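"""Association of stratification groups with clinical covariates and
external per-sample measurements (e.g. RPPA protein levels)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cnv import rank_sum_test
from .datatypes import Stratification

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyResult",
    "ContinuousComparison",
    "contingency_test",
    "compare_continuous",
    "dichotomize_at_median",
]


@dataclass(frozen=True)
class ContingencyResult:
    table: pd.DataFrame     # groups x categories counts
    chi_square: float
    df: int
    p: float
    fisher_p: float | None  # two-sided Fisher exact p, 2x2 tables only
    n_dropped: int


def contingency_test(
    strat: Stratification,
    covariate: pd.Series,
    groups: tuple[str, str] = ("hi", "lo"),
) -> ContingencyResult:
    """Pearson chi-square test (no continuity correction) of group vs
    categorical covariate; 2x2 tables additionally get a two-sided Fisher
    exact p. Samples missing the covariate are dropped and logged."""
    covariate = pd.Series(covariate)
    rows = []
    n_dropped = 0
    for group in groups:
        samples = strat.samples(group)
        values = covariate.reindex(samples)
        n_dropped += int(values.isna().sum())
        rows.append(values.dropna())
    if n_dropped:
        log.info("contingency test: dropped %d samples missing the covariate", n_dropped)
    categories = sorted(set().union(*[set(r.unique()) for r in rows]))
    counts = pd.DataFrame(
        [[int((r == c).sum()) for c in categories] for r in rows],
        index=list(groups), columns=categories,
    )
    nonzero_cols = counts.sum(axis=0) > 0
    counts = counts.loc[:, nonzero_cols]
    if counts.shape[1] < 2:
        raise ValueError("covariate has a single nonzero category; test undefined")
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("a stratification group has no usable samples")
    chi2, p, df, _ = stats.chi2_contingency(counts.to_numpy(), correction=False)
    fisher_p = None
    if counts.shape == (2, 2):
        _, fisher_p = stats.fisher_exact(counts.to_numpy(), alternative="two-sided")
        fisher_p = float(fisher_p)
    return ContingencyResult(
        table=counts, chi_square=float(chi2), df=int(df), p=float(p),
        fisher_p=fisher_p, n_dropped=n_dropped,
    )


@dataclass(frozen=True)
class ContinuousComparison:
    p: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    group_a: str
    group_b: str


def compare_continuous(
    strat: Stratification,
    values: pd.Series,
    group_a: str = "hi",
    group_b: str = "lo",
) -> ContinuousComparison:
    """Two-sided Wilcoxon rank-sum comparison of a per-sample numeric
    measurement between two groups (same test as the copy-number scan)."""
    values = pd.Series(values).astype(float)
    a = values.reindex(strat.samples(group_a)).dropna().to_numpy()
    b = values.reindex(strat.samples(group_b)).dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 values per group (got {len(a)}, {len(b)})")
    return ContinuousComparison(
        p=rank_sum_test(a, b),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=len(a), n_b=len(b),
        group_a=group_a, group_b=group_b,
    )


def dichotomize_at_median(values: pd.Series, labels=("low", "high")) -> pd.Series:
    """Split a numeric covariate at its cohort median (<= median -> first
    label) so it can enter a contingency table; the threshold is logged."""
    values = pd.Series(values).astype(float)
    threshold = float(values.median())
    log.info("dichotomizing %s at median %.4g", values.name or "covariate", threshold)
    out = pd.Series(np.where(values > threshold, labels[1], labels[0]),
                    index=values.index)
    return out.where(values.notna())
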