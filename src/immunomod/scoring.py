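"""Per-sample module scoring and sample stratification.

The score of a module in a sample is the *median* log2 expression of the
module's member genes found in the tumor matrix — a robust one-number
summary that is invariant to member-gene ordering. Stratification assigns
"hi"/"lo" (median split) or "lo"/"med"/"hi" (hierarchical clustering on the
member-gene sub-matrix) labels per sample; group names always order by
ascending mean score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import pearsonr

from .datatypes import ExpressionMatrix, Module, Stratification

log = logging.getLogger(__name__)

__all__ = [
    "ScoreVector",
    "InsufficientGenesError",
    "module_score",
    "median_split",
    "cluster_stratify",
    "score_correlation",
]


class InsufficientGenesError(ValueError):
    """Raised when too few module genes are present to score a matrix."""

    def __init__(self, module: str, found: int, required: int):
        super().__init__(
            f"module {module}: only {found} member genes present "
            f"(require >= {required}); module skipped"
        )
        self.module = module
        self.found = found
        self.required = required


@dataclass(frozen=True)
class ScoreVector:
    module: str
    scores: pd.Series  # sample_id -> median log2 expression of member genes
    n_genes_used: int
    n_genes_missing: int


def module_score(
    expr: ExpressionMatrix, module: Module, min_genes: int = 10
) -> ScoreVector:
    """Median log2 expression of the module's genes, per sample.

    Member genes absent from ``expr`` are ignored and counted; if fewer than
    ``min_genes`` remain the module is not scoreable and
    :class:`InsufficientGenesError` is raised.
    """
    present = [g for g in module.genes if g in expr.data.index]
    if len(present) < min_genes:
        raise InsufficientGenesError(module.name, len(present), min_genes)
    missing = len(module.genes) - len(present)
    if missing:
        log.info("module %s: %d member genes absent from matrix", module.name, missing)
    scores = expr.data.loc[present].median(axis=0)
    return ScoreVector(
        module=module.name,
        scores=scores,
        n_genes_used=len(present),
        n_genes_missing=missing,
    )


def median_split(scores: ScoreVector) -> Stratification:
    """Two-group split at the cohort median score.

    "hi" means strictly higher than the median; samples exactly at the
    median go to "lo", so with an odd n the extra sample lands in "lo"
    (sizes ceil(n/2) / floor(n/2)).
    """
    values = scores.scores
    if len(values) < 4:
        raise ValueError("median split needs >= 4 samples")
    med = float(values.median())
    if float(values.max()) == float(values.min()):
        raise ValueError(f"module {scores.module}: all scores identical; degenerate split")
    labels = pd.Series(np.where(values > med, "hi", "lo"), index=values.index)
    return Stratification(
        module=scores.module, labels=labels,
        scheme="median_split", group_order=("lo", "hi"),
    )


def _group_names(k: int) -> tuple[str, ...]:
    if k == 2:
        return ("lo", "hi")
    if k == 3:
        return ("lo", "med", "hi")
    return tuple(f"g{i + 1}" for i in range(k))


def cluster_stratify(
    expr: ExpressionMatrix,
    module: Module,
    k: int = 3,
    linkage: str = "average",
    min_genes: int = 10,
) -> Stratification:
    """Stratify samples by hierarchical clustering on member-gene expression.

    Each member-gene row is standardized to mean 0 / sd 1 across samples,
    samples are clustered agglomeratively (Euclidean distance, configurable
    linkage), the tree is cut into ``k`` groups, and groups are relabeled by
    ascending mean module score (lo < med < hi). Deterministic: no random
    initialization is involved.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > expr.shape[1]:
        raise ValueError(f"k={k} exceeds number of samples ({expr.shape[1]})")
    scores = module_score(expr, module, min_genes=min_genes)
    names = _group_names(k)
    if k == 1:
        labels = pd.Series(names[0], index=expr.data.columns)
        return Stratification(module=module.name, labels=labels,
                              scheme="kgroups", group_order=names)
    present = [g for g in module.genes if g in expr.data.index]
    sub = expr.data.loc[present]
    sd = sub.std(axis=1, ddof=0)
    sub = sub.loc[sd > 0]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
    tree = hierarchy.linkage(z.T.to_numpy(), method=linkage, metric="euclidean")
    raw = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    raw_labels = pd.Series(raw, index=expr.data.columns)
    order = (
        scores.scores.groupby(raw_labels).mean().sort_values().index.tolist()
    )
    if len(order) != k:
        log.warning("module %s: %d-cut produced only %d distinct groups",
                    module.name, k, len(order))
    mapping = {cl: names[i] for i, cl in enumerate(order)}
    labels = raw_labels.map(mapping)
    return Stratification(
        module=module.name, labels=labels,
        scheme="kgroups", group_order=tuple(names[: len(order)]),
    )


def score_correlation(
    expr: ExpressionMatrix,
    module_a: Module,
    module_b: Module,
    min_genes: int = 10,
) -> float:
    """Pearson r between two modules' score vectors across shared samples."""
    a = module_score(expr, module_a, min_genes=min_genes).scores
    b = module_score(expr, module_b, min_genes=min_genes).scores
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    return float(pearsonr(a.loc[shared], b.loc[shared]).statistic)
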