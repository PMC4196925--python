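"""Marker-anchored co-expression module construction.

A module is the marker gene plus the genes whose expression is most
positively Pearson-correlated with it across the reference samples — by
default the top 100, with no correlation cutoff. The marker trivially has
r = 1 with itself and always ranks first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, Module, ModuleSet

log = logging.getLogger(__name__)

__all__ = ["build_module", "build_module_set", "ModuleSetSummary", "ModuleSetBuild"]


def _marker_correlations(ref: ExpressionMatrix, marker: str) -> pd.Series:
    """Pearson r of every non-constant gene row against the marker row."""
    if marker not in ref.data.index:
        raise KeyError(f"marker {marker!r} not in reference matrix")
    if ref.shape[1] < 3:
        raise ValueError("reference matrix needs >= 3 samples")
    values = ref.values
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    eligible = norms > 0
    m_idx = ref.data.index.get_loc(marker)
    if not eligible[m_idx]:
        raise ValueError(f"marker {marker!r} has zero variance across samples")
    m = centered[m_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = centered @ m / (norms * norms[m_idx])
    r = np.clip(r, -1.0, 1.0)
    return pd.Series(r[eligible], index=ref.data.index[eligible])


def build_module(ref: ExpressionMatrix, marker: str, size: int = 100) -> Module:
    """Build one module of (up to) ``size`` genes around ``marker``.

    Genes with zero variance are excluded (their correlation is undefined);
    exact ties at the cutoff rank are broken by gene id, so the result does
    not depend on the row order of the input matrix. If fewer than ``size``
    genes are eligible the module is shorter and a warning is logged.
    """
    if size < 1:
        raise ValueError("size must be positive")
    r = _marker_correlations(ref, marker)
    ranked = (
        r.rename("r").rename_axis("gene_id").reset_index()
        .sort_values(["r", "gene_id"], ascending=[False, True], kind="stable")
    )
    # The marker is a member of its own module and, having r = 1, ranks first
    # ahead of any other perfectly collinear gene.
    ranked = pd.concat([
        ranked[ranked["gene_id"] == marker],
        ranked[ranked["gene_id"] != marker],
    ])
    if len(ranked) < size:
        log.warning("module %s.mod: only %d eligible genes (requested %d)",
                    marker, len(ranked), size)
    top = ranked.head(size)
    members = tuple(zip(top["gene_id"], top["r"]))
    return Module(name=f"{marker}.mod", members=members)


@dataclass(frozen=True)
class ModuleSetSummary:
    """Set-level description of a built module collection."""

    n_modules: int
    n_distinct_genes: int
    min_correlation: float
    median_correlation: float
    max_correlation: float


@dataclass(frozen=True)
class ModuleSetBuild:
    module_set: ModuleSet
    summary: ModuleSetSummary
    failures: dict[str, str]  # marker -> reason


def build_module_set(
    ref: ExpressionMatrix,
    markers: list[str],
    size: int = 100,
) -> ModuleSetBuild:
    """Build one module per marker; failed markers are recorded and skipped."""
    modules: dict[str, Module] = {}
    failures: dict[str, str] = {}
    for marker in markers:
        try:
            mod = build_module(ref, marker, size=size)
        except (KeyError, ValueError) as exc:
            failures[marker] = str(exc)
            log.warning("skipping marker %s: %s", marker, exc)
            continue
        modules[mod.name] = mod
    if not modules:
        raise ValueError(f"no module could be built from {len(markers)} markers")
    module_set = ModuleSet(modules)
    all_r = np.concatenate([np.asarray(m.correlations) for m in module_set])
    summary = ModuleSetSummary(
        n_modules=len(module_set),
        n_distinct_genes=len(module_set.gene_union()),
        min_correlation=float(all_r.min()),
        median_correlation=float(np.median(all_r)),
        max_correlation=float(all_r.max()),
    )
    return ModuleSetBuild(module_set=module_set, summary=summary, failures=failures)
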