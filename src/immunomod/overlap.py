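"""Pairwise gene overlap among modules and grouping into module families."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import ModuleSet

__all__ = ["OverlapMatrix", "ModuleGroups", "overlap_matrix", "cluster_module_groups"]


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric matrix of gene-overlap fractions in [0, 1], diagonal 1."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if not np.allclose(values, values.T):
            raise ValueError("overlap matrix not symmetric")
        if values.min() < 0 or values.max() > 1 + 1e-12:
            raise ValueError("overlap fractions outside [0, 1]")

    @property
    def module_names(self) -> list[str]:
        return list(self.data.index)


def overlap_matrix(
    modules: ModuleSet,
    subset: list[str] | None = None,
    denominator: str = "min",
) -> OverlapMatrix:
    """Fraction of shared genes for every module pair.

    ``denominator='min'`` divides the intersection by the smaller module
    (equal to /100 when all modules are full-size); ``'union'`` gives the
    Jaccard index.
    """
    names = list(subset) if subset is not None else modules.names
    unknown = [n for n in names if n not in modules.modules]
    if unknown:
        raise KeyError(f"unknown modules: {unknown}")
    if not names:
        raise ValueError("empty module subset")
    if denominator not in ("min", "union"):
        raise ValueError(f"unknown denominator {denominator!r}")
    sets = {n: set(modules[n].genes) for n in names}
    out = np.ones((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            inter = len(sets[a] & sets[b])
            if denominator == "min":
                denom = min(len(sets[a]), len(sets[b]))
            else:
                denom = len(sets[a] | sets[b])
            out[i, j] = out[j, i] = inter / denom if denom else 0.0
    return OverlapMatrix(pd.DataFrame(out, index=names, columns=names))


@dataclass(frozen=True)
class ModuleGroups:
    assignments: dict[str, int]       # module -> group id (1-based)
    groups: tuple[tuple[str, ...], ...]  # member lists, ordered

    def n_groups(self) -> int:
        return len(self.groups)


def cluster_module_groups(
    om: OverlapMatrix,
    linkage: str = "complete",
    cut_height: float = 0.7,
    screen_table: pd.DataFrame | None = None,
) -> ModuleGroups:
    """Group modules by hierarchical clustering on distance 1 - overlap.

    The tree is cut at ``cut_height``: two modules end up in one group only
    if they link below that distance. Groups are ordered by the smallest
    member p-value when a screen table (columns ``module``, ``p``) is
    supplied, otherwise by first module name.
    """
    names = om.module_names
    if len(names) == 1:
        return ModuleGroups(assignments={names[0]: 1}, groups=((names[0],),))
    dist = 1.0 - om.data.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = hierarchy.linkage(condensed, method=linkage)
    raw = hierarchy.fcluster(tree, t=cut_height, criterion="distance")
    members: dict[int, list[str]] = {}
    for name, cl in zip(names, raw):
        members.setdefault(int(cl), []).append(name)
    if screen_table is not None:
        best_p = screen_table.set_index("module")["p"]
        key = lambda mods: (float(best_p.reindex(mods).min()), mods[0])
    else:
        key = lambda mods: (0.0, mods[0])
    ordered = sorted(members.values(), key=key)
    assignments = {m: gid for gid, mods in enumerate(ordered, start=1) for m in mods}
    return ModuleGroups(
        assignments=assignments,
        groups=tuple(tuple(mods) for mods in ordered),
    )
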