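"""Core in-memory containers shared by every pipeline stage.

All tabular data is held in :class:`pandas.DataFrame` objects; the thin
dataclass wrappers exist to enforce the invariants each stage relies on
(unique identifiers, finite values, consistent shapes) exactly once, at
construction time, instead of defensively in every function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CopyNumberMatrix",
    "GeneAnnotation",
    "SurvivalTable",
    "Module",
    "ModuleSet",
    "Stratification",
]

#: Canonical clinical covariate columns, in the order they are written to disk.
CLINICAL_COVARIATES = (
    "gender",
    "stage",
    "breslow_mm",
    "ulceration",
    "age_years",
    "primary_site",
)


def _check_unique(values: pd.Index, what: str) -> None:
    if values.has_duplicates:
        dup = values[values.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dup[:5]}")


def _check_finite(frame: pd.DataFrame, what: str) -> None:
    values = frame.to_numpy()
    if not np.isfinite(values).all():
        n_bad = int((~np.isfinite(values)).sum())
        raise ValueError(f"{what} contains {n_bad} non-finite values")


@dataclass(frozen=True)
class _GeneBySampleMatrix:
    """Dense genes x samples matrix keyed by unique string identifiers."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        frame = self.data
        if not all(np.issubdtype(dt, np.number) for dt in frame.dtypes):
            raise ValueError("matrix contains non-numeric columns")
        _check_finite(frame, type(self).__name__)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, samples: Sequence[str]):
        return type(self)(self.data.loc[:, list(samples)])


class ExpressionMatrix(_GeneBySampleMatrix):
    """log2-scale expression, genes x samples."""


class CopyNumberMatrix(_GeneBySampleMatrix):
    """Gene-level copy-number estimates (log-ratio scale, 0 = neutral)."""


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic coordinates and cytoband per gene (0-based, half-open)."""

    data: pd.DataFrame  # columns: chromosome, start, end, gene_id, band

    REQUIRED = ("chromosome", "start", "end", "gene_id", "band")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        _check_unique(pd.Index(self.data["gene_id"]), "annotated gene ids")
        bad = self.data["start"] >= self.data["end"]
        if bad.any():
            raise ValueError(
                f"start >= end for genes: {self.data.loc[bad, 'gene_id'].tolist()[:5]}"
            )

    def genes_in_region(self, region: str) -> pd.DataFrame:
        """Rows matching a cytoband (e.g. ``9p21.3``) or a chromosome label."""
        data = self.data
        if ("p" in region or "q" in region) and region[0].isdigit():
            hit = data[data["band"].astype(str) == region]
        else:
            hit = data[data["chromosome"].astype(str) == str(region)]
        return hit.sort_values(["start", "gene_id"]).reset_index(drop=True)


@dataclass(frozen=True)
class SurvivalTable:
    """Per-sample right-censored survival data plus clinical covariates.

    ``data`` is indexed by sample id and must contain a nonnegative ``time``
    column (days) and a boolean ``event`` column (True = death observed).
    Any additional columns are treated as covariates and may contain NA.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival table missing '{col}' column")
        _check_unique(self.data.index, "sample ids")
        time = pd.to_numeric(self.data["time"], errors="coerce")
        if time.isna().any():
            raise ValueError("non-numeric or missing survival times")
        if (time < 0).any():
            bad = self.data.index[time < 0].tolist()
            raise ValueError(f"negative survival time for samples: {bad[:5]}")
        event = self.data["event"]
        if event.isna().any():
            raise ValueError("event indicator missing for some samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=bool)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(samples)])


@dataclass(frozen=True)
class Module:
    """A marker-anchored gene set: ordered (gene, Pearson r) pairs."""

    name: str
    members: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple((g, float(r)) for g, r in self.members))
        genes = [g for g, _ in self.members]
        if len(set(genes)) != len(genes):
            raise ValueError(f"module {self.name}: duplicate member genes")
        rs = [r for _, r in self.members]
        if any(rs[i] < rs[i + 1] for i in range(len(rs) - 1)):
            raise ValueError(f"module {self.name}: correlations not non-increasing")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.members]

    @property
    def correlations(self) -> list[float]:
        return [r for _, r in self.members]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ModuleSet:
    """Named collection of modules, e.g. ``{"IRF7.mod": Module(...)}``."""

    modules: Mapping[str, Module]

    def __post_init__(self) -> None:
        for name, mod in self.modules.items():
            if name != mod.name:
                raise ValueError(f"module key {name!r} != module name {mod.name!r}")

    @property
    def names(self) -> list[str]:
        return list(self.modules)

    def __getitem__(self, name: str) -> Module:
        return self.modules[name]

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules.values())

    def gene_union(self) -> set[str]:
        out: set[str] = set()
        for mod in self:
            out.update(mod.genes)
        return out


@dataclass(frozen=True)
class Stratification:
    """Per-sample group labels for one module.

    ``group_order`` lists labels by ascending mean module score, so the last
    entry is always the highest-expressing group ("hi").
    """

    module: str
    labels: pd.Series  # sample_id -> label
    scheme: str  # "median_split" | "kgroups"
    group_order: tuple[str, ...]

    def __post_init__(self) -> None:
        _check_unique(self.labels.index, "stratified sample ids")
        seen = set(self.labels.unique())
        declared = set(self.group_order)
        if not seen <= declared:
            raise ValueError(f"labels {seen - declared} not in group order")

    def samples(self, label: str) -> list[str]:
        if label not in self.group_order:
            raise KeyError(f"unknown group {label!r} (have {self.group_order})")
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> dict[str, int]:
        return {g: int((self.labels == g).sum()) for g in self.group_order}
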