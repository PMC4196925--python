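"""Readers/writers for the tab-separated formats the pipeline touches.

The layouts mirror the public tumor-genomics conventions the analysis was
designed around: RSEM gene expression matrices (first column gene ids,
optionally ``SYMBOL|ENTREZ``), GISTIC ``all_data_by_genes`` gene-level
copy-number tables, attribute-rows-by-sample clinical merges, and BED-style
gene annotation. Every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    CopyNumberMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    Module,
    ModuleSet,
    Stratification,
    SurvivalTable,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_module_set",
    "write_module_set",
    "read_copy_number_matrix",
    "write_copy_number_matrix",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_stratification",
    "write_stratification",
    "DEFAULT_CLINICAL_ALIASES",
]

NA = "NA"  # on-disk encoding of missing clinical values


def _read_numeric_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix (first column = row ids) and fail loudly on any
    non-numeric cell, naming the offending row and column."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = raw.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.to_numpy().any():
        row, col = next(zip(*np.nonzero(bad.to_numpy())))
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[row, col]!r} at "
            f"row {raw.index[row]!r}, column {raw.columns[col]!r}"
        )
    return out


def _normalize_gene_ids(index: pd.Index, id_dialect: str) -> tuple[pd.Index, np.ndarray]:
    """Return normalized gene ids and a keep-mask ('?' symbols dropped)."""
    if id_dialect == "plain":
        ids = index.astype(str)
    elif id_dialect == "pipe_symbol_first":
        ids = pd.Index([str(g).split("|", 1)[0] for g in index])
    else:
        raise ValueError(f"unknown id dialect {id_dialect!r}")
    keep = np.asarray(ids != "?")
    return ids, keep


def read_expression_matrix(
    path: str | Path,
    id_dialect: str = "plain",
    raw_counts: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    Parameters
    ----------
    id_dialect
        ``plain`` keeps row ids verbatim; ``pipe_symbol_first`` splits
        ``SYMBOL|ID`` ids and keeps the symbol. Rows whose symbol is ``?``
        are dropped.
    raw_counts
        If True, values are linear-scale counts and are log2(x+1)
        transformed on load; otherwise they are assumed already log2.
    """
    frame = _read_numeric_table(path)
    ids, keep = _normalize_gene_ids(frame.index, id_dialect)
    frame = frame.loc[keep]
    frame.index = ids[keep]
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene id after normalization: {dup[:5]}")
    if raw_counts:
        frame = np.log2(frame + 1.0)
    frame.index.name = "gene_id"
    return ExpressionMatrix(frame)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.data.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

DEFAULT_CLINICAL_ALIASES: dict[str, str] = {
    "time": "time",
    "days_to_death": "time",
    "survival_days": "time",
    "event": "event",
    "vital_status": "event",
    "death_event": "event",
    "gender": "gender",
    "sex": "gender",
    "stage": "stage",
    "clark_stage": "stage",
    "pathologic_stage": "stage",
    "breslow_mm": "breslow_mm",
    "breslow": "breslow_mm",
    "breslow_depth_value": "breslow_mm",
    "ulceration": "ulceration",
    "melanoma_ulceration_indicator": "ulceration",
    "age_years": "age_years",
    "age": "age_years",
    "age_at_initial_pathologic_diagnosis": "age_years",
    "primary_site": "primary_site",
    "tumor_tissue_site": "primary_site",
}

_EVENT_CODES = {
    "1": True, "0": False,
    "true": True, "false": False,
    "dead": True, "deceased": True,
    "alive": False, "living": False,
}


def _parse_event(value) -> bool | None:
    if pd.isna(value):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().lower()
    if key in ("", NA.lower()):
        return None
    if key in _EVENT_CODES:
        return _EVENT_CODES[key]
    try:
        return bool(float(key))
    except ValueError:
        raise ValueError(f"unrecognized event indicator {value!r}")


def read_clinical_table(
    path: str | Path,
    orientation: str = "samples_as_rows",
    aliases: Mapping[str, str] | None = None,
) -> SurvivalTable:
    """Read a clinical TSV into a :class:`SurvivalTable`.

    ``orientation='samples_as_columns'`` accepts attribute-rows x sample-id
    column layouts (TCGA ``clin.merged.picked`` style). Recognized attribute
    names are mapped to canonical covariates via ``aliases`` (defaulting to
    :data:`DEFAULT_CLINICAL_ALIASES`); unrecognized attributes are kept
    verbatim. Samples missing time or event are dropped with a logged count.
    """
    aliases = dict(DEFAULT_CLINICAL_ALIASES if aliases is None else aliases)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=[NA])
    if orientation == "samples_as_columns":
        frame = frame.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    frame.columns = [aliases.get(str(c).strip().lower(), str(c).strip().lower())
                     for c in frame.columns]
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate clinical attribute after aliasing: {dup}")
    if "time" not in frame.columns or "event" not in frame.columns:
        raise ValueError(f"{path}: clinical table lacks survival time/event attributes")

    time = pd.to_numeric(frame["time"], errors="coerce")
    if (time.dropna() < 0).any():
        bad = frame.index[time < 0].tolist()
        raise ValueError(f"{path}: negative survival time for {bad[:5]}")
    event = frame["event"].map(_parse_event)
    usable = time.notna() & event.notna()
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.info("%s: dropped %d samples missing survival time or event", path, n_dropped)
    out = frame.loc[usable].copy()
    out["time"] = time[usable].astype(float)
    out["event"] = event[usable].astype(bool)
    for col in out.columns:
        if col in ("time", "event"):
            continue
        numeric = pd.to_numeric(out[col], errors="coerce")
        if numeric.notna().sum() == out[col].notna().sum():
            out[col] = numeric
    out.index.name = "sample_id"
    return SurvivalTable(out)


def write_clinical_table(table: SurvivalTable, path: str | Path) -> None:
    frame = table.data.copy()
    frame["event"] = frame["event"].astype(int)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t", na_rep=NA)


# ---------------------------------------------------------------------------
# Module sets: one column per module, genes in rank order
# ---------------------------------------------------------------------------


def write_module_set(modules: ModuleSet, path: str | Path) -> None:
    """One column per module; each cell ``GENE=r`` with full float precision.

    A module of 100 genes occupies a header line plus 100 data lines; ragged
    column lengths are padded with empty cells.
    """
    columns = {}
    for name in modules.names:
        mod = modules[name]
        columns[name] = [f"{g}={r!r}" for g, r in mod.members]
    depth = max((len(v) for v in columns.values()), default=0)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for i in range(depth):
            fh.write("\t".join(col[i] if i < len(col) else "" for col in columns.values()) + "\n")


def read_module_set(path: str | Path) -> ModuleSet:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    modules = {}
    for name in frame.columns:
        members = []
        for cell in frame[name]:
            if not cell:
                continue
            gene, _, r_text = cell.rpartition("=")
            if not gene:
                raise ValueError(f"{path}: malformed module cell {cell!r} in {name}")
            try:
                r = float(r_text)
            except ValueError:
                raise ValueError(f"{path}: malformed correlation {r_text!r} in {name}")
            members.append((gene, r))
        modules[name] = Module(name=name, members=tuple(members))
    return ModuleSet(modules)


# ---------------------------------------------------------------------------
# Copy number (GISTIC all_data_by_genes layout) and gene annotation (BED-like)
# ---------------------------------------------------------------------------

_GISTIC_LEAD = ["Gene Symbol", "Locus ID", "Cytoband"]


def write_copy_number_matrix(
    cnv: CopyNumberMatrix,
    path: str | Path,
    annotation: GeneAnnotation | None = None,
) -> None:
    """Write GISTIC ``all_data_by_genes`` layout: three leading annotation
    columns ("Gene Symbol", "Locus ID", "Cytoband"), then one column per
    sample."""
    frame = cnv.data.copy()
    bands = pd.Series(NA, index=frame.index)
    if annotation is not None:
        ann = annotation.data.set_index("gene_id")["band"]
        bands.update(ann.reindex(frame.index).dropna().astype(str))
    out = pd.DataFrame({
        "Gene Symbol": frame.index,
        "Locus ID": np.arange(1, len(frame) + 1),
        "Cytoband": bands.to_numpy(),
    })
    out = pd.concat([out.reset_index(drop=True), frame.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_copy_number_matrix(path: str | Path) -> CopyNumberMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={c: str for c in _GISTIC_LEAD})
    missing = [c for c in _GISTIC_LEAD if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: not a GISTIC all_data_by_genes table (missing {missing})")
    frame = frame.set_index("Gene Symbol").drop(columns=_GISTIC_LEAD[1:])
    frame = frame.apply(pd.to_numeric)
    frame.index.name = "gene_id"
    return CopyNumberMatrix(frame)


_ANNOT_COLS = ["chromosome", "start", "end", "gene_id", "band"]


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    """BED-style, 0-based half-open, headerless: chrom, start, end, gene, band."""
    annotation.data[_ANNOT_COLS].to_csv(path, sep="\t", index=False, header=False)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    frame = pd.read_csv(path, sep="\t", header=None, names=_ANNOT_COLS,
                        dtype={"chromosome": str, "gene_id": str, "band": str})
    frame["start"] = frame["start"].astype(int)
    frame["end"] = frame["end"].astype(int)
    return GeneAnnotation(frame)


# ---------------------------------------------------------------------------
# Stratifications: two-column TSV
# ---------------------------------------------------------------------------


def write_stratification(strat: Stratification, path: str | Path) -> None:
    frame = strat.labels.rename("label").to_frame()
    frame.index.name = "sample_id"
    header = f"# module={strat.module} scheme={strat.scheme} groups={','.join(strat.group_order)}\n"
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t")


def read_stratification(path: str | Path) -> Stratification:
    with open(path) as fh:
        meta_line = fh.readline()
        if not meta_line.startswith("#"):
            raise ValueError(f"{path}: missing stratification metadata header")
        meta = dict(tok.split("=", 1) for tok in meta_line[1:].split())
        frame = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
    return Stratification(
        module=meta["module"],
        labels=frame["label"],
        scheme=meta["scheme"],
        group_order=tuple(meta["groups"].split(",")),
    )
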