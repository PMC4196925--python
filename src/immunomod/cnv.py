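"""Per-gene copy-number comparison between stratification groups.

Every gene is tested with a two-sided Wilcoxon rank-sum (Mann-Whitney)
test between the high- and low-expression groups; "med" samples of a
three-group stratification are excluded. Deliberately NO multiple-testing
correction is applied: adjacent genes ride the same copy-number segments
and are anything but independent, so per-gene p-values are reported raw and
interpreted jointly along the locus profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CopyNumberMatrix, GeneAnnotation, Stratification

__all__ = ["CnvScanResult", "rank_sum_test", "compare_copy_number", "locus_profile"]

EXACT_MAX_GROUP = 8  # exact enumeration when both groups are this small


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p-value.

    Uses exact enumeration of the rank distribution when both groups have
    at most 8 untied observations, and the tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = len(a) <= EXACT_MAX_GROUP and len(b) <= EXACT_MAX_GROUP and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class CnvScanResult:
    """Per-gene group comparison, sorted by p ascending (ties: larger
    |median difference| first, then gene id)."""

    table: pd.DataFrame  # gene_id, p, median_a, median_b, abs_diff
    group_a: str
    group_b: str


def compare_copy_number(
    cnv: CopyNumberMatrix,
    strat: Stratification,
    group_a: str = "hi",
    group_b: str = "lo",
) -> CnvScanResult:
    """Wilcoxon rank-sum scan of every gene between two stratification groups."""
    for group in (group_a, group_b):
        if group not in strat.group_order:
            raise KeyError(f"group {group!r} not in stratification {strat.group_order}")
    cols = pd.Index(cnv.sample_ids)
    samples_a = [s for s in strat.samples(group_a) if s in cols]
    samples_b = [s for s in strat.samples(group_b) if s in cols]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"need >= 2 samples per group in the copy-number matrix "
            f"(got {len(samples_a)} {group_a!r}, {len(samples_b)} {group_b!r})"
        )
    mat_a = cnv.data[samples_a].to_numpy()
    mat_b = cnv.data[samples_b].to_numpy()
    med_a = np.median(mat_a, axis=1)
    med_b = np.median(mat_b, axis=1)
    pvals = np.array([rank_sum_test(mat_a[i], mat_b[i]) for i in range(len(mat_a))])
    table = pd.DataFrame({
        "gene_id": cnv.gene_ids,
        "p": pvals,
        "median_a": med_a,
        "median_b": med_b,
        "abs_diff": np.abs(med_a - med_b),
    })
    table = (
        table.sort_values(["p", "abs_diff", "gene_id"],
                          ascending=[True, False, True], kind="stable")
        .reset_index(drop=True)
    )
    return CnvScanResult(table=table, group_a=group_a, group_b=group_b)


def locus_profile(
    result: CnvScanResult,
    annotation: GeneAnnotation,
    region: str,
    landmarks: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Positional view of the scan over one cytoband or chromosome.

    Returns genes of ``region`` ordered by start coordinate with columns
    ``gene_id, chromosome, start, end, band, neg_log10_p, median_a,
    median_b, is_landmark``; caller-specified landmark genes (e.g. CDKN2A)
    are flagged for plotting.
    """
    region_genes = annotation.genes_in_region(region)
    if region_genes.empty:
        raise KeyError(f"no annotated genes in region {region!r}")
    merged = region_genes.merge(result.table, on="gene_id", how="inner")
    if merged.empty:
        raise KeyError(f"no genes of region {region!r} present in the scan result")
    merged["neg_log10_p"] = -np.log10(merged["p"])
    merged["is_landmark"] = merged["gene_id"].isin(landmarks)
    cols = ["gene_id", "chromosome", "start", "end", "band",
            "neg_log10_p", "p", "median_a", "median_b", "is_landmark"]
    return merged.sort_values(["start", "gene_id"]).reset_index(drop=True)[cols]
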