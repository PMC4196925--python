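"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator plants a single-factor co-expression model: each module has a
latent per-sample immune activity a_s ~ Normal(0, 1), and every member gene
(including the marker that anchors the module) reads

    expression = baseline_g + loading * a_s + Normal(0, noise_sd)

on the log2 scale, while non-member genes are independent noise around their
baselines. A configurable family of "linked" modules shares one latent
factor and draws its members from a common gene pool, reproducing the
overlapping, mutually correlated module families seen in tumor immune
infiltrates. Tumor survival follows a proportional-hazards law on the linked
factor (exponential event times with hazard ``baseline_hazard *
exp(beta * a_s)``, independent exponential censoring), and a focal
copy-number deletion is planted preferentially in low-activity tumors —
the ground truth every downstream stage is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CopyNumberMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    Module,
    ModuleSet,
    SurvivalTable,
)

__all__ = [
    "SimulationConfig",
    "ReferenceCohort",
    "TumorCohort",
    "generate_reference_cohort",
    "generate_tumor_cohort",
]

# Marker genes named after canonical immune cell-surface molecules and
# transcription factors; the first n_linked anchor the interferon-stimulated
# family that drives survival in the planted model.
MARKER_NAMES = (
    "IRF7", "STAT1", "STAT2", "MAF", "CD28", "KLRD1", "EOMES", "NKG7",
    "AFF1", "RBL2", "IL2RA", "TCF7", "CD2", "CD5", "CD6", "ICOS",
    "LCK", "CD160", "GZMB", "TBX21", "CD8A", "FOXP3", "GATA3", "PRF1",
)

# Genes of the planted focal-deletion locus, modeled on chromosome band
# 9p21.3 (CDKN2A/CDKN2B tumor suppressors flanked by the type I interferon
# gene cluster).
LOCUS_GENE_NAMES = (
    "MTAP", "CDKN2A", "CDKN2B", "CDKN2B-AS1", "DMRTA1", "IFNB1", "IFNW1",
    "IFNA21", "IFNA4", "IFNA7", "IFNA10", "IFNA16", "IFNA17", "IFNA14",
    "IFNA5", "IFNA6", "IFNA13", "IFNA2", "IFNA8", "IFNA1", "IFNE",
    "KLHL9", "ELAVL2", "MLLT3", "FOCAD", "PTPLAD2", "IFNK", "MOB3B",
    "EQTN", "TUSC1",
)

LANDMARK_GENES = ("IFNB1", "CDKN2A", "CDKN2B", "IFNE")


@dataclass
class SimulationConfig:
    """Knobs of the planted model.

    Defaults emulate the melanoma study conditions: a 134-sample immune
    reference set, a 291-tumor cohort, median overall survival near 3,100
    days (``baseline_hazard`` = ln2/3136 per day) with roughly 30 percent
    independent censoring, a protective log hazard ratio of -1 per activity
    unit, and a 30-gene focal deletion strongly enriched in low-activity
    tumors. The gene universe is kept at a few thousand genes so planted
    modules sit in a realistic sea of background transcripts while whole
    cohorts still generate in seconds.
    """

    n_ref_samples: int = 134
    n_tumor_samples: int = 291
    n_genes: int = 2500
    n_modules: int = 20
    module_size: int = 100
    loading: float = 2.0            # log2 units per activity unit
    noise_sd: float = 0.5           # log2 units
    beta: float = -1.0              # log hazard ratio per activity unit
    baseline_hazard: float = 2.21e-4  # per day; median survival ~3,136 days
    censor_rate: float = 9.5e-5     # per day; ~30% censored at these rates
    deletion_locus: tuple[str, str, int] = ("9", "9p21.3", 30)
    deletion_depth: float = -0.7    # copy-number log-ratio of deleted genes
    deletion_prob_low: float = 0.8
    deletion_prob_high: float = 0.05
    n_linked_modules: int = 3       # modules sharing the survival-linked factor
    linked_pool_extra: int = 30     # extra genes in the shared family pool
    rppa_loading: float = 0.8       # protein readout per activity unit
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules > 0 and self.module_size > self.n_genes // self.n_modules:
            raise ValueError("module_size must be <= n_genes / n_modules")
        for name in ("deletion_prob_low", "deletion_prob_high"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.n_linked_modules <= self.n_modules:
            raise ValueError("n_linked_modules must be between 0 and n_modules")
        n_locus = self.deletion_locus[2]
        if self._genes_required() + n_locus > self.n_genes:
            raise ValueError("n_genes too small for planted modules plus deletion locus")

    def _genes_required(self) -> int:
        n_linked = self.n_linked_modules
        pooled = self.module_size + self.linked_pool_extra if n_linked >= 2 else \
            n_linked * self.module_size
        return pooled + (self.n_modules - n_linked) * self.module_size


@dataclass(frozen=True)
class _PlantedStructure:
    gene_ids: list[str]
    markers: list[str]
    locus_genes: list[str]
    baselines: pd.Series                 # per-gene log2 baseline
    factor_of_gene: pd.Series            # gene -> factor index (-1 = background)
    module_members: dict[str, list[str]]  # module name -> planted member genes
    factor_of_module: dict[str, int]
    n_factors: int


@dataclass(frozen=True)
class ReferenceCohort:
    expression: ExpressionMatrix
    markers: list[str]
    modules: ModuleSet  # planted ground-truth membership


@dataclass(frozen=True)
class TumorCohort:
    expression: ExpressionMatrix
    survival: SurvivalTable
    copy_number: CopyNumberMatrix
    annotation: GeneAnnotation
    rppa: pd.Series  # per-sample protein readout tracking the linked factor
    truth: dict


def _names(prefix: str, base: Sequence[str], n: int) -> list[str]:
    out = list(base[:n])
    out += [f"{prefix}{i:04d}" for i in range(len(out), n)]
    return out


def _planted_structure(config: SimulationConfig) -> _PlantedStructure:
    """Gene universe, module membership and baselines; deterministic in the
    config seed and shared by the reference and tumor cohorts."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n_linked = config.n_linked_modules
    markers = _names("MARKER", MARKER_NAMES, config.n_modules)
    n_locus = config.deletion_locus[2]
    locus_genes = _names("LOC9P21_", LOCUS_GENE_NAMES, n_locus)

    factor_of_module = {
        f"{m}.mod": (0 if j < n_linked else j - max(n_linked - 1, 0))
        for j, m in enumerate(markers)
    }
    n_factors = max(factor_of_module.values(), default=-1) + 1

    gene_ids: list[str] = []
    factor_of_gene: dict[str, int] = {}
    module_members: dict[str, list[str]] = {}
    next_gene = 0

    def fresh(count: int) -> list[str]:
        nonlocal next_gene
        out = [f"GENE{next_gene + i:05d}" for i in range(count)]
        next_gene += count
        return out

    if n_linked >= 2:
        pool = markers[:n_linked] + fresh(
            config.module_size + config.linked_pool_extra - n_linked)
        gene_ids += pool
        for g in pool:
            factor_of_gene[g] = 0
        for marker in markers[:n_linked]:
            others = [g for g in pool if g != marker]
            picked = list(rng.choice(others, size=config.module_size - 1, replace=False))
            module_members[f"{marker}.mod"] = [marker] + sorted(picked)
    for j, marker in enumerate(markers):
        name = f"{marker}.mod"
        if name in module_members:
            continue
        members = [marker] + fresh(config.module_size - 1)
        gene_ids += members
        for g in members:
            factor_of_gene[g] = factor_of_module[name]
        module_members[name] = members

    gene_ids += locus_genes
    gene_ids += fresh(config.n_genes - len(gene_ids))
    baselines = pd.Series(rng.uniform(3.0, 9.0, size=len(gene_ids)), index=gene_ids)
    factor = pd.Series([factor_of_gene.get(g, -1) for g in gene_ids], index=gene_ids)
    return _PlantedStructure(
        gene_ids=gene_ids,
        markers=markers,
        locus_genes=locus_genes,
        baselines=baselines,
        factor_of_gene=factor,
        module_members=module_members,
        factor_of_module=factor_of_module,
        n_factors=n_factors,
    )


def _expression(
    structure: _PlantedStructure,
    config: SimulationConfig,
    sample_ids: list[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Expression matrix plus the (n_factors x n_samples) activity draws."""
    n_samples = len(sample_ids)
    activities = rng.standard_normal((max(structure.n_factors, 1), n_samples))
    noise = rng.normal(0.0, config.noise_sd,
                       size=(len(structure.gene_ids), n_samples))
    values = structure.baselines.to_numpy()[:, None] + noise
    factor = structure.factor_of_gene.to_numpy()
    loaded = factor >= 0
    values[loaded] += config.loading * activities[factor[loaded]]
    frame = pd.DataFrame(values, index=structure.gene_ids, columns=sample_ids)
    frame.index.name = "gene_id"
    return frame, activities


def _truth_modules(structure: _PlantedStructure, config: SimulationConfig) -> ModuleSet:
    # Theoretical marker-member correlation under the single-factor model.
    r = config.loading**2 / (config.loading**2 + config.noise_sd**2)
    modules = {}
    for name, members in structure.module_members.items():
        marker = members[0]
        pairs = [(marker, 1.0)] + [(g, r) for g in members[1:]]
        modules[name] = Module(name=name, members=tuple(pairs))
    return ModuleSet(modules)


def generate_reference_cohort(config: SimulationConfig) -> ReferenceCohort:
    """Reference immune expression cohort with planted module structure."""
    structure = _planted_structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    samples = [f"REF{i:03d}" for i in range(1, config.n_ref_samples + 1)]
    frame, _ = _expression(structure, config, samples, rng)
    return ReferenceCohort(
        expression=ExpressionMatrix(frame),
        markers=list(structure.markers),
        modules=_truth_modules(structure, config),
    )


def _clinical_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariates with marginal frequencies typical of a metastatic
    melanoma cohort; independent of the planted survival signal."""
    stage_p = np.array([3, 53, 78, 99, 12], dtype=float)
    site_p = np.array([37, 50, 157, 31], dtype=float)
    return pd.DataFrame({
        "gender": rng.choice(["M", "F"], size=n, p=[170 / 277, 107 / 277]),
        "stage": rng.choice(["0", "I", "II", "III", "IV"], size=n, p=stage_p / stage_p.sum()),
        "breslow_mm": np.round(rng.lognormal(np.log(2.5), 0.8, size=n), 2),
        "ulceration": rng.choice(["yes", "no"], size=n, p=[90 / 188, 98 / 188]),
        "age_years": np.round(np.clip(rng.normal(56, 16, size=n), 18, 95), 1),
        "primary_site": rng.choice(
            ["primary_tumor", "regional_cutaneous", "regional_lymph_node",
             "distant_metastasis"],
            size=n, p=site_p / site_p.sum()),
    })


def _annotation(structure: _PlantedStructure, config: SimulationConfig) -> GeneAnnotation:
    chrom, band, _ = config.deletion_locus
    locus = set(structure.locus_genes)
    rows = []
    other_chroms = [c for c in map(str, range(1, 23)) if c != chrom]
    locus_idx = other_idx = 0
    for gene in structure.gene_ids:
        if gene in locus:
            start = 21_000_000 + locus_idx * 50_000
            rows.append((chrom, start, start + 20_000, gene, band))
            locus_idx += 1
        else:
            c = other_chroms[other_idx % len(other_chroms)]
            start = 1_000_000 + (other_idx // len(other_chroms)) * 100_000
            rows.append((c, start, start + 20_000, gene, f"{c}q11.1"))
            other_idx += 1
    frame = pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene_id", "band"])
    return GeneAnnotation(frame)


def generate_tumor_cohort(config: SimulationConfig) -> TumorCohort:
    """Tumor cohort: expression, survival, clinical covariates, gene-level
    copy number, annotation, a protein (RPPA-like) readout, and the planted
    truth record."""
    structure = _planted_structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    samples = [f"TUMOR{i:03d}" for i in range(1, config.n_tumor_samples + 1)]
    frame, activities = _expression(structure, config, samples, rng)
    activity = activities[0]  # the survival-linked factor

    hazard = config.baseline_hazard * np.exp(config.beta * activity)
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor_time = rng.exponential(1.0 / config.censor_rate, size=len(samples))
    else:
        censor_time = np.full(len(samples), np.inf)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    clinical = _clinical_covariates(len(samples), rng)
    clinical.index = pd.Index(samples, name="sample_id")
    clinical.insert(0, "event", event)
    clinical.insert(0, "time", time)
    survival = SurvivalTable(clinical)

    # Copy number: background noise everywhere; planted locus genes shifted by
    # deletion_depth in carrier tumors, with carriers drawn preferentially
    # from the low-activity half of the cohort.
    cnv_values = rng.normal(0.0, 0.1, size=(len(structure.gene_ids), len(samples)))
    low_half = activity < np.median(activity)
    p_del = np.where(low_half, config.deletion_prob_low, config.deletion_prob_high)
    carriers = rng.random(len(samples)) < p_del
    locus_rows = [structure.gene_ids.index(g) for g in structure.locus_genes]
    cnv_values[np.ix_(locus_rows, np.nonzero(carriers)[0])] += config.deletion_depth
    cnv_frame = pd.DataFrame(cnv_values, index=structure.gene_ids, columns=samples)
    cnv_frame.index.name = "gene_id"

    rppa = pd.Series(
        config.rppa_loading * activity + rng.normal(0.0, 0.5, size=len(samples)),
        index=samples, name="LCK",
    )

    truth = {
        "beta": config.beta,
        "activity": pd.Series(activity, index=samples),
        "activities": pd.DataFrame(
            activities.T, index=samples,
            columns=[f"factor{k}" for k in range(activities.shape[0])]),
        "deletion_carriers": [s for s, c in zip(samples, carriers) if c],
        "locus_genes": list(structure.locus_genes),
        "linked_modules": [
            name for name, f in structure.factor_of_module.items() if f == 0
        ][: max(config.n_linked_modules, 0)] if config.n_linked_modules else [],
        "module_members": {k: list(v) for k, v in structure.module_members.items()},
        "config": asdict(config),
    }
    return TumorCohort(
        expression=ExpressionMatrix(frame),
        survival=survival,
        copy_number=CopyNumberMatrix(cnv_frame),
        annotation=_annotation(structure, config),
        rppa=rppa,
        truth=truth,
    )
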