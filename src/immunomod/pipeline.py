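"""End-to-end orchestration: simulate -> build modules -> score -> screen ->
stratify -> overlap -> copy-number scan -> covariate association.

A run is driven by one :class:`RunConfig` (YAML-loadable). Every stage
writes its outputs under the run directory and appends a manifest entry
with parameters, input/output SHA-256 hashes and the stage seed, so a rerun
with an identical config reproduces byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .covariates import compare_continuous, contingency_test, dichotomize_at_median
from .cnv import compare_copy_number, locus_profile
from .datatypes import ModuleSet
from .modules import build_module_set
from .overlap import cluster_module_groups, overlap_matrix
from .scoring import InsufficientGenesError, cluster_stratify, median_split, module_score
from .simulate import LANDMARK_GENES, SimulationConfig, generate_reference_cohort, generate_tumor_cohort
from .survival import estimate_fdr, permutation_calibration, screen_modules

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "build_modules", "score", "screen",
          "stratify", "overlap", "cnv_scan", "associate")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    outdir: str
    seed: int | None = None
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    module_size: int = 100
    min_genes: int = 10
    alpha: float = 0.01
    n_permutations: int = 10000
    k_groups: int = 3
    cluster_linkage: str = "average"    # sample stratification
    overlap_linkage: str = "complete"   # module-family clustering
    overlap_denominator: str = "min"
    cut_height: float = 0.7
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.outdir:
            raise ValueError("config requires an output directory")
        if self.n_permutations > 0 and self.seed is None:
            raise ValueError("config requires a seed when permutations are requested")
        if self.seed is None:
            raise ValueError("config requires a seed (the simulate stage is stochastic)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.overlap_denominator not in ("min", "union"):
            raise ValueError("overlap_denominator must be 'min' or 'union'")
        if self.k_groups < 2:
            raise ValueError("k_groups must be >= 2")


def _stage_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.entries: list[dict] = []

    def record(self, stage: str, params: dict, inputs: list[Path],
               outputs: list[Path], seed: int | None = None) -> None:
        self.entries.append({
            "stage": stage,
            "seed": seed,
            "params": params,
            "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        })

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.entries, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


def run_pipeline(config: RunConfig) -> list[dict]:
    """Run all stages on a simulated cohort; returns the manifest entries."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = _Manifest(outdir)

    # --- simulate -----------------------------------------------------------
    sim_seed = _stage_seed(config.seed, 0)
    sim_config = SimulationConfig(**{"seed": sim_seed, **config.simulation})
    reference = generate_reference_cohort(sim_config)
    tumor = generate_tumor_cohort(sim_config)

    paths = {
        "ref_expr": outdir / "reference_expression.tsv",
        "markers": outdir / "markers.txt",
        "tumor_expr": outdir / "tumor_expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "cnv": outdir / "copy_number.tsv",
        "annot": outdir / "gene_annotation.bed",
        "rppa": outdir / "rppa_lck.tsv",
        "truth": outdir / "truth.json",
    }
    io.write_expression_matrix(reference.expression, paths["ref_expr"])
    paths["markers"].write_text("\n".join(reference.markers) + "\n")
    io.write_expression_matrix(tumor.expression, paths["tumor_expr"])
    io.write_clinical_table(tumor.survival, paths["clinical"])
    io.write_copy_number_matrix(tumor.copy_number, paths["cnv"], tumor.annotation)
    io.write_gene_annotation(tumor.annotation, paths["annot"])
    tumor.rppa.rename("LCK").to_frame().rename_axis("sample_id").to_csv(
        paths["rppa"], sep="\t")
    truth_json = {
        "beta": tumor.truth["beta"],
        "linked_modules": tumor.truth["linked_modules"],
        "deletion_carriers": tumor.truth["deletion_carriers"],
        "locus_genes": tumor.truth["locus_genes"],
        "activity": {s: float(v) for s, v in tumor.truth["activity"].items()},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.record("simulate", {"config": asdict(sim_config)}, [],
                    list(paths.values()), seed=sim_seed)

    # --- build modules ------------------------------------------------------
    build = build_module_set(reference.expression, reference.markers,
                             size=config.module_size)
    modules = build.module_set
    modules_path = outdir / "modules.tsv"
    io.write_module_set(modules, modules_path)
    summary_path = outdir / "module_summary.json"
    with open(summary_path, "w") as fh:
        json.dump({**asdict(build.summary), "failed_markers": build.failures},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.record("build_modules", {"size": config.module_size},
                    [paths["ref_expr"], paths["markers"]],
                    [modules_path, summary_path])

    # --- score --------------------------------------------------------------
    score_rows = {}
    for name in modules.names:
        try:
            score_rows[name] = module_score(tumor.expression, modules[name],
                                            min_genes=config.min_genes).scores
        except InsufficientGenesError as exc:
            log.warning("score: %s", exc)
    scores_frame = pd.DataFrame(score_rows).T
    scores_frame.index.name = "module"
    scores_path = outdir / "module_scores.tsv"
    scores_frame.to_csv(scores_path, sep="\t")
    manifest.record("score", {"min_genes": config.min_genes},
                    [paths["tumor_expr"], modules_path], [scores_path])

    # --- screen (+ permutation calibration and screen-level FDR) ------------
    screen = screen_modules(tumor.expression, modules, tumor.survival,
                            min_genes=config.min_genes)
    screen_path = outdir / "screen.tsv"
    screen.table.to_csv(screen_path, sep="\t", index=False)
    perm_seed = _stage_seed(config.seed, 3)
    calibration = permutation_calibration(
        tumor.survival, n_perm=config.n_permutations,
        alpha=config.alpha, seed=perm_seed)
    n_significant = int((screen.table["p"] < config.alpha).sum())
    expected_false = calibration.proportion * len(screen.table)
    fdr = estimate_fdr(expected_false, n_significant) if n_significant else None
    calib_path = outdir / "calibration.json"
    with open(calib_path, "w") as fh:
        json.dump({
            "n_permutations": calibration.n_permutations,
            "alpha": calibration.alpha,
            "n_exceed": calibration.n_exceed,
            "proportion": calibration.proportion,
            "n_modules_tested": len(screen.table),
            "n_significant": n_significant,
            "expected_false": expected_false,
            "fdr": None if fdr is None else fdr.fraction,
            "fdr_percent": None if fdr is None else fdr.percent_label,
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.record("screen",
                    {"alpha": config.alpha, "n_permutations": config.n_permutations},
                    [scores_path, paths["clinical"]],
                    [screen_path, calib_path], seed=perm_seed)

    # --- stratify the top module (median split and k-group clustering) ------
    top_module = modules[screen.table.iloc[0]["module"]]
    top_scores = module_score(tumor.expression, top_module, min_genes=config.min_genes)
    median_strat = median_split(top_scores)
    kgroup_strat = cluster_stratify(tumor.expression, top_module,
                                    k=config.k_groups,
                                    linkage=config.cluster_linkage,
                                    min_genes=config.min_genes)
    median_path = outdir / "stratification_median.tsv"
    kgroup_path = outdir / "stratification_kgroups.tsv"
    io.write_stratification(median_strat, median_path)
    io.write_stratification(kgroup_strat, kgroup_path)
    manifest.record("stratify",
                    {"module": top_module.name, "k": config.k_groups,
                     "linkage": config.cluster_linkage},
                    [paths["tumor_expr"], modules_path, screen_path],
                    [median_path, kgroup_path])

    # --- overlap clustering of significant modules --------------------------
    significant = screen.table.loc[screen.table["p"] < config.alpha, "module"].tolist()
    if len(significant) < 2:
        log.warning("overlap: %d modules below alpha; using top 5 by p", len(significant))
        significant = screen.table["module"].head(5).tolist()
    om = overlap_matrix(modules, subset=significant,
                        denominator=config.overlap_denominator)
    groups = cluster_module_groups(om, linkage=config.overlap_linkage,
                                   cut_height=config.cut_height,
                                   screen_table=screen.table)
    overlap_path = outdir / "overlap_matrix.tsv"
    om.data.rename_axis("module").to_csv(overlap_path, sep="\t")
    groups_path = outdir / "module_groups.json"
    with open(groups_path, "w") as fh:
        json.dump({"assignments": groups.assignments,
                   "groups": [list(g) for g in groups.groups]},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.record("overlap",
                    {"denominator": config.overlap_denominator,
                     "linkage": config.overlap_linkage,
                     "cut_height": config.cut_height},
                    [modules_path, screen_path], [overlap_path, groups_path])

    # --- copy-number scan (hi vs lo; med excluded by construction) ----------
    scan = compare_copy_number(tumor.copy_number, kgroup_strat,
                               group_a="hi", group_b="lo")
    scan_path = outdir / "cnv_scan.tsv"
    scan.table.to_csv(scan_path, sep="\t", index=False)
    band = sim_config.deletion_locus[1]
    profile = locus_profile(scan, tumor.annotation, band, landmarks=LANDMARK_GENES)
    profile_path = outdir / "locus_profile.tsv"
    profile.to_csv(profile_path, sep="\t", index=False)
    manifest.record("cnv_scan", {"region": band, "groups": ["hi", "lo"]},
                    [paths["cnv"], kgroup_path, paths["annot"]],
                    [scan_path, profile_path])

    # --- covariate association ----------------------------------------------
    clinical = tumor.survival.data
    assoc_rows = []
    for cov in ("gender", "stage", "ulceration", "primary_site"):
        res = contingency_test(kgroup_strat, clinical[cov])
        assoc_rows.append({"covariate": cov, "test": "chi_square",
                           "statistic": res.chi_square, "df": res.df, "p": res.p})
    for cov in ("age_years", "breslow_mm"):
        res = contingency_test(kgroup_strat, dichotomize_at_median(clinical[cov]))
        assoc_rows.append({"covariate": f"{cov}_median_split", "test": "chi_square",
                           "statistic": res.chi_square, "df": res.df, "p": res.p})
    rppa_res = compare_continuous(kgroup_strat, tumor.rppa)
    assoc_rows.append({"covariate": "LCK_rppa", "test": "rank_sum",
                       "statistic": float("nan"), "df": 0, "p": rppa_res.p})
    assoc_path = outdir / "associations.tsv"
    pd.DataFrame(assoc_rows).to_csv(assoc_path, sep="\t", index=False)
    manifest.record("associate", {"groups": ["hi", "lo"]},
                    [kgroup_path, paths["clinical"], paths["rppa"]], [assoc_path])

    manifest.write()
    return manifest.entries
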