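"""End-to-end runner: simulate -> preprocess -> network -> module statistics
-> differential expression & classifier -> CFG prioritization.

Every stage persists its artifacts under the output directory and reads only
artifacts of earlier stages; a machine-readable run report captures configs,
seeds, stage timings and the headline outputs. A single global seed derives
per-stage seeds by fixed offsets so stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .cfg import CFGConfig, cfg_module_enrichment, score_table
from .classify import exclude_confounded, moderated_ttest, permutation_pvalue, rfe_loocv
from .modstats import BayesAnovaConfig, bayes_anova, correlate_traits
from .network import (
    NetworkConfig,
    detect_modules,
    merge_close_modules,
    module_eigengenes,
    module_membership,
    signed_adjacency,
    scale_free_fit,
    topological_overlap,
)
from .preprocess import detect_outliers, filter_low_expression, voom_normalize
from .simulate import CohortConfig, generate_cohort, generate_evidence_db

log = logging.getLogger(__name__)

STAGE_SEED_OFFSETS = {"simulate": 11, "classify": 23}

CONFOUNDER_TRAITS = ("nicotine_use", "cannabis_use", "alcohol_use")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    anova: BayesAnovaConfig = field(default_factory=BayesAnovaConfig)
    cfg: CFGConfig = field(default_factory=CFGConfig)
    min_reads: int = 20
    min_subjects: int = 10
    de_alpha: float = 0.01
    confounder_alpha: float = 0.05
    map_module_alpha: float = 0.05
    n_permutations: int = 0  # label permutations for classifier p-values
    run_classifier: bool = True
    seed: int = 0
    outdir: str | None = None


def _stage_seed(config: RunConfig, stage: str) -> int:
    return int((config.seed + STAGE_SEED_OFFSETS.get(stage, 0)) % (2**31 - 1))


def map_associated_modules(anova_table: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Modules whose eigengene differs for MAP in either pairwise contrast."""
    cols = [
        c
        for c in anova_table.columns
        if c.startswith("p_") and "MAP" in c and not c.endswith("_corrected")
    ]
    hit = (anova_table[cols] < alpha).any(axis=1)
    return [str(m) for m in anova_table.index[hit]]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and persists) the run report."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "package": "bloodmark",
        "seed": config.seed,
        "configs": {
            "cohort": _asdict(config.cohort),
            "network": _asdict(config.network),
            "anova": _asdict(config.anova),
            "cfg": _asdict(config.cfg),
        },
        "stages": {},
    }
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    # -- simulate -----------------------------------------------------------
    stage("simulate")
    cohort_cfg = dataclasses.replace(config.cohort, seed=_stage_seed(config, "simulate"))
    counts, phenotypes, truth = generate_cohort(cohort_cfg)
    evidence = generate_evidence_db(truth, cohort_cfg)
    done("simulate")
    if outdir:
        bio.write_counts(counts, outdir / "counts.tsv")
        bio.write_table(phenotypes, outdir / "phenotypes.tsv", index=False)
        bio.write_table(evidence, outdir / "evidence.tsv", index=False)
        truth.to_json(outdir / "truth.json")

    # -- preprocess ---------------------------------------------------------
    stage("preprocess")
    filtered = filter_low_expression(counts, config.min_reads, config.min_subjects)
    expr = voom_normalize(filtered)
    outliers = detect_outliers(expr)
    done("preprocess")
    report["stages"]["preprocess"] = {
        "filter": filtered.attrs["filter_report"],
        "outliers": outliers,
    }
    if outdir:
        bio.write_table(expr.values, outdir / "expression.tsv")
        bio.write_table(expr.weights, outdir / "weights.tsv")
        bio.write_json(report["stages"]["preprocess"], outdir / "qc_report.json")

    # -- network ------------------------------------------------------------
    stage("network")
    adj = signed_adjacency(expr.values, config.network)
    sf_r2 = scale_free_fit(adj)
    _, diss = topological_overlap(adj)
    pre_partition = detect_modules(diss, config.network)
    partition = merge_close_modules(expr.values, pre_partition, config.network)
    eigengenes = module_eigengenes(expr.values, partition)
    kme, hubs = module_membership(expr.values, eigengenes, partition)
    done("network")
    n_modules = int((partition.unique() != 0).sum())
    report["stages"]["network"] = {
        "scale_free_r2": None if np.isnan(sf_r2) else float(sf_r2),
        "n_modules": n_modules,
        "n_grey_genes": int((partition == 0).sum()),
        "hub_genes": hubs,
    }
    if outdir:
        partition.rename("module").to_frame().to_csv(outdir / "partition.tsv", sep="\t")
        bio.write_table(eigengenes.values, outdir / "eigengenes.tsv")
        bio.write_table(kme, outdir / "kme.tsv")

    # -- module statistics --------------------------------------------------
    stage("modstats")
    groups = phenotypes.loc[list(expr.values.columns), "group"].to_numpy()
    me_anova = bayes_anova(eigengenes.values, groups, config.anova)
    map_modules = map_associated_modules(me_anova, config.map_module_alpha)
    trait_cor = correlate_traits(eigengenes.values, phenotypes)
    volume_cols = [c for c in phenotypes.columns if c.endswith(("_L", "_R"))] + [
        c for c in phenotypes.columns if c.startswith("CC_")
    ]
    volumes = phenotypes.loc[list(expr.values.columns), volume_cols].T.astype(float)
    volume_anova = bayes_anova(volumes, groups, config.anova)
    done("modstats")
    report["stages"]["modstats"] = {"map_modules": map_modules}
    if outdir:
        bio.write_table(me_anova, outdir / "me_group_tests.tsv")
        bio.write_table(volume_anova, outdir / "volume_group_tests.tsv")
        bio.write_table(trait_cor, outdir / "module_trait_correlations.tsv", index=False)

    # -- differential expression & classifier -------------------------------
    stage("classify")
    comparisons = {
        "p_map_vs_ctrl": ("MAP", "control"),
        "p_map_vs_ma": ("MAP", "MA"),
        "p_ctrl_vs_ma": ("control", "MA"),
    }
    de_tables = {}
    for key, (a, b) in comparisons.items():
        de = moderated_ttest(expr.values, groups, a, b)
        de_tables[key] = exclude_confounded(
            de, partition, trait_cor, CONFOUNDER_TRAITS, config.confounder_alpha
        )
    candidate_pool = sorted(
        set().union(
            *[set(t.index[t["p"] < config.de_alpha]) for t in de_tables.values()]
        )
    )
    classifier_report = {}
    if config.run_classifier and len(candidate_pool) >= 2:
        meth_labels = np.where(groups == "control", "control", "METH")
        models = {
            "controls_vs_meth": (meth_labels, np.ones(len(groups), dtype=bool)),
            "ma_vs_map": (groups, groups != "control"),
        }
        rng_seed = _stage_seed(config, "classify")
        for label, (lab, mask) in models.items():
            sub_vals = expr.values.loc[:, expr.values.columns[mask]]
            result, panel = rfe_loocv(
                sub_vals, lab[mask], candidate_pool, model_label=label
            )
            entry = {
                "best_size": panel.size,
                "best_accuracy": result.best_accuracy[panel.classifier],
                "best_accuracy_by_classifier": result.best_accuracy,
                "panel_genes": panel.genes,
            }
            if config.n_permutations > 0:
                entry["permutation_p"] = permutation_pvalue(
                    sub_vals,
                    lab[mask],
                    candidate_pool,
                    n_perm=config.n_permutations,
                    seed=rng_seed,
                )
            classifier_report[label] = entry
            if outdir:
                bio.write_table(result.accuracy, outdir / f"accuracy_{label}.tsv")
                panel_df = pd.DataFrame(
                    {
                        "gene": panel.genes,
                        "cv_support_pct": panel.cv_support.reindex(panel.genes).to_numpy(),
                        "module": partition.reindex(panel.genes).to_numpy(),
                    }
                )
                bio.write_table(panel_df, outdir / f"panel_{label}.tsv", index=False)
    done("classify")
    report["stages"]["classify"] = {
        "n_candidates": len(candidate_pool),
        "models": classifier_report,
    }
    if outdir:
        for key, t in de_tables.items():
            bio.write_table(t, outdir / f"de_{key}.tsv")

    # -- CFG scoring --------------------------------------------------------
    stage("cfg")
    pvals = pd.DataFrame({k: t["p"] for k, t in de_tables.items()})
    pvals = pvals.dropna()
    map_module_genes = set()
    for m in map_modules:
        label = int(str(m).lstrip("M"))
        map_module_genes |= set(partition.index[partition == label])
    cfg_table = score_table(pvals, map_module_genes, evidence, config.cfg)
    evidence_genes = set(evidence["gene"]) if len(evidence) else set()
    background = int(expr.values.shape[0])
    enrich_rows = []
    for m in sorted(x for x in partition.unique() if x != 0):
        mg = partition.index[partition == m]
        overlap, p = cfg_module_enrichment(mg, evidence_genes, background)
        enrich_rows.append({"module": f"M{m}", "overlap": overlap, "p": p})
    enrichment = pd.DataFrame(enrich_rows)
    done("cfg")
    top = cfg_table.head(10)
    report["stages"]["cfg"] = {
        "n_scored": int(len(cfg_table)),
        "n_prioritized": int(cfg_table["prioritized"].sum()) if len(cfg_table) else 0,
        "top_genes": top["gene"].tolist() if len(top) else [],
        "top_scores": [float(x) for x in top["total"]] if len(top) else [],
    }
    if outdir:
        bio.write_table(cfg_table, outdir / "cfg_scores.tsv", index=False)
        bio.write_table(enrichment, outdir / "cfg_module_enrichment.tsv", index=False)

    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    if outdir:
        bio.write_json(report, outdir / "report.json")
    return report


REPORT_REQUIRED_KEYS = {"package", "seed", "configs", "stages", "timings_s"}
REPORT_STAGE_KEYS = {"preprocess", "network", "modstats", "classify", "cfg"}


def validate_report(report: dict) -> None:
    """Raise if the run report is structurally incomplete."""
    missing = REPORT_REQUIRED_KEYS - set(report)
    if missing:
        raise ValueError(f"report missing keys: {sorted(missing)}")
    missing_stages = REPORT_STAGE_KEYS - set(report["stages"])
    if missing_stages:
        raise ValueError(f"report missing stages: {sorted(missing_stages)}")


def headline(report: dict) -> dict:
    """Deterministic subset of a report (excludes timings)."""
    out = json.loads(json.dumps({k: v for k, v in report.items() if k != "timings_s"}))
    return out


def _asdict(obj) -> dict:
    d = dataclasses.asdict(obj)

    def clean(v):
        if isinstance(v, dict):
            return {str(k): clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    return clean(d)
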