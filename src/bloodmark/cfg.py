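"""Convergent functional genomics (CFG) biomarker prioritization.

Two-step evidence scoring. Internal lines of evidence come from the three
group-wise differential-expression comparisons: per comparison, 1 point for
p < 0.001, 0.5 for p in [0.001, 0.01), 0.2 for p in [0.01, 0.05) (boundaries
fall in the lower-scoring bin), plus a 0.5 bonus when both MAP comparisons
pass p < 0.01 and a 0.5 bonus for membership in a MAP-associated module --
internal maximum 4, minimum 0.2 for an included gene (a gene is included
only if at least one comparison has p < 0.05). External lines of evidence
come from a curated literature database: one line per distinct
(evidence_type, disease) combination, capped at five lines, with one extra
point (outside the cap) when a peripheral-blood psychosis line exists.
Maximum total score 10 = 4 + 5 + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modstats import hypergeometric_enrichment

EVIDENCE_TYPES = ("blood_expression", "brain_expression", "genetic")
DISEASES = ("psychosis", "SCZ", "depression_stress", "neurocognitive")


@dataclass
class CFGConfig:
    #: p-value upper bounds and the points awarded for falling below them
    p_thresholds: tuple[tuple[float, float], ...] = ((0.001, 1.0), (0.01, 0.5), (0.05, 0.2))
    both_map_bonus: float = 0.5
    both_map_p: float = 0.01
    module_bonus: float = 0.5
    external_cap: int = 5
    blood_psychosis_bonus: float = 1.0
    priority_threshold: float = 3.0
    inclusion_p: float = 0.05


def _points(p: float, config: CFGConfig) -> float:
    for bound, pts in config.p_thresholds:
        if p < bound:
            return pts
    return 0.0


def internal_score(
    p_map_vs_ctrl: float,
    p_map_vs_ma: float,
    p_ctrl_vs_ma: float,
    in_both_map_comparisons: bool | None = None,
    in_map_module: bool = False,
    config: CFGConfig | None = None,
) -> float | None:
    """Internal line-of-evidence score, or None for an excluded gene.

    ``in_both_map_comparisons`` defaults to the p-value-derived condition
    (both MAP comparisons below 0.01); pass a boolean to override.
    """
    config = config or CFGConfig()
    ps = (p_map_vs_ctrl, p_map_vs_ma, p_ctrl_vs_ma)
    if min(ps) >= config.inclusion_p:
        return None
    score = sum(_points(p, config) for p in ps)
    if in_both_map_comparisons is None:
        in_both_map_comparisons = (
            p_map_vs_ctrl < config.both_map_p and p_map_vs_ma < config.both_map_p
        )
    if in_both_map_comparisons:
        score += config.both_map_bonus
    if in_map_module:
        score += config.module_bonus
    return score


def _clean_evidence(db: pd.DataFrame) -> pd.DataFrame:
    """Drop METH-component records and reject malformed ones with a report."""
    db = db.copy()
    if "meth_study" in db.columns:
        db = db.loc[~db["meth_study"].astype(bool)]
    ok = db["evidence_type"].isin(EVIDENCE_TYPES) & db["disease"].isin(DISEASES)
    rejected = db.loc[~ok]
    db = db.loc[ok]
    subset = [c for c in ("gene", "evidence_type", "disease", "source_id") if c in db.columns]
    db = db.drop_duplicates(subset=subset)
    db.attrs["n_rejected"] = int(len(rejected))
    return db


def external_score(
    gene: str, db: pd.DataFrame, config: CFGConfig | None = None
) -> tuple[float, list[tuple[str, str]], float]:
    """(capped external score, counted lines, blood-psychosis bonus) for one gene.

    One line of evidence = one distinct (evidence_type, disease) combination
    with at least one record, worth 1 point, at most ``external_cap`` lines.
    The blood-psychosis weighting sits outside the cap.
    """
    config = config or CFGConfig()
    if len(db) == 0:
        return 0.0, [], 0.0
    db = _clean_evidence(db)
    recs = db.loc[db["gene"] == gene]
    lines = sorted(set(zip(recs["evidence_type"], recs["disease"])))
    score = float(min(len(lines), config.external_cap))
    bonus = (
        config.blood_psychosis_bonus
        if ("blood_expression", "psychosis") in lines
        else 0.0
    )
    return score, lines, bonus


def cfg_total(
    internal: float, external: float, bonus: float, config: CFGConfig | None = None
) -> tuple[float, bool]:
    """Total CFG score and the prioritized flag at the configured threshold."""
    config = config or CFGConfig()
    total = internal + external + bonus
    return total, bool(total >= config.priority_threshold)


def score_table(
    de_pvalues: pd.DataFrame,
    map_module_genes,
    evidence_db: pd.DataFrame,
    config: CFGConfig | None = None,
) -> pd.DataFrame:
    """Score every included gene and rank the table.

    ``de_pvalues`` must have columns ``p_map_vs_ctrl``, ``p_map_vs_ma``,
    ``p_ctrl_vs_ma`` indexed by gene. Genes with all three p >= 0.05 are
    excluded. Sorted by total descending, ties by internal score then gene
    id.
    """
    config = config or CFGConfig()
    map_module_genes = set(map_module_genes)
    db = _clean_evidence(evidence_db) if len(evidence_db) else evidence_db
    rows = []
    for gene, row in de_pvalues.iterrows():
        p1, p2, p3 = row["p_map_vs_ctrl"], row["p_map_vs_ma"], row["p_ctrl_vs_ma"]
        internal = internal_score(
            p1, p2, p3, in_map_module=gene in map_module_genes, config=config
        )
        if internal is None:
            continue
        ext, lines, bonus = external_score(gene, db, config=config)
        total, prioritized = cfg_total(internal, ext, bonus, config=config)
        rows.append(
            {
                "gene": gene,
                "p_map_vs_ctrl": p1,
                "p_map_vs_ma": p2,
                "p_ctrl_vs_ma": p3,
                "internal": internal,
                "external_lines": ";".join(f"{t}|{d}" for t, d in lines),
                "external": ext,
                "blood_psychosis_bonus": bonus,
                "total": total,
                "prioritized": prioritized,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "p_map_vs_ctrl",
            "p_map_vs_ma",
            "p_ctrl_vs_ma",
            "internal",
            "external_lines",
            "external",
            "blood_psychosis_bonus",
            "total",
            "prioritized",
        ],
    )
    if len(out):
        out = out.sort_values(
            ["total", "internal", "gene"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return out


def cfg_module_enrichment(
    module_genes, evidence_genes, background_size: int
) -> tuple[int, float]:
    """Overlap and one-tailed hypergeometric p of CFG-evidence genes in a module."""
    p, overlap = hypergeometric_enrichment(
        module_genes, evidence_genes, background_size, min_overlap=0
    )
    return overlap, p


def gene_disease_edges(evidence_db: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Long-form gene-disease edge list for network visualization."""
    db = _clean_evidence(evidence_db) if len(evidence_db) else evidence_db
    if genes is not None:
        db = db.loc[db["gene"].isin(set(genes))]
    return (
        db[["gene", "disease", "evidence_type"]]
        .drop_duplicates()
        .sort_values(["gene", "disease", "evidence_type"])
        .reset_index(drop=True)
    )
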