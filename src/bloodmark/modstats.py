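"""Group statistics for module eigengenes and phenotype tables.

* :func:`bayes_anova` -- a Bayes-regularized one-way ANOVA in the Cyber-T
  tradition: each group's sample variance is shrunk toward a background
  variance pooled over the ``win_size`` features with the nearest overall
  mean, with prior strength ``conf`` pseudo-observations. Pairwise post hoc
  tests use the regularized pooled variance with a Tukey-style (studentized
  range) family correction over the three group pairs.
* :func:`correlate_traits` -- module-eigengene x trait Pearson correlations
  with Student asymptotic two-sided p-values.
* :func:`hypergeometric_enrichment` -- one-tailed hypergeometric gene-set
  enrichment with a two-gene minimum overlap and Bonferroni correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class BayesAnovaConfig:
    conf: float = 12.0
    bayes: bool = True
    win_size: int = 5
    #: "tukey" for studentized-range-corrected pairwise tests, None to skip
    posthoc: str | None = "tukey"

    def __post_init__(self):
        if self.conf < 0:
            raise ValueError("conf must be non-negative")
        if self.win_size < 1 or self.win_size % 2 == 0:
            raise ValueError("win_size must be a positive odd integer")


def _background_variance(variances: np.ndarray, overall_mean: np.ndarray, win: int) -> np.ndarray:
    """Mean sample variance over the ``win`` features nearest in overall mean.

    Features are ranked by overall mean; the window is centered on each
    feature and clipped at the edges (so edge features still average over
    ``win`` neighbours).
    """
    order = np.argsort(overall_mean, kind="stable")
    v_sorted = variances[order]
    n = len(variances)
    win = min(win, n)
    half = win // 2
    csum = np.concatenate([[0.0], np.cumsum(v_sorted)])
    bg_sorted = np.empty(n)
    for i in range(n):
        lo = min(max(0, i - half), n - win)
        bg_sorted[i] = (csum[lo + win] - csum[lo]) / win
    bg = np.empty(n)
    bg[order] = bg_sorted
    return bg


def bayes_anova(
    values: pd.DataFrame,
    groups,
    config: BayesAnovaConfig | None = None,
) -> pd.DataFrame:
    """Regularized one-way ANOVA per feature (row) across subject groups.

    The regularized within-group variance is
    s~^2 = (conf * s_bg^2 + (n-1) * s^2) / (conf + n - 1), which recovers the
    classical sample variance (and hence classical ANOVA) as conf -> 0 or
    with ``bayes`` off. The omnibus F uses the pooled regularized variance
    with an effective error df of sum_k (n_k - 1) + K * conf.

    Returns one row per feature with group means/sds, F, p, raw and
    Tukey-corrected pairwise p-values, and direction labels.
    """
    config = config or BayesAnovaConfig()
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))  # preserve order of first appearance
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    idx = {g: np.flatnonzero(groups == g) for g in labels}
    for g, ii in idx.items():
        if len(ii) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")

    x = values.to_numpy(dtype=float)
    n_feat = x.shape[0]
    counts = {g: len(ii) for g, ii in idx.items()}
    n_total = sum(counts.values())
    k = len(labels)

    means = {g: x[:, ii].mean(axis=1) for g, ii in idx.items()}
    sds = {g: x[:, ii].std(axis=1, ddof=1) for g, ii in idx.items()}
    overall_mean = x.mean(axis=1)
    grand = sum(counts[g] * means[g] for g in labels) / n_total

    conf = config.conf if config.bayes else 0.0
    reg_var = {}
    for g in labels:
        s2 = sds[g] ** 2
        if conf > 0:
            bg = _background_variance(s2, overall_mean, config.win_size)
            reg_var[g] = (conf * bg + (counts[g] - 1) * s2) / (conf + counts[g] - 1)
        else:
            reg_var[g] = s2

    ss_between = sum(counts[g] * (means[g] - grand) ** 2 for g in labels)
    msb = ss_between / (k - 1)
    err_df = sum(counts[g] - 1 for g in labels) + k * conf
    msw = sum((conf + counts[g] - 1) * reg_var[g] for g in labels) / err_df
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat = np.where(msw > 0, msb / msw, 0.0)
    p_omni = stats.f.sf(f_stat, k - 1, err_df)
    p_omni = np.where(msb == 0, 1.0, p_omni)

    rows = {"feature": values.index, "F": f_stat, "p": p_omni}
    for g in labels:
        rows[f"mean_{g}"] = means[g]
        rows[f"sd_{g}"] = sds[g]

    pairs = itertools.combinations(labels, 2) if config.posthoc else ()
    for ga, gb in pairs:
        na, nb = counts[ga], counts[gb]
        pooled = (
            (conf + na - 1) * reg_var[ga] + (conf + nb - 1) * reg_var[gb]
        ) / (2 * conf + na + nb - 2)
        pair_df = na + nb - 2 + 2 * conf
        diff = means[ga] - means[gb]
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
            t = np.where(se > 0, diff / se, 0.0)
            q = np.where(se > 0, np.abs(diff) / np.sqrt(pooled / 2.0 * (1.0 / na + 1.0 / nb)), 0.0)
        p_raw = 2.0 * stats.t.sf(np.abs(t), pair_df)
        p_tukey = stats.studentized_range.sf(q, k, err_df)
        p_corr = np.maximum(p_raw, p_tukey)
        direction = np.where(diff > 0, f"{ga}>{gb}", np.where(diff < 0, f"{gb}>{ga}", "="))
        rows[f"p_{ga}_vs_{gb}"] = p_raw
        rows[f"p_{ga}_vs_{gb}_corrected"] = p_corr
        rows[f"direction_{ga}_vs_{gb}"] = direction

    out = pd.DataFrame(rows).set_index("feature")
    out.attrs["groups"] = labels
    out.attrs["err_df"] = float(err_df)
    out.attrs["window_note"] = (
        f"background variance window win_size={config.win_size}, clipped at edges"
        if conf > 0
        else "no regularization"
    )
    return out


def pearson_pvalue(r: np.ndarray, n) -> np.ndarray:
    """Two-sided Student asymptotic p for a Pearson r at sample size n."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2.0) / np.clip(1.0 - r**2, 1e-300, None))
    return 2.0 * stats.t.sf(np.abs(t), n - 2.0)


def correlate_traits(
    eigengenes, phenotypes: pd.DataFrame, encode_groups: bool = True
) -> pd.DataFrame:
    """Module x trait Pearson correlations with asymptotic p-values.

    Group labels are encoded as one-vs-rest 0/1 indicator traits
    (``<group>_status``). Non-numeric columns are ignored; constant traits
    are recorded with missing r and a warning. Returns a long-format table
    (module, trait, r, p, n) with the Bonferroni threshold in ``attrs``.
    """
    me = eigengenes if isinstance(eigengenes, pd.DataFrame) else eigengenes.values
    pheno = phenotypes.copy()
    if not set(me.columns) <= set(pheno.index):
        if "subject_id" in pheno.columns:
            pheno = pheno.set_index("subject_id", drop=False)
        if not set(me.columns) <= set(pheno.index):
            raise ValueError("phenotype table does not cover the eigengene subjects")
    pheno = pheno.loc[list(me.columns)]

    traits = {}
    if encode_groups and "group" in pheno.columns:
        for g in pd.unique(pheno["group"]):
            traits[f"{g}_status"] = (pheno["group"] == g).astype(float).to_numpy()
    for col in pheno.columns:
        if col in ("subject_id", "group"):
            continue
        vals = pd.to_numeric(pheno[col], errors="coerce")
        if vals.notna().sum() >= 3:
            traits[col] = vals.to_numpy(dtype=float)

    records = []
    for mod in me.index:
        y = me.loc[mod].to_numpy(dtype=float)
        for trait, tv in traits.items():
            mask = np.isfinite(tv) & np.isfinite(y)
            n = int(mask.sum())
            if n < 3 or np.std(tv[mask]) == 0 or np.std(y[mask]) == 0:
                warnings.warn(f"trait {trait!r} constant or too sparse; r undefined", stacklevel=2)
                records.append({"module": mod, "trait": trait, "r": np.nan, "p": np.nan, "n": n})
                continue
            r = float(np.corrcoef(y[mask], tv[mask])[0, 1])
            p = float(pearson_pvalue(np.array(r), n))
            records.append({"module": mod, "trait": trait, "r": r, "p": p, "n": n})
    out = pd.DataFrame(records)
    n_tests = int(out["r"].notna().sum())
    out.attrs["bonferroni_threshold"] = 0.05 / n_tests if n_tests else np.nan
    out.attrs["n_tests"] = n_tests
    return out


def hypergeometric_enrichment(
    query_genes, gene_set, background_size: int, min_overlap: int = 2
) -> tuple[float, int]:
    """Upper-tail hypergeometric p of the query/set overlap.

    Returns ``(p, overlap)``; ``p`` is NaN when the overlap is below
    ``min_overlap`` (the set is skipped, not tested).
    """
    query = set(query_genes)
    gset = set(gene_set)
    if len(query | gset) > background_size:
        raise ValueError("background smaller than the union of query and gene set")
    overlap = len(query & gset)
    if overlap < min_overlap:
        return float("nan"), overlap
    p = float(stats.hypergeom.sf(overlap - 1, background_size, len(gset), len(query)))
    return p, overlap


def enrichment_table(
    query_genes, gene_sets: dict, background_size: int, min_overlap: int = 2
) -> pd.DataFrame:
    """Test many gene sets; Bonferroni across the sets actually tested."""
    rows = []
    for name, gset in gene_sets.items():
        p, ov = hypergeometric_enrichment(query_genes, gset, background_size, min_overlap)
        rows.append({"gene_set": name, "set_size": len(set(gset)), "overlap": ov, "p": p})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["p_bonferroni"] = np.nan
    out.loc[tested, "p_bonferroni"] = np.minimum(out.loc[tested, "p"] * tested.sum(), 1.0)
    return out.sort_values("p", na_position="last").reset_index(drop=True)
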