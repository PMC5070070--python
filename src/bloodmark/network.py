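"""Signed weighted co-expression network construction and module detection.

Pipeline: Pearson correlation -> soft-thresholded signed adjacency
a_ij = ((1 + r_ij)/2)^beta -> topological overlap matrix (TOM) -> average
linkage hierarchical clustering of 1 - TOM -> a simplified hybrid tree cut
honoring a minimum module size and a deep-split sensitivity level ->
eigengene-based merging of close modules. Module summaries are eigengenes
(first right-singular vector of the standardized module submatrix), gene
module-membership values (kME) and hub genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

GREY = 0  # reserved label for unassigned genes


@dataclass
class NetworkConfig:
    beta: float = 9.0
    min_module_size: int = 15
    deep_split: int = 2
    merge_cut_height: float = 0.2
    signed: bool = True
    #: small branches are absorbed into the nearest module only if their mean
    #: dissimilarity to it is below this bound; otherwise they go grey
    absorb_max_dissimilarity: float = 0.8
    #: a terminal cluster counts as a module only if its mean internal
    #: dissimilarity is below this fraction of the matrix-wide mean
    cohesion_ratio: float = 0.95

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")
        if not 0.0 < self.merge_cut_height < 1.0:
            raise ValueError("merge_cut_height must be in (0, 1)")


@dataclass
class EigengeneMatrix:
    """Module x subject eigengene values plus variance explained."""

    values: pd.DataFrame
    var_explained: pd.Series


def _drop_zero_variance(values: pd.DataFrame) -> pd.DataFrame:
    sd = values.to_numpy().std(axis=1)
    if (sd == 0).any():
        bad = list(values.index[sd == 0])
        warnings.warn(
            f"dropping {len(bad)} zero-variance gene(s) before correlation: {bad[:5]}",
            stacklevel=3,
        )
        values = values.loc[sd > 0]
    return values


def signed_adjacency(values: pd.DataFrame, config: NetworkConfig | None = None) -> pd.DataFrame:
    """Soft-thresholded adjacency; signed (default) or unsigned |r|^beta."""
    config = config or NetworkConfig()
    if values.shape[1] < 3:
        raise ValueError("need at least 3 subjects to build a network")
    values = _drop_zero_variance(values)
    if (values.to_numpy().std(axis=1) == 0).any():
        bad = values.index[values.to_numpy().std(axis=1) == 0][0]
        raise ValueError(f"zero-variance gene remains: {bad}")
    r = np.corrcoef(values.to_numpy())
    r = np.clip(r, -1.0, 1.0)
    if config.signed:
        a = ((1.0 + r) / 2.0) ** config.beta
    else:
        a = np.abs(r) ** config.beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=values.index, columns=values.index)


def scale_free_fit(adjacency: pd.DataFrame, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity-frequency fit.

    Connectivity k_i = sum_{j != i} a_ij is binned; log10 frequency is
    regressed on log10 mean connectivity per bin. The R^2 is negated when the
    slope is positive (anti-scale-free). Returns NaN with a warning when all
    connectivities coincide.
    """
    a = adjacency.to_numpy(dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    if np.ptp(k) == 0:
        warnings.warn("all connectivities equal; scale-free fit undefined", stacklevel=2)
        return float("nan")
    n_distinct = len(np.unique(k))
    if n_distinct < n_bins:
        warnings.warn(
            f"only {n_distinct} distinct connectivities; reducing bin count", stacklevel=2
        )
        n_bins = max(2, n_distinct)
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        warnings.warn("too few occupied bins for a scale-free fit", stacklevel=2)
        return float("nan")
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = np.array(ys) - (slope * np.array(xs) + intercept)
    ss_tot = np.sum((np.array(ys) - np.mean(ys)) ** 2)
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    return float(-r2 if slope > 0 else r2)


def topological_overlap(adjacency: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TOM and its dissimilarity 1 - TOM.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j
    with unit diagonal, where k excludes the diagonal.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    shared = a0 @ a0
    k = a0.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a0) / (min_k + 1.0 - a0)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    tom_df = pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom_df, 1.0 - tom_df


def _largest_valid_gap_cut(sub: np.ndarray, min_size: int, gap_frac: float):
    """Find a cut of the average-linkage tree of ``sub`` at the widest
    relative merge-height gap that separates at least two clusters of
    size >= max(3, min_size // 2). Returns labels or None."""
    n = sub.shape[0]
    if n < 4:
        return None
    z = linkage(squareform(sub, checks=False), method="average")
    heights = np.sort(z[:, 2])
    h_range = heights[-1] - heights[0]
    if h_range <= 0:
        return None
    gaps = np.diff(heights)
    order = np.argsort(gaps)[::-1]
    min_part = max(3, min_size // 2)
    for idx in order:
        if gaps[idx] < gap_frac * h_range:
            break
        t = (heights[idx] + heights[idx + 1]) / 2.0
        labels = fcluster(z, t, criterion="distance")
        sizes = np.bincount(labels)[1:]
        if (sizes >= min_part).sum() >= 2:
            return labels
    return None


def detect_modules(dissimilarity: pd.DataFrame, config: NetworkConfig | None = None) -> pd.Series:
    """Partition genes into modules from a TOM dissimilarity.

    A simplified hybrid tree cut in three passes over the average-linkage
    dendrogram:

    1. scan candidate cut heights and keep the one producing the most
       *accepted* clusters -- clusters of at least ``min_module_size`` genes
       whose mean internal dissimilarity stays below ``cohesion_ratio``
       times the matrix-wide mean (this rejects loose agglomerates of
       unrelated genes). ``deep_split`` breaks ties between equally good
       heights: deeper split prefers lower (finer) cuts;
    2. re-split each accepted cluster at the widest relative gap of its own
       merge heights when that yields two or more accepted sub-clusters
       (hidden sub-structure);
    3. genes outside accepted clusters are absorbed into the nearest module
       when their branch's mean dissimilarity to it is below
       ``absorb_max_dissimilarity``; everything else is grey (label 0).

    Deterministic given its input.
    """
    config = config or NetworkConfig()
    d = dissimilarity.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be square and symmetric")
    genes = list(dissimilarity.index)
    n = len(genes)
    if n < config.min_module_size:
        warnings.warn("fewer genes than min_module_size; all grey", stacklevel=2)
        return pd.Series(GREY, index=genes, name="module")

    overall_mean = d[np.triu_indices(n, k=1)].mean()
    cohesion_bound = (
        config.cohesion_ratio * overall_mean if overall_mean > 0 else np.inf
    )

    def cohesion(idx: np.ndarray) -> float:
        if len(idx) < 2:
            return 0.0
        block = d[np.ix_(idx, idx)]
        return float(block[np.triu_indices(len(idx), k=1)].mean())

    def accepted_clusters(idx_all: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
        out = []
        for l in np.unique(labels):
            c = idx_all[labels == l]
            if len(c) >= config.min_module_size and cohesion(c) <= cohesion_bound:
                out.append(c)
        return out

    z = linkage(squareform(d, checks=False), method="average")
    heights = np.unique(z[:, 2])
    if len(heights) > 80:
        qs = np.linspace(0.0, 1.0, 80)
        heights = np.unique(np.quantile(heights, qs))
    idx_all = np.arange(n)

    best: tuple[int, list[np.ndarray]] = (0, [])
    candidates: list[tuple[float, list[np.ndarray]]] = []
    for t in heights:
        labels = fcluster(z, t, criterion="distance")
        acc = accepted_clusters(idx_all, labels)
        if len(acc) > best[0]:
            best = (len(acc), acc)
            candidates = [(t, acc)]
        elif len(acc) == best[0] and len(acc) > 0:
            candidates.append((t, acc))
    if candidates:
        # deep_split 4 -> finest (lowest) qualifying cut, 0 -> coarsest
        pick = int(round((1.0 - config.deep_split / 4.0) * (len(candidates) - 1)))
        accepted = candidates[pick][1]
    else:
        accepted = []

    # second pass: split hidden sub-structure inside each accepted cluster
    gap_frac = max(0.05, 0.40 - 0.075 * config.deep_split)
    refined: list[np.ndarray] = []
    for c in accepted:
        labels = _largest_valid_gap_cut(
            d[np.ix_(c, c)], config.min_module_size, gap_frac
        )
        if labels is not None:
            sub = accepted_clusters(c, labels)
            if len(sub) >= 2:
                refined.extend(sub)
                continue
        refined.append(c)

    assignment = np.full(n, GREY, dtype=int)
    refined.sort(key=lambda c: c.min())  # stable module numbering
    for label, c in enumerate(refined, start=1):
        assignment[c] = label

    # absorb remaining genes into the nearest module when close enough
    if refined:
        loose = idx_all[assignment == GREY]
        for g in loose:
            mean_d = [d[g, c].mean() for c in refined]
            k = int(np.argmin(mean_d))
            if mean_d[k] < config.absorb_max_dissimilarity:
                assignment[g] = k + 1

    return pd.Series(assignment, index=genes, name="module")


def module_eigengenes(values: pd.DataFrame, partition: pd.Series) -> EigengeneMatrix:
    """First principal component summary of each module.

    Member genes are standardized across subjects; the eigengene is the first
    right-singular vector (unit norm over subjects), sign-oriented so that
    the majority of member genes correlate positively with it. Variance
    explained is the first squared singular value over the total.
    """
    modules = sorted(m for m in partition.unique() if m != GREY)
    rows, varexp = [], []
    for m in modules:
        member = partition.index[partition == m]
        x = values.loc[member].to_numpy(dtype=float)
        sd = x.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"module {m} contains constant gene(s); cannot standardize")
        xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(xs, full_matrices=False)
        me = vt[0]
        cors = _row_cor(xs, me)
        if np.sum(cors > 0) < np.sum(cors < 0) or (
            np.sum(cors > 0) == np.sum(cors < 0) and cors.sum() < 0
        ):
            me = -me
        rows.append(me)
        varexp.append(s[0] ** 2 / np.sum(s**2))
    index = pd.Index([f"M{m}" for m in modules], name="module")
    return EigengeneMatrix(
        values=pd.DataFrame(rows, index=index, columns=values.columns),
        var_explained=pd.Series(varexp, index=index, name="var_explained"),
    )


def _row_cor(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, xc @ vc / denom, 0.0)


def merge_close_modules(
    values: pd.DataFrame, partition: pd.Series, config: NetworkConfig | None = None
) -> pd.Series:
    """Merge modules whose eigengenes are closer than ``merge_cut_height``.

    Modules are clustered on 1 - cor(ME) with average linkage and merged
    below the cut height; eigengenes are recomputed and the process repeats
    until no pair of eigengenes has correlation > 1 - merge_cut_height.
    """
    config = config or NetworkConfig()
    part = partition.copy()
    for _ in range(100):
        modules = sorted(m for m in part.unique() if m != GREY)
        if len(modules) < 2:
            break
        eg = module_eigengenes(values, part)
        me = eg.values.to_numpy()
        r = np.corrcoef(me)
        diss = np.clip(1.0 - r, 0.0, None)
        np.fill_diagonal(diss, 0.0)
        if (diss[np.triu_indices(len(modules), k=1)] >= config.merge_cut_height).all():
            break
        z = linkage(squareform(diss, checks=False), method="average")
        groups = fcluster(z, config.merge_cut_height, criterion="distance")
        relabel = {}
        new_label = 0
        for g in groups:
            if g not in relabel:
                new_label += 1
                relabel[g] = new_label
        mapping = {m: relabel[g] for m, g in zip(modules, groups)}
        mapping[GREY] = GREY
        part = part.map(mapping)
    return part.rename("module")


def module_membership(
    values: pd.DataFrame, eigengenes: EigengeneMatrix, partition: pd.Series | None = None
) -> tuple[pd.DataFrame, dict[str, str]]:
    """kME (gene x module correlation with eigengenes) and per-module hub genes.

    The hub gene of a module is its member with maximal own-module kME, ties
    broken by gene-id order. Without a partition, hubs are taken over all
    genes.
    """
    x = values.to_numpy(dtype=float)
    me = eigengenes.values.to_numpy(dtype=float)
    kme = np.empty((x.shape[0], me.shape[0]))
    for j in range(me.shape[0]):
        kme[:, j] = _row_cor(x, me[j])
    kme_df = pd.DataFrame(kme, index=values.index, columns=eigengenes.values.index)

    hubs: dict[str, str] = {}
    for j, mod in enumerate(eigengenes.values.index):
        if partition is not None:
            label = int(str(mod).lstrip("M"))
            members = partition.index[partition == label]
        else:
            members = values.index
        if len(members) == 0:
            continue
        col = kme_df.loc[members, mod]
        best = col.max()
        hubs[str(mod)] = sorted(col.index[col == best])[0]
    return kme_df, hubs
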