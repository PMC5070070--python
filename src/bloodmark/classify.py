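"""Moderated differential expression and RFE+DLDA diagnostic classifiers.

The moderated t-test shrinks per-gene variances toward a common prior in the
empirical-Bayes style: hyperparameters (prior df d0, prior variance s0^2)
are estimated by method of moments on the log sample variances, the
posterior variance is s~_g^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g), and the
statistic is referenced to a t distribution with d0 + d_g degrees of
freedom.

Diagnostic panels are built by recursive feature elimination under
leave-one-out cross-validation: within every fold the candidate genes are
re-ranked by |moderated t| on the training subjects only, nested panels
along the elimination path (drop the lowest-ranked 10% per step) are
evaluated with DLDA and three comparator classifiers (linear SVM, nearest
centroid, 3-NN), and the best panel size maximizes held-out accuracy (ties
to the smallest panel). Permutation p-values rerun the full procedure on
label-permuted data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, special
from scipy.optimize import brentq
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.svm import SVC

DEFAULT_CLASSIFIERS = ("dlda", "svm", "centroid", "knn")


# ---------------------------------------------------------------------------
# moderated t-test


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on sample variances.

    Given s2_g ~ s0^2 * F(df, d0), solve for (d0, s0^2) from the mean and
    variance of log s2_g using digamma/trigamma identities. Returns
    (inf, exp(mean-adjusted)) when the observed spread is no larger than the
    sampling spread (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.clip(s2, 1e-300, None)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = z.var(ddof=1) if len(z) > 1 else 0.0
    excess = e_var - special.polygamma(1, df / 2.0)
    if not np.isfinite(excess) or excess <= 1e-12:
        return np.inf, float(np.exp(e_mean))

    def fun(x):  # x = d0/2
        return special.polygamma(1, x) - excess

    # trigamma is decreasing; bracket the root
    lo, hi = 1e-6, 1e6
    if fun(lo) < 0:
        return np.inf, float(np.exp(e_mean))
    half_d0 = brentq(fun, lo, hi)
    d0 = 2.0 * half_d0
    s0_2 = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_2


def moderated_ttest(
    values: pd.DataFrame,
    labels,
    group_a: str,
    group_b: str,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated two-sample t-test between two subject groups.

    ``prior_df`` overrides the estimated d0 (``prior_df=0`` gives the
    ordinary pooled two-sample t-test). Returns a DataFrame indexed by gene
    with log-fold-change (mean difference on the log2 scale), moderated t,
    raw p, and the hyperparameters used.
    """
    labels = np.asarray(labels)
    ia = np.flatnonzero(labels == group_a)
    ib = np.flatnonzero(labels == group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs at least 2 subjects")
    na, nb = len(ia), len(ib)
    df_resid = na + nb - 2
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom")

    x = values.to_numpy(dtype=float)
    ma, mb = x[:, ia].mean(axis=1), x[:, ib].mean(axis=1)
    ssa = ((x[:, ia] - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((x[:, ib] - mb[:, None]) ** 2).sum(axis=1)
    s2 = (ssa + ssb) / df_resid

    if prior_df is None:
        d0, s0_2 = _fit_f_dist(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0_2 = float(np.median(s2)) if d0 > 0 else 0.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, (ma - mb) / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame(
        {
            "logFC": ma - mb,
            "t": t,
            "p": p,
            "s2": s2,
            "s2_post": s2_post,
        },
        index=values.index,
    )
    out.index.name = "gene"
    out.attrs["comparison"] = f"{group_a}_vs_{group_b}"
    out.attrs["d0"] = float(d0) if np.isfinite(d0) else np.inf
    out.attrs["s0_2"] = s0_2
    return out


def exclude_confounded(
    de: pd.DataFrame,
    partition: pd.Series,
    trait_cor: pd.DataFrame,
    confounder_traits,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Drop genes from modules associated with confounder traits at raw p < alpha.

    ``trait_cor`` is the long-format output of
    :func:`bloodmark.modstats.correlate_traits` with module labels matching
    ``"M" + partition`` labels. The removal log sits in
    ``result.attrs["excluded"]``.
    """
    confounder_traits = list(confounder_traits)
    missing = set(confounder_traits) - set(trait_cor["trait"])
    if missing:
        raise ValueError(f"confounder trait(s) not in correlation table: {sorted(missing)}")
    mask = trait_cor["trait"].isin(confounder_traits) & (trait_cor["p"] < alpha)
    bad_modules = {
        int(str(m).lstrip("M")) for m in trait_cor.loc[mask, "module"].unique()
    }
    bad_genes = set(partition.index[partition.isin(bad_modules)])
    keep = [g for g in de.index if g not in bad_genes]
    out = de.loc[keep].copy()
    out.attrs.update(de.attrs)
    out.attrs["excluded"] = {
        "modules": sorted(bad_modules),
        "n_genes_removed": int(len(de) - len(out)),
        "confounder_traits": confounder_traits,
        "alpha": alpha,
    }
    return out


# ---------------------------------------------------------------------------
# DLDA


def dlda_fit_predict(train_x: np.ndarray, train_y, test_x: np.ndarray) -> np.ndarray:
    """Diagonal LDA: argmin_k sum_j (x_j - mu_kj)^2 / sigma_j^2.

    ``train_x``/``test_x`` are subjects x genes. The pooled within-class
    variance is diagonal; zero-variance genes are dropped with a warning.
    Ties go to the first class in sorted label order.
    """
    train_x = np.asarray(train_x, dtype=float)
    test_x = np.atleast_2d(np.asarray(test_x, dtype=float))
    train_y = np.asarray(train_y)
    classes = np.array(sorted(set(train_y.tolist())))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    centroids, pooled_ss, pooled_df = [], np.zeros(train_x.shape[1]), 0
    for c in classes:
        xc = train_x[train_y == c]
        if xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training subjects")
        centroids.append(xc.mean(axis=0))
        pooled_ss += ((xc - xc.mean(axis=0)) ** 2).sum(axis=0)
        pooled_df += xc.shape[0] - 1
    var = pooled_ss / pooled_df
    usable = var > 0
    if not usable.all():
        warnings.warn(f"dropping {int((~usable).sum())} zero-variance gene(s)", stacklevel=2)
    if not usable.any():
        raise ValueError("no gene with positive pooled variance")
    centroids = np.array(centroids)[:, usable]
    scores = (
        (test_x[:, None, usable] - centroids[None, :, :]) ** 2 / var[usable][None, None, :]
    ).sum(axis=2)
    return classes[np.argmin(scores, axis=1)]


def _predict(name: str, train_x, train_y, test_x) -> np.ndarray:
    test_x = np.atleast_2d(test_x)
    if name == "dlda":
        return dlda_fit_predict(train_x, train_y, test_x)
    if name == "svm":
        model = SVC(kernel="linear", C=1.0)
    elif name == "centroid":
        model = NearestCentroid()
    elif name == "knn":
        model = KNeighborsClassifier(n_neighbors=min(3, len(train_y)))
    else:
        raise ValueError(f"unknown classifier {name!r}")
    model.fit(train_x, train_y)
    return model.predict(test_x)


# ---------------------------------------------------------------------------
# RFE + LOOCV


def rfe_path_sizes(n_features: int, drop_frac: float = 0.1) -> list[int]:
    """Nested panel sizes: drop the lowest-ranked 10% (>= 1 gene) per step."""
    sizes = [n_features]
    while sizes[-1] > 1:
        drop = max(1, int(np.floor(sizes[-1] * drop_frac)))
        sizes.append(sizes[-1] - drop)
    return sizes


@dataclass
class CVResult:
    """LOOCV accuracy curves and the best panel per classifier family."""

    accuracy: pd.DataFrame  # classifier x panel size
    best_size: dict[str, int]
    best_accuracy: dict[str, float]
    fold_rankings: list[np.ndarray] = field(repr=False, default_factory=list)
    permutation_p: float | None = None


@dataclass
class ClassifierPanel:
    model_label: str
    classifier: str
    genes: list[str]
    size: int
    cv_support: pd.Series  # % of folds selecting each candidate gene


def rfe_loocv(
    values: pd.DataFrame,
    labels,
    candidate_genes,
    classifiers=DEFAULT_CLASSIFIERS,
    chosen_classifier: str = "dlda",
    model_label: str = "model",
) -> tuple[CVResult, ClassifierPanel]:
    """Recursive feature elimination under leave-one-out cross-validation.

    ``values`` is genes x subjects. Candidate genes are re-ranked inside
    every fold by |moderated t| computed on the training subjects only, so
    feature selection never sees the held-out subject. The returned panel is
    the refit on all subjects at the best cross-validated size for
    ``chosen_classifier``; CV support is the percentage of folds whose
    selected panel contained the gene.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("rfe_loocv expects a binary classification problem")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 subjects; LOOCV degenerates")
    candidate_genes = [g for g in candidate_genes if g in values.index]
    if not candidate_genes:
        raise ValueError("no candidate genes present in the expression matrix")
    sub = values.loc[candidate_genes]
    x = sub.to_numpy(dtype=float)
    n_sub = x.shape[1]
    sizes = rfe_path_sizes(len(candidate_genes))

    def rank_genes(col_mask: np.ndarray) -> np.ndarray:
        de = moderated_ttest(
            sub.loc[:, sub.columns[col_mask]], labels[col_mask], classes[0], classes[1]
        )
        # descending |t|; ties broken by gene order for determinism
        return np.lexsort((np.arange(len(candidate_genes)), -np.abs(de["t"].to_numpy())))

    correct = {c: np.zeros(len(sizes)) for c in classifiers}
    fold_rankings = []
    fold_top = []  # per fold, ranked gene indices (full order)
    for held in range(n_sub):
        mask = np.ones(n_sub, dtype=bool)
        mask[held] = False
        order = rank_genes(mask)
        fold_rankings.append(order)
        fold_top.append(order)
        train_x_full = x[:, mask].T  # subjects x genes
        test_x_full = x[:, held][None, :]
        train_y = labels[mask]
        for si, size in enumerate(sizes):
            gi = order[:size]
            for c in classifiers:
                pred = _predict(c, train_x_full[:, gi], train_y, test_x_full[:, gi])
                if pred[0] == labels[held]:
                    correct[c][si] += 1

    acc = pd.DataFrame(
        {c: correct[c] / n_sub for c in classifiers}, index=pd.Index(sizes, name="panel_size")
    ).T
    best_size, best_acc = {}, {}
    for c in classifiers:
        row = acc.loc[c]
        best = row.max()
        best_size[c] = int(min(s for s in sizes if row[s] == best))
        best_acc[c] = float(best)

    b = best_size[chosen_classifier]
    support = np.zeros(len(candidate_genes))
    for order in fold_top:
        support[order[:b]] += 1
    support = pd.Series(
        100.0 * support / n_sub, index=candidate_genes, name="cv_support_pct"
    )

    full_order = rank_genes(np.ones(n_sub, dtype=bool))
    panel_genes = [candidate_genes[i] for i in full_order[:b]]
    panel = ClassifierPanel(
        model_label=model_label,
        classifier=chosen_classifier,
        genes=panel_genes,
        size=b,
        cv_support=support,
    )
    result = CVResult(
        accuracy=acc,
        best_size=best_size,
        best_accuracy=best_acc,
        fold_rankings=fold_rankings,
    )
    return result, panel


def permutation_pvalue(
    values: pd.DataFrame,
    labels,
    candidate_genes,
    n_perm: int = 1000,
    seed: int = 0,
    classifier: str = "dlda",
) -> float:
    """Permutation p for the cross-validated misclassification rate.

    p = (1 + #{permutations with error <= observed}) / (n_perm + 1), with
    feature selection rerun inside every permutation's LOOCV loop.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    result, _ = rfe_loocv(
        values, labels, candidate_genes, classifiers=(classifier,), chosen_classifier=classifier
    )
    observed_error = 1.0 - result.best_accuracy[classifier]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        res, _ = rfe_loocv(
            values, perm, candidate_genes, classifiers=(classifier,), chosen_classifier=classifier
        )
        if 1.0 - res.best_accuracy[classifier] <= observed_error + 1e-12:
            count += 1
    return (1.0 + count) / (n_perm + 1.0)
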