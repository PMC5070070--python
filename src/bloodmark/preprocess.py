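"""Count filtering, voom-style normalization and subject outlier screening.

The normalization follows the published voom recipe: log2 counts-per-million
with 0.5/1 offsets, a lowess trend of sqrt(residual sd) against average log2
count, and per-observation precision weights equal to the inverse of the
predicted variance (predicted sqrt-sd to the power −4).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Normalized log2-scale expression with per-observation weights."""

    values: pd.DataFrame  # genes x subjects, log2-CPM
    weights: pd.DataFrame  # same shape, inverse predicted variance
    trend_x: np.ndarray = field(default_factory=lambda: np.empty(0))  # mean log2 count knots
    trend_y: np.ndarray = field(default_factory=lambda: np.empty(0))  # sqrt-sd at knots

    def __post_init__(self):
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights must have identical shape")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if (self.weights.to_numpy() <= 0).any():
            raise ValueError("weights must be strictly positive")

    @property
    def genes(self):
        return self.values.index

    @property
    def subjects(self):
        return self.values.columns


def filter_low_expression(
    counts: pd.DataFrame, min_reads: int = 20, min_subjects: int = 10
) -> pd.DataFrame:
    """Keep genes with at least ``min_reads`` reads in at least ``min_subjects`` subjects.

    The retained/removed tally is stored in ``result.attrs["filter_report"]``.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be non-negative")
    if min_subjects > counts.shape[1]:
        raise ValueError(
            f"min_subjects={min_subjects} exceeds subject count {counts.shape[1]}"
        )
    keep = (counts.to_numpy() >= min_reads).sum(axis=1) >= min_subjects
    out = counts.loc[keep].copy()
    report = {
        "input_genes": int(counts.shape[0]),
        "retained_genes": int(keep.sum()),
        "removed_genes": int((~keep).sum()),
        "min_reads": int(min_reads),
        "min_subjects": int(min_subjects),
    }
    out.attrs["filter_report"] = report
    if out.empty:
        warnings.warn("filter_low_expression removed every gene", stacklevel=2)
    log.info("filter_low_expression retained %d/%d genes", report["retained_genes"], report["input_genes"])
    return out


def voom_normalize(counts: pd.DataFrame, span: float = 0.5) -> ExpressionMatrix:
    """log2-CPM transform with mean-variance trend precision weights.

    values[g, s] = log2((count + 0.5) / (lib_size_s + 1) * 1e6). The trend is
    a lowess fit of sqrt(residual sd per gene) against average log2 count;
    each observation's weight is the predicted sqrt-sd at its fitted log2
    count, raised to the power −4. Ties in mean log count are resolved by the
    lowess sort, i.e. effectively by gene order.
    """
    c = counts.to_numpy(dtype=float)
    lib = c.sum(axis=0)
    zero_lib = np.flatnonzero(lib == 0)
    if zero_lib.size:
        bad = ", ".join(str(counts.columns[i]) for i in zero_lib)
        raise ValueError(f"zero library size for subject(s): {bad}")

    values = np.log2((c + 0.5) / (lib + 1.0)[None, :] * 1e6)

    # mean-variance trend on (average log2 count, sqrt residual sd)
    mean_log_count = values.mean(axis=1) + np.log2(lib + 1.0).mean() - np.log2(1e6)
    sd = values.std(axis=1, ddof=1)
    sqrt_sd = np.sqrt(sd)
    fit = lowess(sqrt_sd, mean_log_count, frac=span, return_sorted=True)
    trend_x, trend_y = fit[:, 0], fit[:, 1]
    # collapse duplicated x for interpolation
    ux, first = np.unique(trend_x, return_index=True)
    uy = trend_y[first]

    # fitted log2 count of every observation given its library size
    logcpm_mean = values.mean(axis=1)
    fitted = logcpm_mean[:, None] + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted, ux, uy)
    pred_sqrt_sd = np.clip(pred_sqrt_sd, 1e-6, None)
    weights = pred_sqrt_sd**-4

    vdf = pd.DataFrame(values, index=counts.index, columns=counts.columns)
    wdf = pd.DataFrame(weights, index=counts.index, columns=counts.columns)
    return ExpressionMatrix(values=vdf, weights=wdf, trend_x=ux, trend_y=uy)


def detect_outliers(expr: ExpressionMatrix | pd.DataFrame, k_sd: float = 2.0) -> list[str]:
    """Flag subjects beyond ``k_sd`` standard deviations on either QC criterion.

    Criterion (a): each subject's mean Pearson correlation with all other
    subjects (the hierarchical-clustering distance view). Criterion (b):
    subject scores on the first two principal components. A subject flagged
    by either criterion is returned; a constant-expression subject (undefined
    correlation) is always flagged.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    x = values.to_numpy(dtype=float)
    subjects = list(values.columns)
    if len(subjects) < 3:
        raise ValueError("outlier detection needs at least 3 subjects")

    flagged: set[str] = set()
    col_sd = x.std(axis=0)
    constant = np.flatnonzero(col_sd == 0)
    for i in constant:
        warnings.warn(f"subject {subjects[i]} has constant expression", stacklevel=2)
        flagged.add(subjects[i])

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(corr, np.nan)
    mean_cor = np.nanmean(corr, axis=1)

    def z_outliers(scores: np.ndarray, low_only: bool = False) -> np.ndarray:
        finite = np.isfinite(scores)
        sd = scores[finite].std()
        if sd == 0 or not np.isfinite(sd):
            return np.zeros(len(scores), dtype=bool)
        z = (scores - scores[finite].mean()) / sd
        z[~finite] = -np.inf if low_only else np.inf
        return (z < -k_sd) if low_only else (np.abs(z) > k_sd)

    # an outlier can only be *less* correlated with the rest of the cohort
    for i in np.flatnonzero(z_outliers(mean_cor, low_only=True)):
        flagged.add(subjects[i])

    centered = x - x.mean(axis=1, keepdims=True)
    # subject scores on PC1/PC2 of the gene x subject matrix
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    for pc in range(min(2, vt.shape[0])):
        for i in np.flatnonzero(z_outliers(s[pc] * vt[pc])):
            flagged.add(subjects[i])

    return sorted(flagged)
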