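"""Sample/gene QC filters and the normalization stack.

Implements the standard bulk RNA-seq normalization chain: a library-size
filter (samples with more than 10 million counts retained), a low-expression
gene filter equivalent to edgeR's ``filterByExpr`` defaults, TMM scaling
factors (trimmed mean of M-values), logCPM, RPKM, and voom-style precision
weights from the fitted mean-variance trend.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess


@dataclass
class FilterReport:
    removed: list[str]
    kept: list[str]
    threshold: float

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_library_size(counts: pd.DataFrame, meta: pd.DataFrame | None = None,
                        min_total: int = 10_000_000):
    """Drop samples whose total count is not strictly greater than ``min_total``.

    Returns ``(counts, meta, report)`` (``meta`` is None if not supplied).
    """
    lib = counts.sum(axis=0)
    keep = lib > min_total
    removed = list(counts.columns[~keep])
    if not keep.any():
        raise ValueError(
            f"library-size filter at {min_total} removed all {len(lib)} samples")
    counts_f = counts.loc[:, keep]
    meta_f = None
    if meta is not None:
        meta_f = meta[meta["sample_id"].isin(counts_f.columns)].reset_index(drop=True)
    report = FilterReport(removed=removed, kept=list(counts_f.columns),
                          threshold=float(min_total))
    return counts_f, meta_f, report


def filter_low_expression(counts: pd.DataFrame, groups,
                          min_count: float = 10.0,
                          min_total_count: float = 15.0):
    """Keep genes that are expressed at a worthwhile level, edgeR-default rule.

    A gene is kept when (a) its CPM exceeds the cutoff implied by
    ``min_count`` at the median library size in at least ``min_n`` samples,
    where ``min_n`` is the smallest group size (shrunk as ``10 + (n-10)*0.7``
    when above 10), and (b) its total count across samples is at least
    ``min_total_count``.  Both clauses use a small tolerance so exact-boundary
    genes are kept, matching the reference rule.
    """
    groups = pd.Series(np.asarray(groups), index=counts.columns)
    lib = counts.sum(axis=0).to_numpy(float)
    median_lib = float(np.median(lib))
    cpm_cutoff = min_count / median_lib * 1e6
    min_n = float(groups.value_counts().min())
    if min_n > 10:
        min_n = 10 + (min_n - 10) * 0.7
    tol = 1e-14
    cpm = counts.to_numpy(float) / lib[None, :] * 1e6
    keep_cpm = (cpm >= cpm_cutoff - tol).sum(axis=1) >= min_n - tol
    keep_total = counts.sum(axis=1).to_numpy(float) >= min_total_count - tol
    keep = keep_cpm & keep_total
    if not keep.any():
        raise ValueError("low-expression filter removed every gene")
    report = FilterReport(removed=list(counts.index[~keep]),
                          kept=list(counts.index[keep]), threshold=cpm_cutoff)
    return counts.loc[keep], report


def tmm_factors(counts: pd.DataFrame, trim_logratio: float = 0.3,
                trim_abs: float = 0.05) -> pd.Series:
    """TMM scaling factors: doubly trimmed, precision-weighted mean of
    gene-wise log ratios against a reference sample.

    The reference is the sample whose upper-quartile CPM is closest to the
    mean upper-quartile.  Per sample, gene-wise log2 ratios M and average
    log2 abundances A against the reference are computed on genes expressed
    in both; the top and bottom ``trim_logratio`` of M and ``trim_abs`` of A
    are trimmed; the factor is 2 to the inverse-variance-weighted mean of
    the surviving M values (weights from the asymptotic binomial variance).
    Factors are rescaled to geometric mean one.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    y = counts.to_numpy(float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        bad = list(counts.columns[lib <= 0])
        raise ValueError(f"samples with zero library size: {bad}")
    f75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    yr, lr = y[:, ref], lib[ref]

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        factors[j] = _tmm_pair(y[:, j], lib[j], yr, lr, trim_logratio, trim_abs,
                               sample=str(counts.columns[j]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def _tmm_pair(obs, lib_obs, ref, lib_ref, trim_logratio, trim_abs,
              sample="sample") -> float:
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        raise ValueError(
            f"sample {sample} shares no co-expressed genes with the TMM reference")
    p_obs = obs[ok] / lib_obs
    p_ref = ref[ok] / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    w = (lib_obs - obs[ok]) / (lib_obs * obs[ok]) + (lib_ref - ref[ok]) / (lib_ref * ref[ok])
    n = m.size
    lo_m = math.floor(n * trim_logratio) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_abs) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def effective_lib_sizes(counts: pd.DataFrame,
                        factors: pd.Series | None = None) -> pd.Series:
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.loc[counts.columns]
    return lib


def logcpm(counts: pd.DataFrame, factors: pd.Series | None = None,
           prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: ``log2((count + prior) / (eff_lib + 2*prior) * 1e6)``."""
    lib = effective_lib_sizes(counts, factors).to_numpy()
    vals = np.log2((counts.to_numpy(float) + prior)
                   / (lib[None, :] + 2.0 * prior) * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
         factors: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase per million: count / (length_kb * eff_lib_millions)."""
    missing = [g for g in counts.index if g not in gene_lengths.index]
    if missing:
        raise ValueError(f"gene lengths missing for: {missing[:10]}")
    lengths = gene_lengths.loc[counts.index].to_numpy(float)
    if (lengths <= 0).any():
        bad = list(counts.index[lengths <= 0])
        raise ValueError(f"non-positive gene lengths: {bad[:10]}")
    lib = effective_lib_sizes(counts, factors).to_numpy()
    vals = counts.to_numpy(float) / (lengths[:, None] / 1e3) / (lib[None, :] / 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


@dataclass
class WeightedLogExpression:
    """logCPM values with observation-level precision weights (same shape)."""

    logcpm: pd.DataFrame
    weights: pd.DataFrame

    def __post_init__(self):
        if self.logcpm.shape != self.weights.shape:
            raise ValueError("logCPM and weight matrices must have the same shape")
        if not np.isfinite(self.weights.to_numpy()).all() or \
                (self.weights.to_numpy() <= 0).any():
            raise ValueError("weights must be finite and strictly positive")


def voom_weights(counts: pd.DataFrame, factors: pd.Series | None,
                 design: pd.DataFrame, span: float = 0.5) -> WeightedLogExpression:
    """Precision weights from the fitted mean-variance trend of logCPM.

    Per gene, a linear model in ``design`` is fitted to logCPM; a lowess
    trend of sqrt(residual SD) against mean log2 count is fitted across
    genes; each observation's predicted sqrt-SD is looked up at its fitted
    log2 count; the weight is predicted-SD to the -4.
    """
    if counts.shape[0] < 10:
        raise ValueError("voom trend needs at least 10 genes")
    X = design.to_numpy(float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not of full column rank")
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    lib = effective_lib_sizes(counts, factors).to_numpy()
    y = np.log2((counts.to_numpy(float) + 0.5) / (lib[None, :] + 1.0) * 1e6)

    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T                       # genes x p
    fitted = beta @ X.T
    resid = y - fitted
    sigma = np.sqrt((resid ** 2).sum(axis=1) / (n - p))

    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    trend = _lowess(sy, sx, frac=span, it=3, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]

    fitted_logcount = fitted + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)  # rule-2 extrapolation
    pred_sqrt_sd = np.clip(pred_sqrt_sd, 1e-4, None)   # keep weights finite
    w = pred_sqrt_sd ** -4.0

    return WeightedLogExpression(
        logcpm=pd.DataFrame(y, index=counts.index, columns=counts.columns),
        weights=pd.DataFrame(w, index=counts.index, columns=counts.columns))
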