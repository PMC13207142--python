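"""Study-blocked weighted linear modeling and moderated differential expression.

Each gene's logCPM is modeled by weighted least squares on a group-means
design (one indicator per group PS_male, PS_female, Control_male,
Control_female — no intercept, so contrasts read exactly as printed) plus
study indicators as a blocking factor.  Residual variances are shrunk toward
an empirical-Bayes prior (d0, s0^2) estimated by matching moments of
log residual variances (digamma/trigamma inversion), giving moderated
t-statistics with d0 + d_g degrees of freedom.  Three contrasts are standard:

    male     = PS_male - Control_male
    female   = PS_female - Control_female
    interaction = male - female

A gene is called differentially expressed when |log2FC| > 1 and the
Benjamini-Hochberg adjusted p-value < 0.05 (both inequalities strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import GROUPS, group_labels, validate_pairing
from .normalize import (WeightedLogExpression, filter_low_expression,
                        tmm_factors, voom_weights)

STUDY_PREFIX = "study:"

#: The three standard contrasts over the four group columns.
STANDARD_CONTRASTS = ("male", "female", "interaction")


def build_design(meta: pd.DataFrame) -> pd.DataFrame:
    """Group-means + study-block design matrix (samples x columns).

    Columns: one indicator per group present (in GROUPS order) followed by
    treatment-coded study indicators (first study is the reference).  Raises
    on rank deficiency, naming the collinear columns.
    """
    groups = group_labels(meta)
    present = [g for g in GROUPS if (groups == g).any()]
    cols = {g: (groups == g).astype(float).to_numpy() for g in present}
    studies = list(pd.unique(meta["study"]))
    for s in studies[1:]:
        cols[f"{STUDY_PREFIX}{s}"] = (meta["study"] == s).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=meta["sample_id"].to_numpy())
    _check_full_rank(X)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(float)
    rank = np.linalg.matrix_rank(A)
    if rank < X.shape[1]:
        # QR with pivoting: columns beyond the numerical rank are dependent
        from scipy.linalg import qr
        _, r, piv = qr(A, pivoting=True)
        dependent = [X.columns[j] for j in piv[rank:]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} "
            f"columns); collinear columns: {dependent}")


def standard_contrasts(design: pd.DataFrame) -> dict[str, np.ndarray]:
    """PS-vs-control per sex and the sex-by-disease interaction."""
    def vec(plus: list[str], minus: list[str]) -> np.ndarray:
        v = np.zeros(design.shape[1])
        for g in plus + minus:
            if g not in design.columns:
                raise ValueError(f"group {g} absent from the design")
        for g in plus:
            v[design.columns.get_loc(g)] += 1.0
        for g in minus:
            v[design.columns.get_loc(g)] -= 1.0
        return v

    male = vec(["PS_male"], ["Control_male"])
    female = vec(["PS_female"], ["Control_female"])
    return {"male": male, "female": female, "interaction": male - female}


@dataclass
class GeneLMFit:
    """Per-gene weighted least-squares fits against a shared design."""

    design: pd.DataFrame
    coefficients: pd.DataFrame       # genes x design columns
    sigma2: pd.Series                # residual variance per gene
    df_resid: float
    xtx_inv: np.ndarray              # genes x p x p, (X' W X)^-1 per gene


def fit_weighted_lm(y: WeightedLogExpression | pd.DataFrame,
                    design: pd.DataFrame,
                    weights: pd.DataFrame | None = None) -> GeneLMFit:
    """Per-gene WLS: coefficients, residual variance, unscaled covariances.

    ``y`` may be a :class:`WeightedLogExpression` (weights inside) or a plain
    logCPM DataFrame with optional ``weights``; unit weights give OLS.
    """
    if isinstance(y, WeightedLogExpression):
        E, W = y.logcpm, y.weights
    else:
        E, W = y, weights
    X = design.to_numpy(float)
    n, p = X.shape
    if E.shape[1] != n:
        raise ValueError(f"expression has {E.shape[1]} samples, design has {n}")
    _check_full_rank(design)
    if n - p <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    Ev = E.to_numpy(float)
    Wv = np.ones_like(Ev) if W is None else W.to_numpy(float)

    xtwx = np.einsum("gi,ip,iq->gpq", Wv, X, X, optimize=True)
    xtwy = np.einsum("gi,ip->gp", Wv * Ev, X, optimize=True)
    xtx_inv = np.linalg.inv(xtwx)
    beta = np.einsum("gpq,gq->gp", xtx_inv, xtwy)
    resid = Ev - beta @ X.T
    sigma2 = (Wv * resid ** 2).sum(axis=1) / (n - p)
    return GeneLMFit(design=design,
                     coefficients=pd.DataFrame(beta, index=E.index,
                                               columns=design.columns),
                     sigma2=pd.Series(sigma2, index=E.index),
                     df_resid=float(n - p), xtx_inv=xtx_inv)


def trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(sigma2: np.ndarray, df: float,
                            ) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed log residual variances.

    Returns (d0, s0^2); d0 may be ``inf`` when the variances are essentially
    homogeneous (then the posterior variance is s0^2 for every gene).
    """
    sigma2 = np.asarray(sigma2, float)
    ok = sigma2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    e = (np.log(sigma2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0))
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0)
                             - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def posterior_variances(sigma2: np.ndarray, df: float, d0: float,
                        s0_sq: float) -> np.ndarray:
    """Squeeze per-gene variances toward the prior: (d0 s0^2 + d s^2)/(d0 + d)."""
    sigma2 = np.asarray(sigma2, float)
    if np.isinf(d0):
        return np.full_like(sigma2, s0_sq)
    return (d0 * s0_sq + df * sigma2) / (d0 + df)


@dataclass
class ModeratedFit:
    """A gene-level fit with empirical-Bayes moderated variances."""

    fit: GeneLMFit
    d0: float
    s0_sq: float
    post_var: pd.Series

    @property
    def df_total(self) -> float:
        return self.fit.df_resid + self.d0


def ebayes_moderate(fit: GeneLMFit, prior_df: float | None = None) -> ModeratedFit:
    """Estimate (d0, s0^2) and the posterior variances.

    ``prior_df`` overrides the estimated d0 (0 disables moderation; ``inf``
    collapses every variance to s0^2) — useful for limit-behavior checks.
    """
    if len(fit.sigma2) < 10:
        raise ValueError("empirical-Bayes moderation needs at least 10 genes")
    sigma2 = fit.sigma2.to_numpy()
    if np.allclose(sigma2, sigma2[0]):
        d0, s0_sq = np.inf, float(sigma2[0])
    else:
        d0, s0_sq = estimate_variance_prior(sigma2, fit.df_resid)
    if prior_df is not None:
        d0 = float(prior_df)
        if d0 == 0:
            s0_sq = float(np.median(sigma2))
    post = posterior_variances(sigma2, fit.df_resid, d0, s0_sq)
    return ModeratedFit(fit=fit, d0=d0, s0_sq=s0_sq,
                        post_var=pd.Series(post, index=fit.sigma2.index))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_contrasts(moderated: ModeratedFit,
                    contrasts: dict[str, np.ndarray] | None = None
                    ) -> dict[str, pd.DataFrame]:
    """Per-contrast logFC, moderated t, raw and BH-adjusted p.

    Contrast vectors span the design columns and must be zero on every
    study-blocking column.
    """
    fit = moderated.fit
    if contrasts is None:
        contrasts = standard_contrasts(fit.design)
    study_cols = [j for j, c in enumerate(fit.design.columns)
                  if str(c).startswith(STUDY_PREFIX)]
    out: dict[str, pd.DataFrame] = {}
    beta = fit.coefficients.to_numpy()
    df_total = moderated.df_total
    for name, c in contrasts.items():
        c = np.asarray(c, float)
        if c.shape != (fit.design.shape[1],):
            raise ValueError(f"contrast {name!r} has wrong length")
        if any(c[j] != 0 for j in study_cols):
            raise ValueError(
                f"contrast {name!r} touches study-blocking columns")
        logfc = beta @ c
        unscaled = np.einsum("p,gpq,q->g", c, fit.xtx_inv, c)
        se = np.sqrt(moderated.post_var.to_numpy() * unscaled)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, logfc / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        out[name] = pd.DataFrame({
            "logFC": logfc, "t": t, "p_value": p, "adj_p_value": bh_adjust(p),
        }, index=fit.coefficients.index)
    return out


def call_degs(table: pd.DataFrame, lfc_threshold: float = 1.0,
              alpha: float = 0.05) -> pd.DataFrame:
    """Flag DEGs: |log2FC| strictly > threshold and adjusted p strictly < alpha."""
    if "adj_p_value" not in table.columns:
        raise ValueError("table lacks adjusted p-values")
    table = table.copy()
    is_deg = (table["logFC"].abs() > lfc_threshold) & \
             (table["adj_p_value"] < alpha)
    table["is_deg"] = is_deg
    table["direction"] = np.where(~is_deg, "n.s.",
                                  np.where(table["logFC"] > 0, "Up", "Down"))
    return table


def partition_degs(female: pd.DataFrame, male: pd.DataFrame) -> pd.DataFrame:
    """Three-way Venn partition of sex-specific DEG calls with directions.

    ``female``/``male`` are :func:`call_degs` tables.  Returns one row per
    gene that is a DEG in at least one sex, with membership (female-only /
    male-only / overlap), per-sex direction labels, a combined label like
    ``"Up (M) Down (F)"``, and — for overlap genes — a consistent-direction
    flag (reported, not filtered on).
    """
    f_deg = set(female.index[female["is_deg"]])
    m_deg = set(male.index[male["is_deg"]])
    rows = []
    for g in sorted(f_deg | m_deg):
        in_f, in_m = g in f_deg, g in m_deg
        membership = ("overlap" if in_f and in_m
                      else "female-only" if in_f else "male-only")
        dir_f = female.loc[g, "direction"] if in_f else "n.s."
        dir_m = male.loc[g, "direction"] if in_m else "n.s."
        parts = []
        if dir_m != "n.s.":
            parts.append(f"{dir_m} (M)")
        if dir_f != "n.s.":
            parts.append(f"{dir_f} (F)")
        if in_f and in_m and dir_f == dir_m:
            label = f"{dir_m} (M, F)"
        else:
            label = " ".join(parts)
        rows.append({"gene": g, "membership": membership,
                     "direction_female": dir_f, "direction_male": dir_m,
                     "label": label,
                     "consistent": (dir_f == dir_m) if in_f and in_m else None})
    part = pd.DataFrame(rows, columns=["gene", "membership", "direction_female",
                                       "direction_male", "label", "consistent"])
    return part.set_index("gene") if len(part) else part


def venn_counts(partition: pd.DataFrame) -> dict[str, int]:
    if len(partition) == 0:
        return {"female_only": 0, "male_only": 0, "overlap": 0}
    vc = partition["membership"].value_counts()
    return {"female_only": int(vc.get("female-only", 0)),
            "male_only": int(vc.get("male-only", 0)),
            "overlap": int(vc.get("overlap", 0))}


class DifferentialExpressionModel:
    """Study-blocked, voom-weighted differential expression model.

    Parameters
    ----------
    counts : gene x sample integer matrix (already library-size filtered).
    meta : sample metadata with known sex for every sample.
    lfc_threshold, alpha : DEG-calling thresholds (strict inequalities).
    filter_genes : apply the low-expression filter before normalizing.
    """

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame,
                 lfc_threshold: float = 1.0, alpha: float = 0.05,
                 filter_genes: bool = True, min_count: float = 10.0,
                 min_total_count: float = 15.0, voom_span: float = 0.5):
        self.counts, self.meta = validate_pairing(counts, meta)
        self.lfc_threshold = lfc_threshold
        self.alpha = alpha
        self.filter_genes = filter_genes
        self.min_count = min_count
        self.min_total_count = min_total_count
        self.voom_span = voom_span

    def fit(self) -> "DEResults":
        counts = self.counts
        groups = group_labels(self.meta)
        if self.filter_genes:
            counts, gene_report = filter_low_expression(
                counts, groups.to_numpy(), self.min_count, self.min_total_count)
        else:
            gene_report = None
        factors = tmm_factors(counts)
        design = build_design(self.meta)
        weighted = voom_weights(counts, factors, design, span=self.voom_span)
        fit = fit_weighted_lm(weighted, design)
        moderated = ebayes_moderate(fit)
        tables = {name: call_degs(tab, self.lfc_threshold, self.alpha)
                  for name, tab in apply_contrasts(moderated).items()}
        return DEResults(model=self, factors=factors, design=design,
                         weighted=weighted, moderated=moderated,
                         tables=tables, gene_filter_report=gene_report)


@dataclass
class DEResults:
    """Fitted differential-expression results with DEG calls per contrast."""

    model: DifferentialExpressionModel
    factors: pd.Series
    design: pd.DataFrame
    weighted: WeightedLogExpression
    moderated: ModeratedFit
    tables: dict[str, pd.DataFrame]
    gene_filter_report: object | None = None

    def deg_set(self, contrast: str) -> set[str]:
        tab = self.tables[contrast]
        return set(tab.index[tab["is_deg"]])

    def partition(self) -> pd.DataFrame:
        return partition_degs(self.tables["female"], self.tables["male"])

    def venn_counts(self) -> dict[str, int]:
        return venn_counts(self.partition())

    def deg_counts(self) -> dict[str, int]:
        return {name: int(tab["is_deg"].sum())
                for name, tab in self.tables.items()}

    def summary(self) -> str:
        vc = self.venn_counts()
        counts = self.deg_counts()
        lines = ["Sex-stratified differential expression",
                 "=" * 46,
                 f"genes analyzed: {len(self.moderated.post_var)}   "
                 f"samples: {self.design.shape[0]}",
                 f"residual df: {self.moderated.fit.df_resid:.0f}   "
                 f"prior df d0: {self.moderated.d0:.2f}   "
                 f"prior var s0^2: {self.moderated.s0_sq:.4f}",
                 f"DEG rule: |log2FC| > {self.model.lfc_threshold} "
                 f"and BH-adjusted p < {self.model.alpha}",
                 "-" * 46]
        for name in ("female", "male", "interaction"):
            lines.append(f"DEGs ({name}): {counts.get(name, 0)}")
        lines.append(f"female-only: {vc['female_only']}   "
                     f"male-only: {vc['male_only']}   "
                     f"overlap: {vc['overlap']}")
        return "\n".join(lines)


def balanced_sensitivity(counts: pd.DataFrame, meta: pd.DataFrame,
                         seed: int = 0, **model_kwargs) -> dict:
    """Re-run DE on a sex-balanced subsample and compare DEG sets.

    Within each condition, the majority sex is randomly subsampled without
    replacement (seeded) so that male and female totals match; the full
    pipeline is re-run and per-contrast Jaccard overlap with the full-data
    DEG sets is reported.  Already-balanced input is returned unchanged.
    """
    rng = np.random.default_rng(seed)
    counts, meta = validate_pairing(counts, meta)
    keep: list[str] = []
    for condition, sub in meta.groupby("condition", sort=False):
        n_by_sex = sub["sex"].value_counts()
        if n_by_sex.get("male", 0) == 0 or n_by_sex.get("female", 0) == 0:
            raise ValueError(
                f"condition {condition} has a single sex; cannot balance")
        target = int(n_by_sex.min())
        for sex in ("male", "female"):
            ids = sub.loc[sub["sex"] == sex, "sample_id"]
            if len(ids) == target:
                keep.extend(ids)
                continue
            chosen = rng.choice(ids.to_numpy(), size=target, replace=False)
            keep.extend(chosen)
    keep = [s for s in counts.columns if s in set(keep)]  # counts order
    sub_meta = meta[meta["sample_id"].isin(keep)].reset_index(drop=True)
    full = DifferentialExpressionModel(counts, meta, **model_kwargs).fit()
    bal = DifferentialExpressionModel(counts[keep], sub_meta,
                                      **model_kwargs).fit()
    jaccard = {}
    for name in full.tables:
        a, b = full.deg_set(name), bal.deg_set(name)
        union = a | b
        jaccard[name] = (len(a & b) / len(union)) if union else 1.0
    return {"kept_samples": keep, "n_full": len(meta), "n_balanced": len(keep),
            "jaccard": jaccard, "full": full, "balanced": bal}
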