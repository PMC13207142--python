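"""Sex-stratified statistics on cell-type enrichment scores.

Enrichment scores (xCell-style) are relative, ordinal measures of cell-type
abundance, so group comparisons are non-parametric: a four-group
Kruskal-Wallis test with Dunn's post hoc pairwise z-tests.  The magnitude of
the disease effect within each sex is summarized by Cohen's D (pooled-SD
standardized mean difference of psoriasis vs control) with its large-sample
variance

    var(d) = (n1 + n2) / (n1 * n2) + d^2 / (2 * (n1 + n2))

and the male and female effect sizes are compared per cell type with

    z = (d_male - d_female) / sqrt(var_d_male + var_d_female),

two-sided normal p-values, and BH-FDR across cell types (FDR < 0.05
significant).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GROUPS, group_labels
from .linmod import bh_adjust


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p across groups.

    All observations equal (fully tied) degenerates to H = 0, p = 1.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def dunn_posthoc(values, groups, comparisons=None) -> pd.DataFrame:
    """Dunn's post hoc pairwise z-tests on the shared all-group ranking.

    z_ij = (meanRank_i - meanRank_j) /
           sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),  T = sum(t^3 - t)/(12(N-1))

    with two-sided normal p-values and BH adjustment across the reported
    pairs (all pairs by default; ``comparisons`` selects a subset).
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    n_by = {g: int((groups == g).sum()) for g in levels}
    if any(n == 0 for n in n_by.values()):
        raise ValueError("empty group")
    N = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {g: ranks[groups == g].mean() for g in levels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    if comparisons is None:
        comparisons = list(itertools.combinations(levels, 2))
    rows = []
    for g1, g2 in comparisons:
        if g1 not in n_by or g2 not in n_by:
            raise ValueError(f"unknown group in comparison ({g1}, {g2})")
        denom = np.sqrt(var_base * (1.0 / n_by[g1] + 1.0 / n_by[g2]))
        z = (mean_rank[g1] - mean_rank[g2]) / denom if denom > 0 else 0.0
        rows.append({"group1": g1, "group2": g2, "z": z,
                     "p_value": 2.0 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["adj_p_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def cohens_d(x_disease, x_control) -> tuple[float, float]:
    """Pooled-SD Cohen's D of disease vs control and its variance.

    d = (mean_d - mean_c) / s_pooled;
    var(d) = (n1+n2)/(n1 n2) + d^2 / (2 (n1+n2)).
    """
    x1 = np.asarray(x_disease, float)
    x0 = np.asarray(x_control, float)
    n1, n0 = len(x1), len(x0)
    if n1 < 2 or n0 < 2:
        raise ValueError("Cohen's D needs at least 2 observations per group")
    s_pooled_sq = ((n1 - 1) * x1.var(ddof=1) + (n0 - 1) * x0.var(ddof=1)) \
        / (n1 + n0 - 2)
    if s_pooled_sq <= 0:
        raise ValueError("zero pooled variance: Cohen's D undefined")
    d = (x1.mean() - x0.mean()) / np.sqrt(s_pooled_sq)
    var_d = (n1 + n0) / (n1 * n0) + d ** 2 / (2.0 * (n1 + n0))
    return float(d), float(var_d)


def effect_size_sex_test(d_male: float, var_d_male: float,
                         d_female: float, var_d_female: float
                         ) -> tuple[float, float]:
    """z-statistic and two-sided normal p for male-vs-female effect sizes."""
    if var_d_male <= 0 or var_d_female <= 0:
        raise ValueError("effect-size variances must be positive")
    z = (d_male - d_female) / np.sqrt(var_d_male + var_d_female)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def composition_fdr(rows: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-FDR across cell types; ``significant`` flags fdr < alpha."""
    rows = rows.copy()
    rows["fdr"] = bh_adjust(rows["p_value"].to_numpy())
    rows["significant"] = rows["fdr"] < alpha
    return rows


@dataclass
class CompositionResults:
    """Per-cell-type composition statistics (see :func:`analyze_composition`)."""

    table: pd.DataFrame
    dunn: dict[str, pd.DataFrame]
    alpha: float = 0.05

    @property
    def significant_cell_types(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def summary(self) -> str:
        sig = self.significant_cell_types
        lines = ["Sex-stratified cell-composition analysis",
                 "=" * 46,
                 f"cell types: {len(self.table)}   "
                 f"sex-difference FDR < {self.alpha}: {len(sig)}"]
        if sig:
            lines.append("significant: " + ", ".join(sig))
        return "\n".join(lines)


def analyze_composition(scores: pd.DataFrame, meta: pd.DataFrame,
                        comparisons=None, alpha: float = 0.05
                        ) -> CompositionResults:
    """Full composition analysis of a cell-type x sample score table.

    Per cell type: group medians, four-group Kruskal-Wallis, Dunn's post hoc
    pairs, per-sex Cohen's D of PS vs control with variances, the
    male-vs-female z-test, and BH-FDR across cell types.
    """
    meta = meta.set_index("sample_id").loc[scores.columns]
    meta.index.name = "sample_id"
    meta = meta.reset_index()
    groups = group_labels(meta).to_numpy()
    is_group = {g: groups == g for g in GROUPS}
    rows = []
    dunn_tables: dict[str, pd.DataFrame] = {}
    for ct in scores.index:
        vals = scores.loc[ct].to_numpy(float)
        h, kw_p = kruskal_wallis(vals, groups)
        dunn_tables[ct] = dunn_posthoc(vals, groups, comparisons)
        d_m, var_m = cohens_d(vals[is_group["PS_male"]],
                              vals[is_group["Control_male"]])
        d_f, var_f = cohens_d(vals[is_group["PS_female"]],
                              vals[is_group["Control_female"]])
        z, p = effect_size_sex_test(d_m, var_m, d_f, var_f)
        row = {"cell_type": ct, "kw_H": h, "kw_p": kw_p,
               "d_female": d_f, "var_d_female": var_f,
               "d_male": d_m, "var_d_male": var_m,
               "z": z, "p_value": p}
        for g in GROUPS:
            row[f"median_{g}"] = float(np.median(vals[is_group[g]]))
        rows.append(row)
    table = composition_fdr(pd.DataFrame(rows).set_index("cell_type"), alpha)
    return CompositionResults(table=table, dunn=dunn_tables, alpha=alpha)
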