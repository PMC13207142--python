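"""Synthetic multi-study RNA-seq generator with planted, known effects.

The generator emulates the statistical structure of a multi-study skin-biopsy
compendium: several studies with multiplicative batch effects, four groups
(psoriasis/control x male/female), sex-exclusive marker genes (an XIST analog
expressed only in females; EIF1AY, KDM5D, UTY, DDX3Y and RPS4Y1 analogs
expressed only in males), disease genes shared between sexes, sex-unique
disease genes, and sex-by-disease interaction genes.  Every planted effect is
recorded in a :class:`SyntheticTruth` so downstream stages can be tested for
recovery without any external data.

Counts are negative binomial with a common dispersion ``phi``
(variance ``mu + phi * mu**2``).  Per-gene expected logCPM is

    baseline + batch_offset(gene, study) + group_effect(gene, group)

and the expected count is ``lib_size * 2**logcpm / 1e6``.  Batch offsets are
drawn independently per gene and study from N(0, batch_sd), which is exactly
the additive-on-log-scale structure that linear batch correction assumes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import GROUPS, validate_counts

#: The six sex-marker genes, in the fixed feature order used for inference.
MARKER_GENES = ("XIST", "EIF1AY", "KDM5D", "UTY", "DDX3Y", "RPS4Y1")
FEMALE_MARKERS = ("XIST",)
MALE_MARKERS = ("EIF1AY", "KDM5D", "UTY", "DDX3Y", "RPS4Y1")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic compendium.

    Defaults describe a moderate three-study compendium with a slight excess
    of male psoriasis samples (as real psoriasis compendia show), strong
    planted disease effects (|log2FC| = 2, the DEG-calling threshold is 1),
    ten interaction genes, NB dispersion 0.1 (biological CV ~0.32, typical of
    human bulk tissue), and library sizes straddling the 10-million QC
    threshold so the library-size filter is exercised.
    """

    n_studies: int = 3
    samples_per_group_per_study: Mapping[str, int] = field(
        default_factory=lambda: {"PS_male": 8, "PS_female": 5,
                                 "Control_male": 6, "Control_female": 6})
    n_genes: int = 2000
    n_shared_degs: int = 100
    n_female_unique_degs: int = 30
    n_male_unique_degs: int = 30
    n_interaction_genes: int = 10
    deg_log2fc: float = 2.0
    interaction_log2fc: float = 2.0
    batch_sd: float = 0.5
    dispersion: float = 0.1
    lib_size_range: tuple[int, int] = (8_000_000, 30_000_000)
    marker_logcpm_high: float = 8.0
    marker_noise_floor: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        extra = set(self.samples_per_group_per_study) - set(GROUPS)
        if extra:
            raise ValueError(f"unknown groups in samples_per_group_per_study: {extra}")
        if any(n < 0 for n in self.samples_per_group_per_study.values()):
            raise ValueError("group sizes must be >= 0")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        n_planted = (self.n_shared_degs + self.n_female_unique_degs
                     + self.n_male_unique_degs + self.n_interaction_genes)
        if min(self.n_shared_degs, self.n_female_unique_degs,
               self.n_male_unique_degs, self.n_interaction_genes) < 0:
            raise ValueError("planted gene counts must be >= 0")
        if self.n_genes < n_planted + len(MARKER_GENES):
            raise ValueError(
                f"n_genes={self.n_genes} is smaller than the "
                f"{n_planted} planted genes plus {len(MARKER_GENES)} sex markers")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid lib_size_range {self.lib_size_range}")
        if self.batch_sd < 0 or self.marker_noise_floor < 0:
            raise ValueError("batch_sd and marker_noise_floor must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated compendium."""

    marker_genes: dict[str, str]                 # gene -> "female"/"male"
    shared_degs: dict[str, float]                # gene -> planted log2FC (both sexes)
    female_unique_degs: dict[str, float]         # gene -> log2FC in females only
    male_unique_degs: dict[str, float]           # gene -> log2FC in males only
    interaction_genes: dict[str, tuple[float, float]]  # gene -> (male, female) log2FC
    sex_by_sample: dict[str, str]
    batch_offsets: pd.DataFrame                  # genes x studies, log2 scale
    baseline_logcpm: pd.Series
    lib_sizes: pd.Series

    def interaction_delta(self, gene: str) -> float:
        """Planted male-minus-female difference in disease response."""
        m, f = self.interaction_genes[gene]
        return m - f

    def to_json(self, path: str) -> None:
        payload = {
            "marker_genes": self.marker_genes,
            "shared_degs": self.shared_degs,
            "female_unique_degs": self.female_unique_degs,
            "male_unique_degs": self.male_unique_degs,
            "interaction_genes": {g: list(v) for g, v in self.interaction_genes.items()},
            "sex_by_sample": self.sex_by_sample,
            "batch_offsets": self.batch_offsets.to_dict(),
            "baseline_logcpm": self.baseline_logcpm.to_dict(),
            "lib_sizes": {k: int(v) for k, v in self.lib_sizes.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _group_effects(cfg: SimulationConfig, gene_ids: list[str],
                   rng: np.random.Generator):
    """Assign disjoint planted gene sets and their per-group log2 effects."""
    candidates = [g for g in gene_ids if g not in MARKER_GENES]
    n_total = (cfg.n_shared_degs + cfg.n_female_unique_degs
               + cfg.n_male_unique_degs + cfg.n_interaction_genes)
    chosen = rng.choice(len(candidates), size=n_total, replace=False)
    chosen_ids = [candidates[i] for i in chosen]
    i0 = cfg.n_shared_degs
    i1 = i0 + cfg.n_female_unique_degs
    i2 = i1 + cfg.n_male_unique_degs
    shared = chosen_ids[:i0]
    f_only = chosen_ids[i0:i1]
    m_only = chosen_ids[i1:i2]
    inter = chosen_ids[i2:]

    def signs(n):
        return rng.choice([-1.0, 1.0], size=n)

    shared_fc = {g: s * cfg.deg_log2fc for g, s in zip(shared, signs(len(shared)))}
    f_fc = {g: s * cfg.deg_log2fc for g, s in zip(f_only, signs(len(f_only)))}
    m_fc = {g: s * cfg.deg_log2fc for g, s in zip(m_only, signs(len(m_only)))}
    # Interaction genes: the disease response differs between sexes by
    # exactly interaction_log2fc — one sex responds, the other does not;
    # which sex responds alternates at random.
    inter_fc: dict[str, tuple[float, float]] = {}
    resp_male = rng.random(len(inter)) < 0.5
    for g, male_responds, s in zip(inter, resp_male, signs(len(inter))):
        fc = s * cfg.interaction_log2fc
        inter_fc[g] = (fc, 0.0) if male_responds else (0.0, fc)
    return shared_fc, f_fc, m_fc, inter_fc


def generate_counts(cfg: SimulationConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (counts, metadata, truth) for one synthetic compendium.

    Identical config (including seed) gives byte-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_other = cfg.n_genes - len(MARKER_GENES)
    gene_ids = list(MARKER_GENES) + [f"G{i:06d}" for i in range(n_other)]
    studies = [f"study{k + 1}" for k in range(cfg.n_studies)]

    # Sample sheet: per study, per group.
    rows = []
    for study in studies:
        for group in GROUPS:
            n = int(cfg.samples_per_group_per_study.get(group, 0))
            condition, sex = group.split("_")
            for _ in range(n):
                rows.append((study, condition, sex))
    if not rows:
        raise ValueError("no samples requested")
    meta = pd.DataFrame(rows, columns=["study", "condition", "sex"])
    meta.insert(0, "sample_id",
                [f"{s}_s{i:03d}" for s, i in
                 zip(meta["study"], meta.groupby("study").cumcount())])
    n_samples = len(meta)

    # Baseline abundances, shifted so total expected CPM is 1e6 (logCPM is
    # then interpretable on its usual scale).
    base_raw = rng.normal(3.0, 2.0, size=cfg.n_genes)
    base = base_raw + np.log2(1e6 / np.sum(2.0 ** base_raw))
    noise_logcpm = np.log2(max(cfg.marker_noise_floor, 1e-4))
    for i, g in enumerate(MARKER_GENES):
        base[i] = cfg.marker_logcpm_high if g in FEMALE_MARKERS else noise_logcpm

    shared_fc, f_fc, m_fc, inter_fc = _group_effects(cfg, gene_ids, rng)

    offsets = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_genes, cfg.n_studies))
    offsets[:len(MARKER_GENES), :] = 0.0  # markers carry no batch effect

    lo, hi = cfg.lib_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples)).round()

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    effect = np.zeros((cfg.n_genes, len(GROUPS)))  # columns follow GROUPS order
    col = {g: j for j, g in enumerate(GROUPS)}
    for g, fc in shared_fc.items():
        effect[gene_pos[g], col["PS_male"]] = fc
        effect[gene_pos[g], col["PS_female"]] = fc
    for g, fc in f_fc.items():
        effect[gene_pos[g], col["PS_female"]] = fc
    for g, fc in m_fc.items():
        effect[gene_pos[g], col["PS_male"]] = fc
    for g, (fcm, fcf) in inter_fc.items():
        effect[gene_pos[g], col["PS_male"]] = fcm
        effect[gene_pos[g], col["PS_female"]] = fcf

    study_idx = meta["study"].map({s: k for k, s in enumerate(studies)}).to_numpy()
    group_idx = meta["condition"].str.cat(meta["sex"], sep="_").map(col).to_numpy()

    logcpm = (base[:, None] + offsets[:, study_idx] + effect[:, group_idx])
    # Sex-exclusive markers: overwrite with the sex-specific level.
    is_female = (meta["sex"] == "female").to_numpy()
    for i, g in enumerate(MARKER_GENES):
        high = is_female if g in FEMALE_MARKERS else ~is_female
        logcpm[i, :] = np.where(high, cfg.marker_logcpm_high, noise_logcpm)

    mu = 2.0 ** logcpm * lib[None, :] / 1e6
    r = 1.0 / cfg.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(counts.astype(np.int64), index=gene_ids,
                             columns=meta["sample_id"].to_numpy())
    truth = SyntheticTruth(
        marker_genes={g: ("female" if g in FEMALE_MARKERS else "male")
                      for g in MARKER_GENES},
        shared_degs=shared_fc,
        female_unique_degs=f_fc,
        male_unique_degs=m_fc,
        interaction_genes=inter_fc,
        sex_by_sample=dict(zip(meta["sample_id"], meta["sex"])),
        batch_offsets=pd.DataFrame(offsets, index=gene_ids, columns=studies),
        baseline_logcpm=pd.Series(base, index=gene_ids),
        lib_sizes=pd.Series(lib, index=meta["sample_id"].to_numpy()),
    )
    return validate_counts(counts_df), meta, truth


def hide_sex(meta: pd.DataFrame, sample_ids=None, studies=None) -> pd.DataFrame:
    """Return a copy of metadata with sex set to ``unknown`` for the given
    samples and/or every sample of the given studies (emulating studies that
    did not report sex)."""
    meta = meta.copy()
    mask = pd.Series(False, index=meta.index)
    if sample_ids is not None:
        mask |= meta["sample_id"].isin(set(sample_ids))
    if studies is not None:
        mask |= meta["study"].isin(set(studies))
    meta.loc[mask, "sex"] = "unknown"
    return meta


def generate_enrichment_scores(
    n_cell_types: int,
    group_sizes: Mapping[str, int],
    planted_effects: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    score_sd: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, tuple[float, float]]]:
    """Generate a cell-type x sample enrichment-score table.

    Scores for each cell type are Normal(group mean, ``score_sd``) truncated
    at zero.  ``planted_effects`` maps cell-type name to the (male, female)
    standardized shift (in SD units) of psoriasis vs control for that sex.
    Returns (scores, metadata, truth) where truth records the per-sex
    standardized effect actually planted for every cell type.

    Base means are kept well above zero relative to ``score_sd`` so the
    truncation is negligible and the planted standardized effect is the
    realized one.
    """
    if score_sd < 0:
        raise ValueError("score_sd must be >= 0")
    missing = [g for g in GROUPS if g not in group_sizes]
    if missing:
        raise ValueError(f"group_sizes missing groups: {missing}")
    planted_effects = dict(planted_effects or {})
    rng = np.random.default_rng(seed)
    cell_types = [f"celltype_{i + 1:02d}" for i in range(n_cell_types)]
    unknown = set(planted_effects) - set(cell_types)
    if unknown:
        raise ValueError(f"planted_effects for unknown cell types: {sorted(unknown)}")

    rows = []
    for group in GROUPS:
        condition, sex = group.split("_")
        for i in range(int(group_sizes[group])):
            rows.append((f"{group}_s{i:03d}", "xcell", condition, sex))
    meta = pd.DataFrame(rows, columns=["sample_id", "study", "condition", "sex"])

    base = rng.uniform(0.3, 0.8, size=n_cell_types)
    is_ps = (meta["condition"] == "PS").to_numpy()
    is_male = (meta["sex"] == "male").to_numpy()

    means = np.tile(base[:, None], (1, len(meta)))
    truth: dict[str, tuple[float, float]] = {}
    for i, ct in enumerate(cell_types):
        dm, df_ = planted_effects.get(ct, (0.0, 0.0))
        means[i, is_ps & is_male] += dm * score_sd
        means[i, is_ps & ~is_male] += df_ * score_sd
        truth[ct] = (float(dm), float(df_))

    scores = np.clip(rng.normal(means, score_sd), 0.0, None)
    scores_df = pd.DataFrame(scores, index=cell_types,
                             columns=meta["sample_id"].to_numpy())
    return scores_df, meta, truth
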