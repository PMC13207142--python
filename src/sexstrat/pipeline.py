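"""End-to-end orchestration: simulate/load -> QC -> sex inference ->
normalization -> differential expression with interaction -> MDS ->
cell composition, from a single YAML config, with a machine-readable run
report.

All thresholds the analysis depends on (the 10-million library-size filter,
|log2FC| > 1, adjusted p < 0.05, the 0.5 probability threshold for calling
a sample female) are config keys with those values as defaults.  All
randomness is controlled by config seeds, so re-running with the same
config and inputs reproduces outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import analyze_composition
from .io import (group_labels, read_counts, read_metadata, validate_pairing,
                 write_counts, write_metadata, write_table)
from .linmod import DifferentialExpressionModel
from .mds import mds_embed, remove_batch
from .normalize import filter_library_size, logcpm
from .sexinfer import (SexClassifier, SexInferenceModel, evaluate_classifier,
                       infer_missing_sex)
from .simulate import (SimulationConfig, generate_counts,
                       generate_enrichment_scores, hide_sex)

log = logging.getLogger("sexstrat")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Pipeline configuration; sections mirror the module names."""

    seed: int = 0
    # input: either files ...
    counts_file: str | None = None
    counts_format: str = "tsv"
    metadata_file: str | None = None
    scores_file: str | None = None
    # ... or simulation
    simulate: SimulationConfig | None = None
    hide_sex_studies: list[str] = field(default_factory=list)
    simulate_scores: bool = False
    n_cell_types: int = 64
    score_sd: float = 0.1
    # QC
    min_library_size: int = 10_000_000
    min_count: float = 10.0
    min_total_count: float = 15.0
    # sex inference
    infer_sex: bool = True
    sex_model_file: str | None = None
    sex_n_folds: int = 10
    sex_threshold: float = 0.5
    # differential expression
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    voom_span: float = 0.5
    # MDS
    mds_top_genes: int = 500
    # composition
    composition_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            if "lib_size_range" in sim:
                sim["lib_size_range"] = tuple(sim["lib_size_range"])
            if "samples_per_group_per_study" in sim:
                sim["samples_per_group_per_study"] = dict(
                    sim["samples_per_group_per_study"])
            cfg.simulate = SimulationConfig(**sim)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None and (self.counts_file is None
                                      or self.metadata_file is None):
            raise ValueError("config needs either a 'simulate' section or "
                             "counts_file + metadata_file")
        if self.simulate is not None:
            self.simulate.validate()


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> dict:
    """Run every stage and return the RunReport dict (also written as JSON)."""
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)
        return name

    # ---- input -------------------------------------------------------
    name = stage("input")
    try:
        truth = None
        if config.simulate is not None:
            counts, meta, truth = generate_counts(config.simulate)
            if config.hide_sex_studies:
                meta = hide_sex(meta, studies=config.hide_sex_studies)
        else:
            counts = read_counts(config.counts_file, config.counts_format)
            meta = read_metadata(config.metadata_file)
        counts, meta = validate_pairing(counts, meta)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc
    report["stages"][name] = {"n_genes": int(counts.shape[0]),
                              "n_samples": int(counts.shape[1])}

    # ---- library-size QC --------------------------------------------
    name = stage("library_filter")
    try:
        counts, meta, lib_report = filter_library_size(
            counts, meta, config.min_library_size)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc
    report["stages"][name] = {"threshold": config.min_library_size,
                              "removed": lib_report.removed,
                              "n_samples": int(counts.shape[1])}

    # ---- sex inference ----------------------------------------------
    name = stage("sex_inference")
    n_unknown = int((meta["sex"] == "unknown").sum())
    try:
        clf_info: dict = {"n_unknown": n_unknown, "enabled": config.infer_sex}
        if n_unknown and not config.infer_sex:
            raise ValueError(f"{n_unknown} samples have unknown sex but "
                             "sex inference is disabled")
        if n_unknown:
            if config.sex_model_file:
                clf = SexClassifier.from_json(config.sex_model_file)
                clf_info["model"] = "loaded"
            else:
                sex_model = SexInferenceModel.from_counts(counts, meta)
                results = sex_model.fit(
                    n_folds=config.sex_n_folds, seed=config.seed,
                    threshold=config.sex_threshold)
                clf = results.classifier
                rep = results.evaluate(sex_model.features,
                                       sex_model.labels.to_numpy())
                clf_info.update(model="trained", lambda_=clf.lambda_,
                                train_accuracy=rep.accuracy,
                                train_sensitivity=rep.sensitivity,
                                train_specificity=rep.specificity)
                if outdir:
                    clf.to_json(os.path.join(outdir, "sex_classifier.json"))
            meta = infer_missing_sex(counts, meta, clf)
        report["stages"][name] = clf_info
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc

    # ---- differential expression ------------------------------------
    name = stage("differential_expression")
    try:
        model = DifferentialExpressionModel(
            counts, meta, lfc_threshold=config.lfc_threshold,
            alpha=config.alpha, min_count=config.min_count,
            min_total_count=config.min_total_count,
            voom_span=config.voom_span)
        de = model.fit()
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc
    report["stages"][name] = {
        "n_genes_tested": int(len(de.moderated.post_var)),
        "group_sizes": {g: int(n) for g, n in
                        group_labels(meta).value_counts().items()},
        "lfc_threshold": config.lfc_threshold, "alpha": config.alpha,
        "prior_df": float(de.moderated.d0)
        if np.isfinite(de.moderated.d0) else "inf",
        "deg_counts": de.deg_counts(), "venn": de.venn_counts()}
    if outdir:
        for cname, tab in de.tables.items():
            write_table(tab, os.path.join(outdir, f"de_{cname}.tsv"),
                        index_label="gene_id")
        part = de.partition()
        if len(part):
            write_table(part, os.path.join(outdir, "deg_partition.tsv"),
                        index_label="gene_id")
        with open(os.path.join(outdir, "venn_counts.json"), "w") as fh:
            json.dump(de.venn_counts(), fh, indent=1)

    # ---- MDS ---------------------------------------------------------
    name = stage("mds")
    try:
        lcpm = logcpm(de.model.counts.loc[de.weighted.logcpm.index],
                      de.factors)
        groups = group_labels(meta)
        protected = pd.get_dummies(groups).astype(float)
        corrected = remove_batch(lcpm, meta["study"].to_numpy(), protected)
        embedding = mds_embed(corrected, config.mds_top_genes)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc
    report["stages"][name] = {
        "n_top_genes": len(embedding.genes_used),
        "explained": list(embedding.explained)}
    if outdir:
        coords = embedding.coordinates.copy()
        coords["group"] = groups.loc[coords.index].to_numpy()
        coords["sex"] = meta.set_index("sample_id").loc[coords.index, "sex"]
        coords["study"] = meta.set_index("sample_id").loc[coords.index, "study"]
        write_table(coords, os.path.join(outdir, "mds_coordinates.tsv"),
                    index_label="sample_id")
        embedding.plot(coords["group"],
                       os.path.join(outdir, "mds_groups.png"),
                       title="MDS (batch removed)")

    # ---- cell composition -------------------------------------------
    name = stage("composition")
    comp_info: dict = {"enabled": False}
    try:
        scores = score_meta = None
        if config.scores_file:
            scores = pd.read_csv(config.scores_file, sep="\t", index_col=0)
            score_meta = meta
        elif config.simulate_scores:
            sizes = group_labels(meta).value_counts().to_dict()
            scores, score_meta, _ = generate_enrichment_scores(
                config.n_cell_types, sizes, None, seed=config.seed,
                score_sd=config.score_sd)
        if scores is not None:
            comp = analyze_composition(scores, score_meta,
                                       alpha=config.composition_alpha)
            comp_info = {"enabled": True, "n_cell_types": int(len(comp.table)),
                         "significant": comp.significant_cell_types}
            if outdir:
                write_table(comp.table,
                            os.path.join(outdir, "composition.tsv"),
                            index_label="cell_type")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(name, exc) from exc
    report["stages"][name] = comp_info

    if outdir:
        write_counts(counts, os.path.join(outdir, "counts_filtered.tsv"))
        write_metadata(meta, os.path.join(outdir, "metadata_final.tsv"))
        if truth is not None:
            truth.to_json(os.path.join(outdir, "truth.json"))
        with open(os.path.join(outdir, "run_report.json"), "w") as fh:
            json.dump(report, fh, indent=1)
    return report
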