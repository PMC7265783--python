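"""End-to-end pipeline orchestration from one validated config.

Stages: simulate -> fit-networks -> score-samples -> compare-networks ->
stratify -> train-drugs -> predict-patients. Every stage records its
parameters and outputs in ``manifest.json``; all randomness descends from the
single global seed through a fixed per-stage counter scheme, so reruns with
the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from . import io as pio
from .graphical_regression import (
    CancerNetwork,
    MCMCSettings,
    aggregate_pathway_scores,
    call_edges,
    fit_cancer_network,
    score_samples,
)
from .netcompare import (
    connectivity_score,
    edge_consistency,
    link_lineages,
    random_cs_null,
)
from .stratify import (
    aberration_scores,
    avatar_links,
    cluster_samples,
    pairwise_correlations,
)
from .drugpredict import predict_patients, train_drug_models
from .synthetic import default_config, make_fixture_study

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "fit_networks",
    "score_samples",
    "compare_networks",
    "stratify",
    "train_drugs",
    "predict_patients",
)


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: Literal["default"] = "default"
    n_cases: int | None = Field(default=None, ge=10)
    n_baseline: int | None = Field(default=None, ge=10)
    shift: float | None = Field(default=None, ge=0)


class InputsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    expression: str
    annotations: str
    pathways: str
    drug_panel: str | None = None
    drug_mode: Literal["continuous", "binary"] = "binary"


class MCMCBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    iterations: int = Field(default=20_000, ge=100)
    burn_in: int = Field(default=5_000, ge=10)
    null_iterations: int = Field(default=2_000, ge=100)
    null_burn_in: int = Field(default=500, ge=10)


class ThresholdsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ppi: float = Field(default=0.5, gt=0, lt=1)
    avatar_r: float = Field(default=0.9, gt=0, lt=1)
    avatar_fraction: float = Field(default=0.75, gt=0, lt=1)
    link_cutoff: float = Field(default=0.9, gt=0, lt=1)
    auc_cutoff: float = Field(default=0.85, gt=0, le=1)
    min_profiles: int = Field(default=10, ge=2)
    tail_cutoff: float = Field(default=1.0, gt=0)


class ClusterBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_max: int = Field(default=10, ge=2)
    gap_B: int = Field(default=50, ge=2)


class BartBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    trees: int = Field(default=20, ge=2)
    draws: int = Field(default=500, ge=50)
    burn: int = Field(default=100, ge=10)


class PipelineConfig(BaseModel):
    """Validated pipeline settings; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "proteopath_out"
    simulate: SimulateBlock | None = None
    inputs: InputsBlock | None = None
    null_reps: int = Field(default=1000, ge=1)
    mcmc: MCMCBlock = MCMCBlock()
    thresholds: ThresholdsBlock = ThresholdsBlock()
    cluster: ClusterBlock = ClusterBlock()
    bart: BartBlock = BartBlock()
    lineage_map: dict[str, str] | None = None

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + STAGES.index(stage)) % (2**31 - 1)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and strictly validate a YAML or JSON config file."""
    import yaml

    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    try:
        cfg = PipelineConfig(**data)
    except PydanticValidationError as exc:
        raise ValueError(f"invalid pipeline config: {exc}") from exc
    if cfg.simulate is None and cfg.inputs is None:
        raise ValueError("config must provide either a simulate block or an inputs block")
    if cfg.inputs is not None:
        for key in ("expression", "annotations", "pathways"):
            p = getattr(cfg.inputs, key)
            if not Path(p).exists():
                raise ValueError(f"input file does not exist: {key}={p}")
    return cfg


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data: dict = {"stages": {}}

    def record(self, stage: str, params: dict, outputs: list[str], t0: float) -> None:
        self.data["stages"][stage] = {
            "params": params,
            "outputs": outputs,
            "runtime_s": round(time.time() - t0, 3),
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))

    def fail(self, stage: str, err: Exception) -> None:
        self.data["stages"][stage] = {"failed": True, "error": str(err)}
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order, writing outputs and a manifest to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    stage = "simulate"
    try:
        study, catalog, panel = _stage_inputs(config, outdir, manifest)
        stage = "fit_networks"
        networks = _stage_fit_networks(config, study, catalog, outdir, manifest)
        stage = "score_samples"
        scores = _stage_scores(config, study, catalog, networks, outdir, manifest)
        stage = "compare_networks"
        conn = _stage_compare(config, study, catalog, networks, outdir, manifest)
        stage = "stratify"
        ab, links = _stage_stratify(config, study, scores, outdir, manifest)
        stage = "train_drugs"
        models = _stage_drugs(config, study, ab, panel, outdir, manifest)
        stage = "predict_patients"
        _stage_predict(config, study, ab, links, models, outdir, manifest)
    except Exception as exc:  # record the failure, then re-raise
        manifest.fail(stage, exc)
        raise
    return outdir


# ---------------------------------------------------------------------------


def _stage_inputs(config, outdir: Path, manifest: _Manifest):
    t0 = time.time()
    if config.inputs is not None:
        study = pio.read_expression_study(config.inputs.expression, config.inputs.annotations)
        catalog = pio.read_pathway_catalog(config.inputs.pathways)
        catalog.validate_against(study)
        panel = (
            pio.read_drug_panel(config.inputs.drug_panel, config.inputs.drug_mode)
            if config.inputs.drug_panel
            else None
        )
        manifest.record("inputs", config.inputs.model_dump(), [], t0)
        return study, catalog, panel

    sim = config.simulate
    sim_cfg = default_config()
    if sim.n_cases is not None:
        for plan in sim_cfg.lineages:
            plan.n_cases = sim.n_cases
    if sim.n_baseline is not None:
        for plan in sim_cfg.lineages:
            plan.n_baseline = sim.n_baseline
    if sim.shift is not None:
        sim_cfg.shift = sim.shift
    bundle = make_fixture_study(sim_cfg, seed=config.stage_seed("simulate"))
    pio.write_expression_study(bundle.study, outdir / "expression.tsv", outdir / "annotations.tsv")
    pio.write_pathway_catalog(bundle.catalog, outdir / "pathways.gmt")
    pio.write_drug_panel(bundle.panel, outdir / "drug_panel.tsv")
    bundle.truth.to_json(outdir / "ground_truth.json")
    manifest.record(
        "simulate",
        {"seed": config.stage_seed("simulate"), **sim.model_dump()},
        ["expression.tsv", "annotations.tsv", "pathways.gmt", "drug_panel.tsv", "ground_truth.json"],
        t0,
    )
    return bundle.study, bundle.catalog, bundle.panel


def _stage_fit_networks(config, study, catalog, outdir: Path, manifest: _Manifest):
    t0 = time.time()
    seed0 = config.stage_seed("fit_networks")
    networks: dict[tuple[str, str], CancerNetwork] = {}
    for li, lineage in enumerate(study.lineages()):
        for pi_, (pathway, proteins) in enumerate(catalog.pathways.items()):
            fit = study.fit_slice(lineage, proteins=proteins)
            mc = MCMCSettings(
                iterations=config.mcmc.iterations,
                burn_in=config.mcmc.burn_in,
                seed=(seed0 + li * 101 + pi_) % (2**31 - 1),
            )
            networks[(lineage, pathway)] = fit_cancer_network(fit, mc, pathway=pathway)
    pio.write_network_edges(networks.values(), outdir / "networks.tsv")
    manifest.record(
        "fit_networks",
        {"iterations": config.mcmc.iterations, "burn_in": config.mcmc.burn_in, "seed": seed0},
        ["networks.tsv"],
        t0,
    )
    return networks


def _stage_scores(config, study, catalog, networks, outdir: Path, manifest: _Manifest):
    t0 = time.time()
    scores = {}
    for (lineage, pathway), net in networks.items():
        sl = study.case_slice(lineage=lineage, proteins=net.proteins)
        if sl.n_samples == 0:
            continue
        ss = score_samples(net, sl)
        scores[(lineage, pathway)] = aggregate_pathway_scores(ss)
    pio.write_pathway_scores(scores.values(), outdir / "scores.tsv")
    manifest.record(
        "score_samples",
        {"tail_cutoff": config.thresholds.tail_cutoff},
        ["scores.tsv"],
        t0,
    )
    return scores


def _stage_compare(config, study, catalog, networks, outdir: Path, manifest: _Manifest):
    t0 = time.time()
    seed0 = config.stage_seed("compare_networks")
    table = edge_consistency(list(networks.values()), threshold=config.thresholds.ppi)
    table.to_csv(outdir / "edge_consistency.tsv", sep="\t", index=False)

    pool = catalog.proteins()
    rows = []
    ann = study.annotations
    for i, ((lineage, pathway), net) in enumerate(sorted(networks.items())):
        obs = connectivity_score(
            call_edges(net, config.thresholds.ppi), len(net.proteins), net.proteins
        )
        fit = study.fit_slice(lineage)
        res = random_cs_null(
            fit,
            len(net.proteins),
            pool,
            observed_cs=obs,
            n_reps=config.null_reps,
            seed=(seed0 + i) % (2**31 - 1),
            mcmc=MCMCSettings(
                iterations=config.mcmc.null_iterations, burn_in=config.mcmc.null_burn_in
            ),
            threshold=config.thresholds.ppi,
            lineage=lineage,
            pathway=pathway,
        )
        rows.append(
            {
                "lineage": lineage,
                "system": net.system,
                "pathway": pathway,
                "cs": obs,
                "random_cs_proportion": res.random_cs_proportion,
            }
        )
    conn = pd.DataFrame(rows)
    conn.to_csv(outdir / "connectivity.tsv", sep="\t", index=False, float_format=pio.FLOAT_FORMAT)
    trip = link_lineages(conn, cutoff=config.thresholds.link_cutoff)
    trip.to_csv(outdir / "triplets.tsv", sep="\t", index=False)
    manifest.record(
        "compare_networks",
        {"n_reps": config.null_reps, "link_cutoff": config.thresholds.link_cutoff, "seed": seed0},
        ["edge_consistency.tsv", "connectivity.tsv", "triplets.tsv"],
        t0,
    )
    return conn


def _stage_stratify(config, study, scores, outdir: Path, manifest: _Manifest):
    t0 = time.time()
    ab = aberration_scores(list(scores.values()))
    ann = study.annotations.loc[ab.index]
    ab.to_csv(outdir / "aberration.tsv", sep="\t", float_format=pio.FLOAT_FORMAT, index_label="sample_id")

    pat = ab.loc[ann["system"] == "patient"]
    cl = ab.loc[ann["system"] == "cell_line"]
    links = pd.DataFrame()
    if len(pat) and len(cl):
        corr = pairwise_correlations(pat, cl)
        links = avatar_links(
            corr,
            ann["lineage"],
            ann["lineage"],
            r_threshold=config.thresholds.avatar_r,
            pair_fraction=config.thresholds.avatar_fraction,
        )
        links.to_csv(outdir / "avatar_links.tsv", sep="\t", index=False, float_format=pio.FLOAT_FORMAT)

    result = cluster_samples(
        ab,
        k_max=config.cluster.k_max,
        gap_B=config.cluster.gap_B,
        seed=config.stage_seed("stratify"),
    )
    result.labels.to_frame().to_csv(outdir / "clusters.tsv", sep="\t", index_label="sample_id")
    result.gap_curve.to_csv(outdir / "gap_curve.tsv", sep="\t", index=False, float_format=pio.FLOAT_FORMAT)
    _write_newick(result, outdir / "dendrogram.nwk")
    manifest.record(
        "stratify",
        {"k_max": config.cluster.k_max, "gap_B": config.cluster.gap_B, "K": result.K},
        ["aberration.tsv", "avatar_links.tsv", "clusters.tsv", "gap_curve.tsv", "dendrogram.nwk"],
        t0,
    )
    return ab, links


def _write_newick(result, path: Path) -> None:
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(result.linkage_matrix)
    ids = list(result.labels.index)

    def rec(node):
        if node.is_leaf():
            return ids[node.id]
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    Path(path).write_text(rec(tree) + ";\n")


def _stage_drugs(config, study, ab, panel, outdir: Path, manifest: _Manifest):
    t0 = time.time()
    if panel is None:
        manifest.record("train_drugs", {"skipped": "no drug panel"}, [], t0)
        return []
    ann = study.annotations
    cl_ab = ab.loc[ab.index.intersection(panel.values.index)]
    models = train_drug_models(
        cl_ab,
        panel,
        ann["lineage"],
        trees=config.bart.trees,
        draws=config.bart.draws,
        burn=config.bart.burn,
        seed=config.stage_seed("train_drugs"),
    )
    from .drugpredict import pathway_pair_synergy, top_predictor_summary

    pd.DataFrame(
        [
            {"lineage": m.lineage, "drug": m.drug, "n_profiles": m.n_profiles, "cv_auc": m.cv_auc}
            for m in models
        ]
    ).to_csv(outdir / "drug_auc.tsv", sep="\t", index=False, float_format=pio.FLOAT_FORMAT)
    imp = pd.DataFrame(
        [
            {"lineage": m.lineage, "drug": m.drug, **m.importance.to_dict()}
            for m in models
        ]
    )
    imp.to_csv(outdir / "importance.tsv", sep="\t", index=False, float_format=pio.FLOAT_FORMAT)
    top_predictor_summary(models, auc_cutoff=config.thresholds.auc_cutoff).to_csv(
        outdir / "top_predictors.tsv", sep="\t", index=False, float_format=pio.FLOAT_FORMAT
    )
    pathway_pair_synergy(models, auc_cutoff=config.thresholds.auc_cutoff).to_csv(
        outdir / "synergy_pairs.tsv", sep="\t", index=False
    )
    manifest.record(
        "train_drugs",
        {"trees": config.bart.trees, "draws": config.bart.draws, "n_models": len(models)},
        ["drug_auc.tsv", "importance.tsv", "top_predictors.tsv", "synergy_pairs.tsv"],
        t0,
    )
    return models


def _stage_predict(config, study, ab, links, models, outdir: Path, manifest: _Manifest):
    t0 = time.time()
    if not models:
        manifest.record("predict_patients", {"skipped": "no drug models"}, [], t0)
        return
    ann = study.annotations
    lineage_map = config.lineage_map
    if lineage_map is None:
        lineage_map = {}
        if isinstance(links, pd.DataFrame) and len(links):
            for _, row in links[links["linked"]].iterrows():
                lineage_map.setdefault(row["patient_lineage"], row["cellline_lineage"])
    pat_ab = ab.loc[ann.loc[ab.index, "system"] == "patient"]
    rows = []
    for m in models:
        try:
            probs, rate = predict_patients(m, pat_ab, ann["lineage"], lineage_map)
        except Exception as exc:
            logger.info("prediction skipped for %s/%s: %s", m.lineage, m.drug, exc)
            continue
        for sid, pr in probs.items():
            rows.append(
                {
                    "sample_id": sid,
                    "lineage": ann.loc[sid, "lineage"],
                    "drug": m.drug,
                    "model_lineage": m.lineage,
                    "probability": pr,
                    "cohort_response_rate": rate,
                }
            )
    pd.DataFrame(
        rows,
        columns=["sample_id", "lineage", "drug", "model_lineage", "probability", "cohort_response_rate"],
    ).to_csv(outdir / "patient_predictions.tsv", sep="\t", index=False, float_format=pio.FLOAT_FORMAT)
    manifest.record(
        "predict_patients",
        {"lineage_map": lineage_map},
        ["patient_predictions.tsv"],
        t0,
    )
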