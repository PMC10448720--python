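"""End-to-end orchestration of the pipeline stages.

Each stage communicates with the next only through its declared file
interface; ``run_all`` wires them together in memory and writes every
stage's artifact plus a manifest recording the configuration hash and the
per-stage seeds.  Reruns with identical config and inputs are
bit-identical for the deterministic stages (all of them: randomness enters
only through seeds derived from the config).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from ketox import aop_model, assay_select, chem, curves, io, ke_model, tk_overlay
from ketox.config import PipelineConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending detail."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _stage(stage_name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - deliberately annotate and rethrow
                raise StageError(stage_name, str(exc)) from exc

        wrapper.__name__ = fn.__name__
        return wrapper

    return decorate


@_stage("load")
def load_inputs(config: PipelineConfig) -> dict:
    fits = io.read_curve_fits(config.curve_fits)
    labels = io.read_labels(config.labels)
    assignments = io.read_ke_assignments(config.ke_map)
    css = io.read_css(config.css) if config.css else []
    smiles = io.read_smiles(config.smiles) if config.smiles else {}
    return {
        "best_fits": io.best_fits(fits),
        "labels": io.labels_frame(labels),
        "assignments": assignments,
        "css": pd.Series({r.chem_id: r.css_95 for r in css}, dtype=float),
        "smiles": smiles,
    }


@_stage("select-assays")
def stage_select(best_fits, labels, fdr: float) -> assay_select.AssaySelection:
    hit_table = assay_select.hit_call_table(best_fits)
    return assay_select.select_relevant_assays(hit_table, labels, fdr=fdr)


@_stage("ke-scores")
def stage_ke_scores(best_fits, assignments, selected: set, labels, config: PipelineConfig):
    grid = curves.build_grid(config.points_per_decade)
    chem_ids = sorted({c for c, _ in best_fits})
    members = {
        ke: [a for a in assays if a in selected]
        for ke, assays in io.ke_groups(assignments).items()
    }
    members = {ke: assays for ke, assays in members.items() if assays}
    assay_ids = sorted({a for assays in members.values() for a in assays})
    surfaces = curves.build_surfaces(best_fits, grid, chem_ids, assay_ids)
    score_frame = ke_model.score_table(members, surfaces, chem_ids, grid, mode=config.ke_aggregation)
    roc = ke_model.roc_summary(score_frame, labels)
    return grid, members, surfaces, score_frame, roc


@_stage("tk-overlay")
def stage_overlay(members, surfaces, grid, css: pd.Series, config: PipelineConfig):
    activities = []
    for ke_id, assays in members.items():
        chems_with_css = [c for c in css.index]
        curves_frame = ke_model.compose_ke_curves(ke_id, assays, surfaces, chems_with_css, mode=config.ke_aggregation)
        for chem_id, row in curves_frame.iterrows():
            activities.append(
                tk_overlay.realized_ke_score(str(chem_id), ke_id, row.to_numpy(), grid, float(css[chem_id]))
            )
    flagged = tk_overlay.flag_unrealizable(activities, threshold=config.unrealizable_threshold)
    return activities, flagged


@_stage("cluster")
def stage_cluster(smiles: dict, labels, scaled_scores, cutoff: float):
    fps = {c: chem.fingerprint(s, chem_id=c) for c, s in smiles.items()}
    clusters = chem.butina_cluster(fps, similarity_cutoff=cutoff)
    enrichment = chem.enriched_clusters(clusters, labels, scaled_scores)
    return clusters, enrichment


@_stage("fit-models")
def stage_models(scaled_scores, labels, css, descriptors, config: PipelineConfig):
    if scaled_scores.empty:
        return None, None, None
    # both models are trained on the same chemical set: labeled chemicals
    # that also have Css and structure whenever those inputs are available
    eligible = labels.index[labels["hepatotoxic"].notna()]
    if css is not None and len(css):
        eligible = eligible.intersection(css.dropna().index)
    if descriptors is not None and len(descriptors):
        eligible = eligible.intersection(descriptors.index)
    balanced = aop_model.undersample_balance(
        labels.loc[eligible, "hepatotoxic"], seed=config.stage_seed("undersample")
    )
    sub_labels = labels.loc[[c for c in balanced if c in labels.index]]
    X1, y1 = aop_model.build_features(scaled_scores.reindex(sub_labels.index).fillna(0.0), sub_labels, model_id=1)
    result1 = aop_model.loo_cv(
        X1, y1, model_id=1, C=config.logistic_C, penalize=config.logistic_penalize, threshold=config.threshold
    )
    result2 = comparison = None
    if css is not None and len(css) and descriptors is not None and len(descriptors):
        X2, y2 = aop_model.build_features(
            scaled_scores.reindex(sub_labels.index).fillna(0.0),
            sub_labels,
            model_id=2,
            css=css,
            descriptors=descriptors,
        )
        if len(X2) >= 4 and y2.nunique() == 2:
            result2 = aop_model.loo_cv(
                X2, y2, model_id=2, C=config.logistic_C, penalize=config.logistic_penalize, threshold=config.threshold
            )
            comparison = aop_model.compare_models(result1, result2)
    return result1, result2, comparison


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and write the artifact directory.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = load_inputs(config)
    labels = data["labels"]

    selection = stage_select(data["best_fits"], labels, config.fdr)
    selection.to_frame().to_csv(out_dir / "assay_selection.csv", index=False)
    logger.info("selected %d assays (union)", len(selection.union))

    grid, members, surfaces, score_frame, roc = stage_ke_scores(
        data["best_fits"], data["assignments"], selection.union, labels, config
    )
    score_frame.to_csv(out_dir / "ke_scores.csv", index=False)
    roc.to_csv(out_dir / "ke_roc.csv", index=False)
    scaled_wide = ke_model.scores_wide(score_frame)

    if len(data["css"]):
        activities, flagged = stage_overlay(members, surfaces, grid, data["css"], config)
        tk_overlay.overlay_table(activities).to_csv(out_dir / "tk_overlay.csv", index=False)
        (out_dir / "unrealizable.json").write_text(json.dumps(flagged, indent=2))

    if data["smiles"]:
        clusters, enrichment = stage_cluster(data["smiles"], labels, scaled_wide, config.similarity_cutoff)
        enrichment.to_csv(out_dir / "cluster_summary.csv", index=False)
        chem.cluster_members_table(clusters, enrichment).to_csv(out_dir / "clusters.csv", index=False)
        descriptors = chem.descriptor_table(data["smiles"])
        descriptors.to_csv(out_dir / "descriptors.csv")
    else:
        descriptors = None

    result1, result2, comparison = stage_models(
        scaled_wide, labels, data["css"] if len(data["css"]) else None, descriptors, config
    )
    metrics = {}
    predictions = []
    for result in (result1, result2):
        if result is None:
            continue
        metrics[f"model_{result.model_id}"] = result.metrics()
        predictions.append(aop_model.prediction_table(result))
        result.coefficients.to_csv(out_dir / f"coefficients_model{result.model_id}.csv", index=False)
    if predictions:
        pd.concat(predictions, ignore_index=True).to_csv(out_dir / "predictions.csv", index=False)
    if comparison is not None:
        metrics["comparison"] = comparison
    (out_dir / "model_metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in ("undersample",)},
        "artifacts": sorted(p.name for p in out_dir.iterdir() if p.name != "manifest.json"),
        "n_chemicals": int(labels.shape[0]),
        "n_assays_selected": len(selection.union),
        "n_kes": len(members),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
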