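"""End-to-end orchestration: simulate/load -> peel -> split -> select ->
train -> evaluate -> aggregate, with every stage's artifacts and seeds
written so runs are fully reproducible.

A single seed block fans out to per-stage seeds through
:func:`numpy.random.SeedSequence.spawn`, so any stage can be re-run in
isolation with the seed recorded in its artifact.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import evaluation, level_models, vote_select
from .cascade import DEFAULT_MERGE_MAP, build_levels, route_predict, split_level
from .data_io import (
    FEATURES,
    LABEL,
    encode_features,
    load_feature_table,
    save_bundle,
    write_feature_table,
)
from .synthetic_cohort import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "stage_seeds", "run_pipeline"]

logger = logging.getLogger("oncocascade")

_STAGES = ("simulate", "split", "select", "train")


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan one seed out to named per-stage seeds (each < 2**31)."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class PipelineConfig:
    """One-command replication settings; defaults mirror the deployed
    system (vote threshold 3, tenfold CV, 90/10 stratified split)."""

    input_path: str | None = None  # None -> simulate a cohort
    cohort: CohortConfig | None = None
    merge_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_MERGE_MAP))
    vote_threshold: int = 3
    cv_folds: int = 10
    fit_policy: str = "refit-all"
    test_fraction: float = 0.10
    route_threshold: float = 0.5
    paper_faithful_selection: bool = False  # select on the full level before splitting
    seed: int = 17
    outdir: str | Path = "pipeline_out"


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full cascade pipeline and persist all artifacts.

    Returns a dict with the cohort, levels, tallies, fold metrics,
    per-level test reports, the overall (macro-averaged) report, and the
    trained models.  Reports are written deterministically: reruns with
    the same config are byte-identical (timings go to the log only).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s starting", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s finished in %.2fs", name, timings[name])

    # --- cohort -----------------------------------------------------------
    stage("simulate")
    if config.input_path:
        table = load_feature_table(config.input_path)
    else:
        cohort_cfg = config.cohort or CohortConfig(seed=seeds["simulate"])
        table = generate_cohort(cohort_cfg)
        sidecar = {"planted_features": cohort_cfg.planted_features(), "seed": cohort_cfg.seed}
        _dump_json(sidecar, out / "cohort_truth.json")
    write_feature_table(table, out / "cohort.csv")
    done("simulate")

    X_all = encode_features(table)
    cohort = X_all.assign(**{LABEL: table[LABEL].astype(str).to_numpy()})

    # --- peel + split -----------------------------------------------------
    stage("split")
    levels = build_levels(cohort, config.merge_map)
    levels = [
        split_level(lv, config.test_fraction, seed=seeds["split"] + lv.index)
        for lv in levels
    ]
    levels_dir = out / "levels"
    levels_dir.mkdir(exist_ok=True)
    for lv in levels:
        ldir = levels_dir / f"L{lv.index}"
        ldir.mkdir(exist_ok=True)
        train = lv.table.iloc[lv.train_idx].assign(y=lv.y[lv.train_idx])
        test = lv.table.iloc[lv.test_idx].assign(y=lv.y[lv.test_idx])
        train.to_csv(ldir / "train.csv", index=False)
        test.to_csv(ldir / "test.csv", index=False)
        _dump_json(lv.describe(), ldir / "level.json")
    done("split")

    # --- feature selection ------------------------------------------------
    stage("select")
    feature_cols = [c for c in X_all.columns]
    tallies: dict[int, vote_select.VoteTally] = {}
    selected: dict[int, list[str]] = {}
    for lv in levels:
        if config.paper_faithful_selection:
            # published ordering: selection on the full level before the split
            Xl, yl = lv.table[feature_cols], lv.y
        else:
            Xl, yl = lv.table[feature_cols].iloc[lv.train_idx], lv.y[lv.train_idx]
        tally = vote_select.majority_vote_select(
            Xl, yl, threshold=config.vote_threshold, seed=seeds["select"]
        )
        tallies[lv.index] = tally
        feats = tally.selected or list(
            tally.votes[tally.votes == tally.votes.max()].index
        )
        selected[lv.index] = feats
        tally.to_json(levels_dir / f"L{lv.index}" / "tally.json")
    done("select")

    # --- training ---------------------------------------------------------
    stage("train")
    models: dict[int, object] = {}
    fold_metrics: dict[int, level_models.FoldMetrics] = {}
    for lv in levels:
        feats = selected[lv.index]
        Xtr = lv.table[feats].iloc[lv.train_idx]
        ytr = lv.y[lv.train_idx]
        spec_model = level_models.make_level_model(
            lv.index, random_state=seeds["train"], fallback=("rf",)
        )
        fm, final = level_models.crossvalidate(
            spec_model, Xtr, ytr, k=config.cv_folds,
            seed=seeds["train"], policy=config.fit_policy,
        )
        models[lv.index] = final
        fold_metrics[lv.index] = fm
        fm.to_frame().to_csv(levels_dir / f"L{lv.index}" / "cv_metrics.csv")
    done("train")

    # --- evaluation -------------------------------------------------------
    reports: dict[int, evaluation.MetricsReport] = {}
    for lv in levels:
        feats = selected[lv.index]
        Xte = lv.table[feats].iloc[lv.test_idx]
        yte = lv.y[lv.test_idx]
        model = models[lv.index]
        score = model.predict_proba(Xte)[:, 1]
        rep = evaluation.metrics_from_predictions(yte, model.predict(Xte), score, scope="level")
        reports[lv.index] = rep
        _dump_json(rep.to_dict(), levels_dir / f"L{lv.index}" / "test_metrics.json")
        evaluation.roc_points(yte, score).to_csv(
            levels_dir / f"L{lv.index}" / "roc_points.csv", index=False
        )
    overall = evaluation.aggregate_levels(list(reports.values()))
    _dump_json(overall.to_dict(), out / "overall_metrics.json")

    per_level = pd.DataFrame(
        {i: r.to_series() for i, r in reports.items()}
    ).T.rename_axis("level")
    per_level.to_csv(out / "level_test_metrics.csv")

    # --- bundle -----------------------------------------------------------
    levels_meta = [
        {
            "index": lv.index,
            "positive_label": lv.positive_label,
            "negative_pool": sorted(lv.negative_pool),
            "features": selected[lv.index],
        }
        for lv in levels
    ]
    save_bundle(
        out / "bundle",
        models=models,
        tallies={i: t.to_dict() for i, t in tallies.items()},
        reports={"overall": overall.to_dict(), "levels": {i: r.to_dict() for i, r in reports.items()}},
        metadata={
            "seed": config.seed,
            "stage_seeds": seeds,
            "vote_threshold": config.vote_threshold,
            "cv_folds": config.cv_folds,
            "fit_policy": config.fit_policy,
            "route_threshold": config.route_threshold,
            "levels": levels_meta,
        },
    )
    logger.info("stage timings: %s", {k: round(v, 2) for k, v in timings.items()})
    return {
        "table": table,
        "levels": levels,
        "levels_meta": levels_meta,
        "tallies": tallies,
        "selected": selected,
        "models": models,
        "fold_metrics": fold_metrics,
        "level_reports": reports,
        "overall": overall,
        "outdir": out,
    }


def predict_with_bundle(bundle: dict, X: pd.DataFrame, threshold: float | None = None):
    """Route samples through a loaded bundle's per-level models."""
    meta = bundle["manifest"]["metadata"]
    models = [bundle["models"][i] for i in sorted(bundle["models"])]
    levels_meta = meta["levels"]
    thr = meta.get("route_threshold", 0.5) if threshold is None else threshold
    return route_predict(models, levels_meta, X, threshold=thr)
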