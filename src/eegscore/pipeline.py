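"""End-to-end orchestration: simulate -> preprocess -> features -> select
-> train -> report, with every stage output written to a run directory
and a manifest recording the config hash, seed and stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as eio
from .config import PipelineConfig
from .performance import summarize
from .prediction import evaluate_cv, group_prediction_summary
from .preprocessing import clean_recording
from .recording import EEGRecording, ScoreRecord
from .selection import correlation_select, friedman_factor_tests, group_ttest_grid
from .spectral import attach_scores, build_feature_matrix
from .synthetic import CohortSpec, generate_cohort_recordings, generate_scores, inject_artifacts

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def simulate_stage(config: PipelineConfig) -> tuple[list[EEGRecording], list[ScoreRecord]]:
    """Generate the cohort: recordings (with injected artifacts) and scores.

    Scores are derived from the *clean* signals' features so the score
    model stays exact; artifacts only challenge the cleaning stage.
    """
    spec = CohortSpec(
        n_text=config.n_text,
        n_video=config.n_video,
        seed=config.seed,
        artifact_rate=config.artifact_rate,
        artifact_amplitude=config.artifact_amplitude,
    )
    recordings = generate_cohort_recordings(spec)
    fm_clean = build_feature_matrix(recordings)
    scores = generate_scores(spec, fm_clean)
    if spec.artifact_rate > 0:
        recordings = [
            inject_artifacts(
                rec, spec.artifact_rate, spec.artifact_amplitude, seed=config.seed * 1000 + i
            )[0]
            for i, rec in enumerate(recordings)
        ]
    return recordings, scores


def run_pipeline(config: PipelineConfig, out_dir: Path) -> dict:
    """Run every stage in order; returns the manifest (also written to disk)."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical_yaml().encode()).hexdigest(),
        "counts": {},
    }
    config.save(out_dir / "config.yaml")

    stage = "simulate"
    try:
        recordings, scores = simulate_stage(config)
        eio.write_scores_csv(scores, out_dir / "scores.csv")
        if config.write_eeg:
            eeg_dir = out_dir / "eeg"
            for rec in recordings:
                eio.write_recording_edf(rec, eeg_dir / f"{rec.participant_id}.edf")
        manifest["counts"]["recordings"] = len(recordings)
        manifest["counts"]["score_records"] = len(scores)
        logger.info("simulate: %d recordings, %d score records", len(recordings), len(scores))

        stage = "preprocess"
        pp = config.preprocessing
        cleaned = [
            clean_recording(
                rec,
                low=pp.low,
                high=pp.high,
                order=pp.order,
                kappa=pp.kappa,
                calib_segment=pp.calib_segment,
                window_s=pp.window_s,
            )
            for rec in recordings
        ]

        stage = "features"
        fm = build_feature_matrix(cleaned, scores)
        fm.to_csv(out_dir / "features.csv", index=False)
        n_features = fm.shape[1] - 5
        manifest["counts"]["rows"] = int(fm.shape[0])
        manifest["counts"]["features"] = int(n_features)
        logger.info("features: %d rows x %d feature columns", fm.shape[0], n_features)

        stage = "select"
        grid = group_ttest_grid(fm, alpha=config.alpha)
        grid.to_csv(out_dir / "ttest_grid.csv", index=False)
        selection = correlation_select(fm, alpha=config.alpha)
        sel_table = selection.significant.copy()
        sel_table["rank"] = range(1, len(sel_table) + 1)
        sel_table["status"] = [
            "pruned" if f in selection.redundant else "kept" for f in sel_table["feature"]
        ]
        sel_table.to_csv(out_dir / "selection.csv", index=False)
        manifest["counts"]["ttest_entries"] = int(len(grid))
        manifest["counts"]["correlation_tests"] = int(selection.n_tests)
        manifest["counts"]["selected"] = len(selection.kept)
        logger.info(
            "select: %d t-tests, %d correlation tests, %d kept features",
            len(grid), selection.n_tests, len(selection.kept),
        )
        try:
            factors = friedman_factor_tests(
                fm, ["score", "exam_time_s"] + selection.kept[: config.model.K]
            )
            factors.to_csv(out_dir / "factor_tests.csv", index=False)
        except ValueError as exc:  # unbalanced cohorts have no factor layout
            logger.warning("factor tests skipped: %s", exc)

        stage = "train"
        if not selection.kept:
            raise ValueError("no features selected; cannot train")
        K = min(config.model.K, len(selection.kept))
        if config.model.K > len(selection.kept):
            logger.warning(
                "K reduced from %d to %d (selected features)", config.model.K, K
            )
        cv = evaluate_cv(
            fm,
            selection.kept,
            K=K,
            n_iter=config.model.n_iter,
            train_frac=config.model.train_frac,
            seed=config.seed,
        )
        cv.iterations.to_csv(out_dir / "cv_iterations.csv", index=False)
        best = cv.best_k()
        group_summary = group_prediction_summary(
            fm,
            selection.kept,
            k=best,
            n_subsamples=config.model.n_subsamples,
            seed=config.seed,
            train_frac=config.model.train_frac,
        )
        group_summary.records.to_csv(out_dir / "group_prediction_records.csv", index=False)
        manifest["counts"]["train_size"] = cv.train_size
        manifest["counts"]["test_size"] = cv.test_size
        logger.info("train: %d/%d split, best k=%d", cv.train_size, cv.test_size, best)

        stage = "report"
        perf = summarize(scores)
        perf.table().to_csv(out_dir / "performance_table.csv")
        report = {
            "accuracies": {str(k): v for k, v in cv.accuracies.items()},
            "best_k": best,
            "selected_features": selection.kept,
            "group_prediction": group_summary.per_group.to_dict(),
            "improvements": perf.improvements.to_dict(),
        }
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
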