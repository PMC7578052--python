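"""Stage orchestration shared by the CLI and the test harness."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import associate_all, association_frame
from .cohort import CohortSpec, make_cohort, write_cohort
from .config import PipelineConfig
from .io import (
    read_clinical_table,
    read_feature_table,
    read_masked_image,
    clinical_frame,
    write_feature_table,
)
from .selection import evaluate_on_test, rfe_rf, split_cohort
from .texture import TextureConfig, extract_features

__all__ = ["run_simulate", "run_extract", "run_select", "run_associate", "run_full"]

logger = logging.getLogger(__name__)


def _texture_config(config: PipelineConfig) -> TextureConfig:
    return TextureConfig(
        n_levels=config.n_levels,
        glcm_distance=config.glcm_distance,
        lbp_P=config.lbp_P,
        lbp_R=config.lbp_R,
        first_order_on_raw=config.first_order_on_raw,
    )


def _log_defaults(config: PipelineConfig) -> None:
    logger.info(
        "texture conventions: %d gray levels (equal-width min-max), "
        "GLCM distance %d symmetric, LBP P=%d R=%.1f uniform "
        "rotation-invariant on raw intensities, first-order on %s levels",
        config.n_levels, config.glcm_distance, config.lbp_P, config.lbp_R,
        "raw" if config.first_order_on_raw else "discretized",
    )
    logger.info("RFE size grid: %s", config.rfe_sizes)


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> CohortSpec:
    spec = CohortSpec(seed=config.seed, **config.cohort)
    cohort = make_cohort(spec)
    write_cohort(cohort, out_dir)
    logger.info(
        "simulated %d AAH + %d control subjects into %s",
        spec.n_aah, spec.n_control, out_dir,
    )
    return spec


def run_extract(
    cohort_dir: str | Path,
    out: str | Path,
    config: PipelineConfig | None = None,
    keep_going: bool = False,
) -> pd.DataFrame:
    """Extract one 178-feature row per image/mask pair of a cohort directory."""
    config = config or PipelineConfig()
    cohort_dir = Path(cohort_dir)
    tex = _texture_config(config)
    image_paths = sorted((cohort_dir / "images").glob("*.png"))
    if not image_paths:
        raise FileNotFoundError(f"no images under {cohort_dir / 'images'}")
    vectors = []
    failures: list[str] = []
    for ipath in image_paths:
        sid = ipath.stem
        mpath = cohort_dir / "masks" / ipath.name
        if not mpath.exists():
            raise FileNotFoundError(f"subject {sid!r}: missing mask {mpath}")
        try:
            img = read_masked_image(ipath, mpath)
            vectors.append(extract_features(img, tex, subject_id=sid))
        except Exception as exc:
            if not keep_going:
                raise RuntimeError(f"subject {sid!r}: {exc}") from exc
            logger.error("subject %r failed, skipping: %s", sid, exc)
            failures.append(sid)
    write_feature_table(vectors, out)
    table = read_feature_table(out)
    nan_cols = list(table.columns[table.isna().any()])
    if nan_cols:
        logger.warning("feature column(s) with NaN values: %s", nan_cols)
    return table


def _drop_nan_columns(features: pd.DataFrame) -> pd.DataFrame:
    nan_cols = list(features.columns[features.isna().any()])
    if nan_cols:
        logger.warning(
            "dropping %d NaN feature column(s) before selection: %s",
            len(nan_cols), nan_cols[:8],
        )
        features = features.drop(columns=nan_cols)
    return features


def run_select(
    features: pd.DataFrame, labels, config: PipelineConfig
):
    """Split, run RFE-RF on the training part, evaluate on the held-out part."""
    features = _drop_nan_columns(features)
    test_size = config.test_size
    if isinstance(test_size, float) and test_size.is_integer() and test_size >= 1:
        test_size = int(test_size)
    X_tr, X_te, y_tr, y_te = split_cohort(
        features, labels, test_size=test_size, seed=config.seed
    )
    result = rfe_rf(
        X_tr, y_tr,
        sizes=config.rfe_sizes,
        cv_folds=config.cv_folds,
        cv_repeats=config.cv_repeats,
        seed=config.seed,
        n_trees=config.n_trees,
        one_se=config.one_se,
    )
    evaluate_on_test(result, X_te, y_te)
    return result


def run_associate(
    features: pd.DataFrame,
    selected: list[str],
    clinical: pd.DataFrame,
    config: PipelineConfig,
):
    return associate_all(
        features[selected],
        clinical,
        seed=config.seed,
        cv_folds=config.enet_cv_folds,
        l1_ratios=tuple(config.enet_l1_ratios),
        n_alphas=config.enet_n_alphas,
    )


def run_full(config: PipelineConfig, out_dir: str | Path) -> dict:
    """simulate -> extract -> select -> associate, writing all artifacts.

    Produces features.csv, selection.json, associations.csv and
    run_metadata.json under ``out_dir``; returns the metadata dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _log_defaults(config)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    run_simulate(config, out / "cohort")
    timings["simulate_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    features = run_extract(out / "cohort", out / "features.csv", config)
    timings["extract_s"] = round(time.perf_counter() - t0, 3)

    clinical_records = read_clinical_table(out / "cohort" / "clinical.csv")
    clin = clinical_frame(clinical_records).loc[features.index]
    labels = clin["label"]

    t0 = time.perf_counter()
    result = run_select(features, labels, config)
    timings["select_s"] = round(time.perf_counter() - t0, 3)
    (out / "selection.json").write_text(
        json.dumps(result.to_json_dict(), indent=2)
    )

    t0 = time.perf_counter()
    records = run_associate(
        features, result.selected_features, clin, config
    )
    timings["associate_s"] = round(time.perf_counter() - t0, 3)
    association_frame(records).to_csv(out / "associations.csv", index=False)

    metadata = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timings": timings,
        "n_subjects": int(features.shape[0]),
        "best_size": result.best_size,
        "test_accuracy": result.test_metrics.accuracy,
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2))
    logger.info(
        "run complete: best_size=%d cv_acc=%.3f test_acc=%.3f",
        result.best_size, result.cv_accuracy_at_best,
        result.test_metrics.accuracy,
    )
    return metadata
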