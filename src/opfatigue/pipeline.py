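"""End-to-end pipeline: simulate -> features -> index -> grade -> train.

Every artifact embeds the configuration hash and the seed, and a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import simulate_cohort
from .entropy import (
    FeatureMatrix,
    classify_level,
    entropy_weights,
    minmax_normalize,
    shift,
)
from .grading import (
    cluster_thresholds,
    consolidate_levels,
    kmeans,
    select_k,
    weighted_thresholds,
)
from .hrv import FEATURE_NAMES, feature_vector
from .io import PipelineConfig, rr_filename, write_rri
from .mlp import crossvalidate, evaluate, predict, save_model, train
from .reference import REFERENCE_F_BANDS

__all__ = ["run_pipeline", "config_hash", "extract_features", "index_observations"]

log = logging.getLogger("opfatigue")


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def extract_features(series_list) -> pd.DataFrame:
    """Ten canonical HRV features per series, plus subject/stage columns."""
    rows = []
    for rr in series_list:
        feats = feature_vector(rr)
        row = {"subject": rr.subject_id, "stage": rr.stage}
        row.update(feats.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject", "stage", *FEATURE_NAMES])


def index_observations(obs: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Normalize Borg and reaction time, weight them by entropy, compute F.

    Returns the observation table extended with ``rt_norm``, ``borg_norm``,
    ``F`` and the 3-level grade (canonical reference bands), plus a
    weights record (per-feature entropy, difference coefficient, weight).
    """
    raw = FeatureMatrix(obs[["rt_ms", "borg"]].rename(
        columns={"rt_ms": "rt", "borg": "borg"}).astype(float))
    normalized = minmax_normalize(raw)
    weights = entropy_weights(shift(normalized))
    out = obs.copy()
    out["rt_norm"] = normalized.values["rt"].to_numpy()
    out["borg_norm"] = normalized.values["borg"].to_numpy()
    out["F"] = (
        weights.weight("rt") * out["rt_norm"]
        + weights.weight("borg") * out["borg_norm"]
    )
    out["level"] = [classify_level(f, REFERENCE_F_BANDS) for f in out["F"]]
    record = {
        "n": int(len(out)),
        "features": {
            name: {
                "entropy": float(weights.e[name]),
                "difference_coefficient": float(weights.g[name]),
                "weight": float(weights.w[name]),
            }
            for name in weights.w.index
        },
    }
    return out, record


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write all artifacts under *outdir*.

    Artifacts: per-series ``.rr`` files, ``observations.csv``,
    ``features.csv``, ``weights.json``, ``indexed.csv``,
    ``thresholds.json``, ``model.json`` and ``report.json``.  The
    returned dict is the report.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    meta = {"config_hash": config_hash(config), "seed": config.seed,
            "version": __version__}

    # 1. cohort ----------------------------------------------------------
    cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["cohort"])
    series, obs, _latent = simulate_cohort(cohort_cfg)
    rr_dir = outdir / "rr"
    rr_dir.mkdir(exist_ok=True)
    for rr in series:
        write_rri(rr, rr_dir / rr_filename(rr.subject_id, rr.stage))
    obs.to_csv(outdir / "observations.csv", index=False)
    log.info("cohort: %d series, seed %d", len(series), seeds["cohort"])

    # 2. HRV features ----------------------------------------------------
    features = extract_features(series)
    features.to_csv(outdir / "features.csv", index=False)
    log.info("features: %d rows", len(features))

    # 3. entropy weights and composite index -----------------------------
    indexed, weights_record = index_observations(obs)
    weights_record.update(meta)
    _dump(weights_record, outdir / "weights.json")
    indexed.to_csv(outdir / "indexed.csv", index=False)

    # 4. grading ---------------------------------------------------------
    points = indexed[["rt_norm", "borg_norm"]].to_numpy()
    sil_table, best_k = select_k(
        points,
        k_range=range(config.k_range[0], config.k_range[1] + 1),
        replicates=config.replicates,
        seed=seeds["grading"],
    )
    model = kmeans(points, config.k, replicates=config.replicates,
                   seed=seeds["grading"])
    thresholds = cluster_thresholds(points, model.labels)
    w = {name: weights_record["features"][name]["weight"]
         for name in ("rt", "borg")}
    f_intervals = weighted_thresholds(thresholds, w)
    bands3, mapping = consolidate_levels(f_intervals)
    thresholds_record = {
        "k": config.k,
        "silhouette_by_k": {
            str(int(r.K)): float(r.mean_silhouette) for r in sil_table.itertuples()
        },
        "best_k_by_silhouette": best_k,
        "levels_5": [
            {feat: list(iv) for feat, iv in level.items()}
            for level in thresholds.levels
        ],
        "f_intervals_5": [list(iv) for iv in f_intervals],
        "f_bands_3": [list(iv) for iv in bands3],
        "consolidation_map": {str(k): v for k, v in mapping.items()},
        **meta,
    }
    _dump(thresholds_record, outdir / "thresholds.json")
    log.info("grading: K=%d, silhouette argmax K=%d", config.k, best_k)

    # 5. predictor -------------------------------------------------------
    X = features[list(FEATURE_NAMES)].to_numpy()
    y = indexed["F"].to_numpy()
    train_cfg = dataclasses.replace(config.train, seed=seeds["train"])
    n_train, n_test = train_cfg.split_sizes(len(y))
    rng = np.random.default_rng(seeds["train"])
    order = rng.permutation(len(y))
    tr, te = order[:n_train], order[n_train:]
    params, history = train(X[tr], y[tr], train_cfg)
    save_model(params, outdir / "model.json")
    test_report = evaluate(predict(params, X[te]), y[te])
    cv_report, _ = crossvalidate(X, y, folds=config.folds, config=train_cfg,
                                 seed=seeds["cv"])
    log.info("predictor: held-out r2 (pooled CV) = %.4f", cv_report.r2)

    report = {
        "n_observations": int(len(indexed)),
        "weights": weights_record["features"],
        "silhouette_by_k": thresholds_record["silhouette_by_k"],
        "f_bands_3": thresholds_record["f_bands_3"],
        "consolidation_map": thresholds_record["consolidation_map"],
        "split": {"train": int(n_train), "test": int(n_test)},
        "final_train_mse_scaled": history[-1],
        "test": test_report.to_dict(),
        "crossvalidation": cv_report.to_dict(),
        **meta,
    }
    _dump(report, outdir / "report.json")
    return report
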