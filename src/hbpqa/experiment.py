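"""End-to-end orchestration: cohort -> features -> tuned forest -> report.

Feature extraction is deterministic per volume: preprocessing, mixture
features and texture features depend only on the volume itself, and the
smoothed Euler curve is cached per volume.  The FPCA basis, by contrast, is
a population object — it is fit on *training* curves only, and the resulting
eigenfunctions score training and test curves alike, so no information leaks
from the test split into the features.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import __version__
from .classify import (EvalReport, evaluate, learning_curve, train_rf_cv)
from .ecc import (SmoothedECCurve, ecc_curve, fit_fpca, fpc_scores, smooth_ecc)
from .gmm import em_fit, gmm_features
from .phantom import LabeledCohort
from .preprocess import PreprocessConfig, preprocess_pipeline
from .texture import texture_features
from .volume import MaskedVolume

__all__ = [
    "ExperimentConfig",
    "extract_volume",
    "extract_cohort",
    "attach_fpc_scores",
    "stratified_split",
    "run_experiment",
    "run_learning_curve",
]

HC_FEATURES = ["gmm_mu1", "gmm_sigma1", "gmm_pi",
               "ecc_fpc1", "ecc_fpc2", "ecc_fpc3",
               "glcm_energy", "glcm_correlation", "glcm_entropy", "glcm_idm"]


@dataclass(frozen=True)
class ExperimentConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    ecc_thresholds: tuple[float, float, int] = (-3.0, 3.0, 101)
    ecc_slicewise: bool = False
    glcm_levels: int = 32
    glcm_distance: int = 1
    n_fpc: int = 3
    rf_grid: tuple[tuple[int, int], ...] | None = None
    cv_folds: int = 10
    bootstrap_B: int = 2000
    test_fraction: float = 0.3
    n_jobs: int = 1

    def thresholds(self) -> np.ndarray:
        lo, hi, n = self.ecc_thresholds
        return np.linspace(lo, hi, int(n))

    def hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def extract_volume(v: MaskedVolume, cfg: ExperimentConfig
                   ) -> tuple[dict[str, float], SmoothedECCurve]:
    """Preprocess one volume and return its per-volume features plus the
    smoothed Euler curve (FPC scores are attached later, split-aware)."""
    std = preprocess_pipeline(v, cfg.preprocess)
    params, _ = em_fit(std.in_mask())
    mu1, sigma1, pi = gmm_features(params)
    tex = texture_features(std, n_levels=cfg.glcm_levels, d=cfg.glcm_distance)
    curve = smooth_ecc(ecc_curve(std, cfg.thresholds(),
                                 slicewise=cfg.ecc_slicewise))
    row = {"id": v.id, "gmm_mu1": mu1, "gmm_sigma1": sigma1, "gmm_pi": pi}
    row.update(tex.as_dict())
    return row, curve


def extract_cohort(cohort: LabeledCohort, cfg: ExperimentConfig | None = None
                   ) -> tuple[pd.DataFrame, list[SmoothedECCurve]]:
    """Per-volume features and smoothed curves for a whole cohort; the
    reduction order follows the cohort order regardless of parallelism."""
    cfg = cfg or ExperimentConfig()
    results = Parallel(n_jobs=cfg.n_jobs)(
        delayed(extract_volume)(v, cfg) for v in cohort.volumes)
    rows = [r for r, _ in results]
    curves = [c for _, c in results]
    df = pd.DataFrame(rows)
    df["label"] = list(cohort.labels)
    return df, curves


def attach_fpc_scores(df: pd.DataFrame, curves: list[SmoothedECCurve],
                      train_idx: np.ndarray, n_fpc: int = 3):
    """Fit FPCA on the training curves and score every curve; returns the
    augmented table (columns ecc_fpc1..K) and the fitted model."""
    model = fit_fpca([curves[i] for i in train_idx], K=n_fpc)
    scores = np.stack([fpc_scores(model, c) for c in curves])
    out = df.copy()
    for k in range(n_fpc):
        out[f"ecc_fpc{k + 1}"] = scores[:, k]
    cols = ["id"] + [c for c in HC_FEATURES if c in out.columns] + ["label"]
    return out[cols], model


def stratified_split(labels, test_fraction: float = 0.3, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level stratified train/test indices (one volume per subject
    in the synthetic cohorts, so stratifying rows stratifies subjects)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_test = int(round(len(idx) * test_fraction))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def run_experiment(cohort: LabeledCohort, seed: int = 0,
                   cfg: ExperimentConfig | None = None,
                   features: pd.DataFrame | None = None,
                   curves: list[SmoothedECCurve] | None = None) -> EvalReport:
    """Full protocol on one cohort: 70/30 stratified split, FPCA on
    training curves, CV-tuned random forest, bootstrap-CI evaluation.

    Pass pre-extracted *features*/*curves* to reuse the deterministic
    per-volume stage across seeds.
    """
    cfg = cfg or ExperimentConfig()
    if features is None or curves is None:
        features, curves = extract_cohort(cohort, cfg)
    train_idx, test_idx = stratified_split(features["label"].to_numpy(),
                                           cfg.test_fraction, seed)
    table, _ = attach_fpc_scores(features, curves, train_idx, cfg.n_fpc)
    train = table.iloc[train_idx].reset_index(drop=True)
    test = table.iloc[test_idx].reset_index(drop=True)
    grid = list(cfg.rf_grid) if cfg.rf_grid else None
    forest = train_rf_cv(train, grid=grid, k=cfg.cv_folds, seed=seed)
    report = evaluate(forest, test, B=cfg.bootstrap_B, seed=seed)
    report.extra.update({
        "n_train": len(train),
        "chosen_n_split_vars": forest.n_split_vars,
        "chosen_n_trees": forest.n_trees,
        "config_hash": cfg.hash(),
        "version": __version__,
    })
    return report


def run_learning_curve(cohort: LabeledCohort, sizes: list[int],
                       seeds: list[int], cfg: ExperimentConfig | None = None,
                       split_seed: int = 0,
                       features: pd.DataFrame | None = None,
                       curves: list[SmoothedECCurve] | None = None
                       ) -> pd.DataFrame:
    """Learning-curve experiment on a fixed test split.

    For each training size, the training rows are subsampled (stratified),
    the FPCA basis is refit on the subsample's curves, and the tuned forest
    is evaluated on the fixed test set; repeated over seeds.
    """
    cfg = cfg or ExperimentConfig()
    if features is None or curves is None:
        features, curves = extract_cohort(cohort, cfg)
    labels = features["label"].to_numpy()
    train_idx, test_idx = stratified_split(labels, cfg.test_fraction,
                                           split_seed)
    grid = list(cfg.rf_grid) if cfg.rf_grid else None
    y_train = (labels[train_idx] == "suboptimal").astype(int)
    rows = []
    for size in sizes:
        if size > len(train_idx):
            rows.append({"size": size, "skipped": True,
                         "reason": f"size {size} > training rows "
                                   f"{len(train_idx)}"})
            continue
        for seed in seeds:
            rng = np.random.default_rng(seed)
            sub = _stratified_take(train_idx, y_train, size, rng)
            table, _ = attach_fpc_scores(features, curves, sub, cfg.n_fpc)
            sub_train = table.iloc[sub].reset_index(drop=True)
            test = table.iloc[test_idx].reset_index(drop=True)
            minority = min(np.bincount(
                (sub_train["label"] == "suboptimal").astype(int)))
            if minority < cfg.cv_folds:
                rows.append({"size": size, "skipped": True,
                             "reason": f"minority {minority} < "
                                       f"k={cfg.cv_folds}"})
                break
            forest = train_rf_cv(sub_train, grid=grid, k=cfg.cv_folds,
                                 seed=seed)
            from .classify import auc as _auc, predict_scores, \
                specificity_at_sensitivity
            scores = predict_scores(forest, test)
            y_test = test["label"].to_numpy()
            rows.append({
                "size": size, "seed": seed, "skipped": False,
                "auc": _auc(scores, y_test),
                "specificity_at_95sens":
                    specificity_at_sensitivity(scores, y_test),
            })
    return pd.DataFrame(rows)


def _stratified_take(train_idx: np.ndarray, y_train: np.ndarray, size: int,
                     rng: np.random.Generator) -> np.ndarray:
    pos = train_idx[y_train == 1]
    neg = train_idx[y_train == 0]
    n_pos = max(1, int(round(size * len(pos) / len(train_idx))))
    n_pos = min(n_pos, size - 1, len(pos))
    n_neg = min(size - n_pos, len(neg))
    take = np.concatenate([rng.choice(pos, n_pos, replace=False),
                           rng.choice(neg, n_neg, replace=False)])
    return np.sort(take)
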