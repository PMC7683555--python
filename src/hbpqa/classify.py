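"""Random-forest classification and the evaluation protocol.

The 10-dimensional handcrafted feature vector (3 mixture + 3 functional
principal component + 4 texture features, optionally augmented with an
external feature block) feeds a random forest.  Hyperparameters — the number
of split variables (``max_features``) and the number of trees — are tuned by
stratified 10-fold cross-validated AUC; the winner is refit on the full
training set.  Test performance is reported as AUC and specificity at 95%
sensitivity (suboptimal = positive class), with percentile bootstrap
confidence intervals over resamples of the test rows, plus per-feature Mean
Decrease Gini importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "TunedForest",
    "EvalReport",
    "default_grid",
    "train_rf_cv",
    "predict_scores",
    "auc",
    "specificity_at_sensitivity",
    "bootstrap_ci",
    "variable_importance",
    "evaluate",
    "learning_curve",
    "POSITIVE",
    "NEGATIVE",
]

POSITIVE = "suboptimal"   # sensitivity = probability of catching these
NEGATIVE = "adequate"


def default_grid(n_features: int) -> list[tuple[int, int]]:
    """(n_split_vars, n_trees) grid: mtry 1..min(10, p) x {250, 500, 1000}."""
    return [(m, t)
            for m in range(1, min(10, n_features) + 1)
            for t in (250, 500, 1000)]


@dataclass
class TunedForest:
    model: RandomForestClassifier
    n_split_vars: int
    n_trees: int
    cv_auc: dict[tuple[int, int], float]
    feature_names: list[str]
    seed: int


@dataclass
class EvalReport:
    auc: float
    auc_ci: tuple[float, float]
    specificity_at_95sens: float
    spec_ci: tuple[float, float]
    mdg: dict[str, float]
    mdg_ranks: dict[str, int]
    n_test: int
    seed: int
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "specificity_at_95sens": self.specificity_at_95sens,
            "spec_ci": list(self.spec_ci),
            "mdg": self.mdg,
            "mdg_ranks": self.mdg_ranks,
            "n_test": self.n_test,
            "seed": self.seed,
            **self.extra,
        }


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        return (y == POSITIVE).astype(int)
    return y.astype(int)


def _check_table(t: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if "label" not in t.columns:
        raise ValueError("feature table needs a 'label' column")
    feats = [c for c in t.columns if c not in ("label", "id")]
    X = t[feats].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    y = _as_binary(t["label"])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return X, y, feats


def train_rf_cv(t: pd.DataFrame, grid: list[tuple[int, int]] | None = None,
                k: int = 10, seed: int = 0) -> TunedForest:
    """Grid search by mean out-of-fold AUC over stratified *k*-fold CV,
    then refit the winner on all rows.

    Ties are broken toward the smaller number of split variables, then
    fewer trees; fully deterministic given *seed*.
    """
    X, y, feats = _check_table(t)
    minority = int(np.bincount(y).min())
    if k > minority:
        raise ValueError(
            f"k={k} folds exceed the minority class count ({minority})")
    grid = grid or default_grid(X.shape[1])
    grid = [(m, tr) for m, tr in grid if m <= X.shape[1]]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    cv_auc: dict[tuple[int, int], float] = {}
    for m, n_trees in grid:
        fold_aucs = []
        for tr_idx, te_idx in folds:
            rf = RandomForestClassifier(
                n_estimators=n_trees, max_features=m,
                random_state=seed, n_jobs=1)
            rf.fit(X[tr_idx], y[tr_idx])
            scores = rf.predict_proba(X[te_idx])[:, list(rf.classes_).index(1)]
            fold_aucs.append(auc(scores, y[te_idx]))
        cv_auc[(m, n_trees)] = float(np.mean(fold_aucs))
    # max AUC; ties -> smaller mtry, then fewer trees
    best = max(cv_auc, key=lambda p: (cv_auc[p], -p[0], -p[1]))
    model = RandomForestClassifier(n_estimators=best[1], max_features=best[0],
                                   random_state=seed, n_jobs=1)
    model.fit(X, y)
    return TunedForest(model=model, n_split_vars=best[0], n_trees=best[1],
                       cv_auc=cv_auc, feature_names=feats, seed=seed)


def predict_scores(f: TunedForest, t: pd.DataFrame) -> np.ndarray:
    """Suboptimal-class vote fraction per row, in [0, 1]."""
    feats = [c for c in t.columns if c not in ("label", "id")]
    if feats != f.feature_names:
        missing = set(f.feature_names) - set(feats)
        extra = set(feats) - set(f.feature_names)
        raise ValueError(
            f"feature schema mismatch: missing={sorted(missing)}, "
            f"unexpected={sorted(extra)}")
    X = t[f.feature_names].to_numpy(float)
    pos_col = list(f.model.classes_).index(1)
    return f.model.predict_proba(X)[:, pos_col]


def auc(scores, labels) -> float:
    """Area under the ROC curve: the probability that a random positive
    (suboptimal) outranks a random negative, ties counting 1/2
    (Mann-Whitney convention)."""
    y = _as_binary(labels)
    s = np.asarray(scores, float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    u = r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def specificity_at_sensitivity(scores, labels, target: float = 0.95) -> float:
    """Specificity at the highest score threshold whose sensitivity
    (positives scored >= threshold) reaches *target*.

    The all-positive threshold always attains sensitivity 1, so a value is
    always defined; if no other threshold reaches the target the returned
    specificity is whatever the all-positive rule yields (typically 0).
    """
    y = _as_binary(labels)
    s = np.asarray(scores, float)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError("both classes must be present")
    pos = s[y == 1]
    neg = s[y == 0]
    best_spec = 0.0
    found = False
    for thr in np.unique(s)[::-1]:          # descending candidate thresholds
        sens = float((pos >= thr).mean())
        if sens >= target:
            best_spec = float((neg < thr).mean())
            found = True
            break
    if not found:   # unreachable with >= on observed scores; be explicit
        best_spec = 0.0
    return best_spec


def bootstrap_ci(metric_fn, scores, labels, B: int = 2000,
                 level: float = 0.95, seed: int = 0,
                 max_redraw: int = 100) -> tuple[float, float]:
    """Percentile bootstrap interval of ``metric_fn(scores, labels)`` over
    *B* resamples of the test rows; resamples missing a class are redrawn."""
    s = np.asarray(scores, float)
    y = _as_binary(labels)
    n = len(s)
    if n < 10:
        raise ValueError("need at least 10 test rows")
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    n_failed = 0
    for b in range(B):
        for _ in range(max_redraw):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
        try:
            vals[b] = metric_fn(s[idx], yb)
        except ValueError:
            n_failed += 1
            vals[b] = np.nan
    if n_failed > 0.1 * B:
        raise ValueError(
            f"metric undefined on {n_failed}/{B} bootstrap resamples")
    alpha = (1 - level) / 2
    lo, hi = np.nanpercentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return (float(lo), float(hi))


def variable_importance(f: TunedForest) -> pd.DataFrame:
    """Mean Decrease Gini per feature with ranks (1 = most important)."""
    imp = f.model.feature_importances_
    order = np.argsort(imp)[::-1]
    ranks = np.empty(len(imp), dtype=int)
    ranks[order] = np.arange(1, len(imp) + 1)
    return pd.DataFrame({"feature": f.feature_names, "mdg": imp,
                         "rank": ranks}).sort_values("rank").reset_index(drop=True)


def evaluate(f: TunedForest, test: pd.DataFrame, B: int = 2000,
             seed: int = 0, sens_target: float = 0.95) -> EvalReport:
    """Test-set evaluation: AUC and specificity at the sensitivity target,
    both with percentile bootstrap CIs, plus MDG importance."""
    scores = predict_scores(f, test)
    y = test["label"].to_numpy()
    a = auc(scores, y)
    spec = specificity_at_sensitivity(scores, y, sens_target)
    auc_ci = bootstrap_ci(auc, scores, y, B=B, seed=seed)
    spec_ci = bootstrap_ci(
        lambda s_, y_: specificity_at_sensitivity(s_, y_, sens_target),
        scores, y, B=B, seed=seed + 1)
    vi = variable_importance(f)
    return EvalReport(
        auc=a, auc_ci=auc_ci, specificity_at_95sens=spec, spec_ci=spec_ci,
        mdg=dict(zip(vi["feature"], vi["mdg"])),
        mdg_ranks=dict(zip(vi["feature"], vi["rank"].astype(int))),
        n_test=len(test), seed=seed)


def learning_curve(train: pd.DataFrame, test: pd.DataFrame,
                   sizes: list[int], seeds: list[int],
                   grid: list[tuple[int, int]] | None = None,
                   k: int = 10, B: int = 200) -> pd.DataFrame:
    """AUC on a fixed test split for stratified training subsamples of each
    size, repeated over seeds; sizes exceeding the training set (or too
    small for stratified k-fold CV) are skipped with a notice row."""
    y = _as_binary(train["label"])
    rows = []
    for size in sizes:
        if size > len(train):
            rows.append({"size": size, "skipped": True,
                         "reason": f"size {size} > training rows {len(train)}"})
            continue
        for seed in seeds:
            sub = _stratified_subsample(train, y, size, seed)
            y_sub = _as_binary(sub["label"])
            minority = int(np.bincount(y_sub).min())
            if minority < k:
                rows.append({"size": size, "skipped": True,
                             "reason": f"minority count {minority} < k={k}"})
                break
            forest = train_rf_cv(sub, grid=grid, k=k, seed=seed)
            scores = predict_scores(forest, test)
            rows.append({"size": size, "seed": seed, "skipped": False,
                         "auc": auc(scores, test["label"].to_numpy()),
                         "specificity_at_95sens": specificity_at_sensitivity(
                             scores, test["label"].to_numpy())})
    return pd.DataFrame(rows)


def _stratified_subsample(t: pd.DataFrame, y: np.ndarray, size: int,
                          seed: int) -> pd.DataFrame:
    """Class-proportional subsample of *size* rows without replacement."""
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    n_pos = max(1, int(round(size * len(idx_pos) / len(y))))
    n_pos = min(n_pos, size - 1, len(idx_pos))
    n_neg = min(size - n_pos, len(idx_neg))
    take = np.concatenate([rng.choice(idx_pos, n_pos, replace=False),
                           rng.choice(idx_neg, n_neg, replace=False)])
    return t.iloc[np.sort(take)].reset_index(drop=True)
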