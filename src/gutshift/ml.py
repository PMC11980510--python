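"""Nested cross-validation scaffold around a gradient-boosted tree learner.

The design: for each of ``n_iterations`` outer iterations the data is
split at random into an 80/20 train/test partition (stratified for
classification); a hyperparameter grid is tuned by 5-fold cross
validation *inside the training set only*; the winning configuration is
refit on the full training set and evaluated exactly once on the
held-out test set.  Two random benchmark features (one continuous
uniform, one fair coin), regenerated every iteration, are appended to
the predictors: genuine signal features are expected to out-rank them.
A permuted-label twin of every model monitors overfitting — it must
perform at chance.

Metrics: explained variance (1 - SS_res/SS_tot on the test set) for
regression, rank-based AUC for classification.  Feature importances are
total split gain, normalized to sum 1 per iteration, and ranked by their
mean over iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, ParameterGrid, StratifiedKFold, train_test_split
from xgboost import XGBClassifier, XGBRegressor

logger = logging.getLogger(__name__)

DEFAULT_GRID: dict[str, list] = {
    "max_depth": [3, 5, 7],
    "learning_rate": [0.05, 0.1],
    "n_estimators": [100, 300],
    "subsample": [0.7, 1.0],
}

#: One-combination grid for quick runs and smoke tests.
SMALL_GRID: dict[str, list] = {
    "max_depth": [3],
    "learning_rate": [0.1],
    "n_estimators": [100],
    "subsample": [1.0],
}


@dataclass
class MlConfig:
    """Configuration of one prediction task."""

    task: str  # "regression" | "classification"
    n_iterations: int = 200
    test_fraction: float = 0.20
    inner_folds: int = 5
    hyperparameter_grid: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_GRID))
    n_benchmark_features: int = 2
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not self.hyperparameter_grid:
            raise ValueError("hyperparameter grid must be non-empty")


@dataclass
class IterationResult:
    index: int
    params: dict
    metric: float
    importances: pd.Series          # all features incl. benchmarks; sums to 1 (or 0)
    benchmark_importances: pd.Series
    test_index: np.ndarray


@dataclass
class MlSummary:
    task: str
    metric_name: str
    metric_mean: float
    metric_sd: float
    iterations: list[IterationResult]
    ranking: pd.DataFrame           # feature, mean_importance (benchmarks excluded)
    benchmark_summary: pd.DataFrame
    n_redraws: int = 0


# ---------------------------------------------------------------------------
# metrics


def explained_variance(y_true, y_pred) -> float:
    """1 - SS_res/SS_tot; may be negative on held-out data."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.size < 2:
        raise ValueError("y_true and y_pred must share a length >= 2")
    ss_tot = float(((yt - yt.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("explained variance undefined for constant y_true")
    return 1.0 - float(((yt - yp) ** 2).sum()) / ss_tot


def auc(y_true, scores) -> float:
    """Rank-based AUC: P(score_pos > score_neg), ties counting one half."""
    yt = np.asarray(y_true)
    sc = np.asarray(scores, dtype=float)
    pos = yt == np.max(yt)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes in the evaluation set")
    ranks = rankdata(sc)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# benchmark features


def _benchmark_frame(n_rows: int, n: int, rng: np.random.Generator,
                     index) -> pd.DataFrame:
    cols = {}
    for j in range(n):
        if j % 2 == 0:
            name = "benchmark_uniform" if n <= 2 else f"benchmark_uniform_{j}"
            cols[name] = rng.uniform(size=n_rows)
        else:
            name = "benchmark_binary" if n <= 2 else f"benchmark_binary_{j}"
            cols[name] = rng.integers(0, 2, size=n_rows).astype(float)
    return pd.DataFrame(cols, index=index)


def inject_benchmark_features(
    features: pd.DataFrame, n: int = 2, seed: int = 0
) -> tuple[pd.DataFrame, list[str]]:
    """Append ``n`` outcome-independent random features (uniform/Bernoulli)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bench = _benchmark_frame(len(features), n, rng, features.index)
    return pd.concat([features, bench], axis=1), list(bench.columns)


# ---------------------------------------------------------------------------
# core loop


def _make_estimator(task: str, params: dict, seed: int, n_jobs: int):
    common = dict(tree_method="hist", n_jobs=n_jobs, random_state=seed,
                  verbosity=0, **params)
    if task == "regression":
        return XGBRegressor(**common)
    return XGBClassifier(eval_metric="logloss", **common)


def _score(task: str, model, X: pd.DataFrame, y: np.ndarray) -> float:
    if task == "regression":
        return explained_variance(y, model.predict(X))
    return auc(y, model.predict_proba(X)[:, 1])


def _normalized_gain(model, columns) -> pd.Series:
    raw = model.get_booster().get_score(importance_type="total_gain")
    imp = pd.Series([raw.get(c, 0.0) for c in columns], index=columns, dtype=float)
    total = imp.sum()
    return imp / total if total > 0 else imp


def _outer_split(y, test_fraction, task, rng, max_redraws=100):
    """Return (train_idx, test_idx, n_redraws); classification is stratified."""
    n = len(y)
    idx = np.arange(n)
    if task == "classification":
        try:
            tr, te = train_test_split(
                idx, test_size=test_fraction, stratify=y,
                random_state=int(rng.integers(2**31)))
            return tr, te, 0
        except ValueError:
            pass  # class too small to stratify: fall back to redraw loop
        for redraw in range(max_redraws):
            tr, te = train_test_split(
                idx, test_size=test_fraction,
                random_state=int(rng.integers(2**31)))
            if len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2:
                if redraw:
                    warnings.warn(f"redrew outer split {redraw} time(s) to get "
                                  "both classes in the test set", stacklevel=2)
                return tr, te, redraw
        raise ValueError("could not draw a two-class test set")
    tr, te = train_test_split(idx, test_size=test_fraction,
                              random_state=int(rng.integers(2**31)))
    return tr, te, 0


def _validate_xy(features: pd.DataFrame, outcome, config: MlConfig) -> np.ndarray:
    y = np.asarray(pd.Series(outcome).to_numpy())
    if len(y) != len(features):
        raise ValueError("features and outcome are not aligned")
    if config.task == "classification":
        levels = np.unique(y)
        if len(levels) != 2:
            raise ValueError(f"classification outcome must be binary, got {len(levels)} levels")
        y = (y == levels[1]).astype(int)
    else:
        y = y.astype(float)
        if np.ptp(y) == 0:
            raise ValueError("constant outcome")
    return y


def _run_iteration(X: pd.DataFrame, y: np.ndarray, config: MlConfig, i: int,
                   permute: bool) -> tuple[IterationResult, int]:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
    rng = np.random.default_rng(ss)
    if permute:
        y = rng.permutation(y)
    bench = _benchmark_frame(len(X), config.n_benchmark_features, rng, X.index)
    bench_ids = list(bench.columns)
    Xb = pd.concat([X, bench], axis=1)
    train_idx, test_idx, n_redraws = _outer_split(
        y, config.test_fraction, config.task, rng)
    test_set = frozenset(test_idx.tolist())

    if config.task == "classification":
        splitter = StratifiedKFold(config.inner_folds, shuffle=True,
                                   random_state=int(rng.integers(2**31)))
        folds = list(splitter.split(train_idx, y[train_idx]))
    else:
        splitter = KFold(config.inner_folds, shuffle=True,
                         random_state=int(rng.integers(2**31)))
        folds = list(splitter.split(train_idx))
    # audit: the inner loop must never touch the outer test set
    for fold_tr, fold_va in folds:
        inner = frozenset(train_idx[fold_tr].tolist()) | frozenset(train_idx[fold_va].tolist())
        assert inner.isdisjoint(test_set), "inner folds leak into the test set"

    est_seed = int(rng.integers(2**31))
    best_params, best_score = None, -np.inf
    for params in ParameterGrid(config.hyperparameter_grid):
        scores = []
        for fold_tr, fold_va in folds:
            tr, va = train_idx[fold_tr], train_idx[fold_va]
            model = _make_estimator(config.task, params, est_seed, config.n_jobs)
            model.fit(Xb.iloc[tr], y[tr])
            scores.append(_score(config.task, model, Xb.iloc[va], y[va]))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_params, best_score = dict(params), mean_score

    model = _make_estimator(config.task, best_params, est_seed, config.n_jobs)
    model.fit(Xb.iloc[train_idx], y[train_idx])
    metric = _score(config.task, model, Xb.iloc[test_idx], y[test_idx])
    imp = _normalized_gain(model, Xb.columns)
    result = IterationResult(
        index=i, params=best_params, metric=float(metric),
        importances=imp, benchmark_importances=imp[bench_ids],
        test_index=np.asarray(test_idx))
    return result, n_redraws


def _summarize(task: str, results: list[IterationResult],
               feature_ids: Sequence[str], n_redraws: int) -> MlSummary:
    metrics = np.array([r.metric for r in results])
    ranking = aggregate_feature_ranking(results, feature_ids=feature_ids)
    bench_ids = list(results[0].benchmark_importances.index)
    bench = pd.DataFrame({
        "benchmark": bench_ids,
        "mean_importance": [np.mean([r.benchmark_importances[b] for r in results])
                            for b in bench_ids],
    })
    return MlSummary(
        task=task,
        metric_name="explained_variance" if task == "regression" else "auc",
        metric_mean=float(metrics.mean()),
        metric_sd=float(metrics.std(ddof=1)) if len(metrics) > 1 else 0.0,
        iterations=results,
        ranking=ranking,
        benchmark_summary=bench,
        n_redraws=n_redraws,
    )


def run_prediction(features: pd.DataFrame, outcome, config: MlConfig) -> MlSummary:
    """Run the full nested-CV design for one prediction task."""
    y = _validate_xy(features, outcome, config)
    results, redraws = [], 0
    for i in range(config.n_iterations):
        res, n_re = _run_iteration(features, y, config, i, permute=False)
        results.append(res)
        redraws += n_re
    logger.info("run_prediction: %s over %d iterations, mean %s = %.3f",
                config.task, config.n_iterations,
                "EV" if config.task == "regression" else "AUC",
                float(np.mean([r.metric for r in results])))
    return _summarize(config.task, results, list(features.columns), redraws)


def run_permuted_control(features: pd.DataFrame, outcome, config: MlConfig) -> MlSummary:
    """Same design, but the outcome is permuted once per iteration."""
    y = _validate_xy(features, outcome, config)
    results, redraws = [], 0
    for i in range(config.n_iterations):
        res, n_re = _run_iteration(features, y, config, i, permute=True)
        results.append(res)
        redraws += n_re
    return _summarize(config.task, results, list(features.columns), redraws)


def aggregate_feature_ranking(
    results: list[IterationResult], feature_ids: Sequence[str] | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Features ordered by mean normalized importance, ties lexicographic."""
    if not results:
        raise ValueError("no iteration results to aggregate")
    mat = pd.DataFrame([r.importances for r in results])
    if feature_ids is not None:
        mat = mat[list(feature_ids)]
    else:
        bench = set(results[0].benchmark_importances.index)
        mat = mat[[c for c in mat.columns if c not in bench]]
    mean_imp = mat.mean(axis=0)
    order = sorted(mean_imp.index, key=lambda f: (-mean_imp[f], f))
    out = pd.DataFrame({"feature": order,
                        "mean_importance": mean_imp[order].to_numpy()})
    if top_k is not None:
        out = out.head(top_k).reset_index(drop=True)
    return out
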