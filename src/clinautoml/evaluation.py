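"""Model evaluation under progressive sampling.

Owns four concerns of the staged search:

* sample allocation across stages (fixed, per-stage resampled, or — for small
  datasets — dynamic allocation giving every non-training instance to
  validation);
* the dual-validation overfitting guard: every candidate is scored on two
  validation samples and the guarded estimate discounts suspiciously good
  first-sample scores;
* training/scoring of one candidate configuration (feature selection, then
  the learner, with failures absorbed as worst-case error so the search
  steers away instead of crashing);
* a consensus multi-technique feature pre-filter that drops a feature only
  when enough ranking techniques agree it is unpromising.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier, GradientBoostingRegressor,
    RandomForestClassifier, RandomForestRegressor,
)
from sklearn.feature_selection import f_classif, f_regression, mutual_info_classif, mutual_info_regression
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .search_space import Configuration, Registry, aggregation_plan

__all__ = [
    "TabularDataset",
    "SamplePlan",
    "OverfitGuardPolicy",
    "EvaluationRecord",
    "allocate_samples",
    "guarded_error",
    "evaluate_configuration",
    "prefilter_features",
    "AllocationError",
    "DYNAMIC_ALLOCATION_MAX_N",
]

#: datasets below this size default to dynamic allocation (all non-training
#: instances go to validation); configurable at the search level.
DYNAMIC_ALLOCATION_MAX_N = 4000


class AllocationError(ValueError):
    """Requested training sizes do not fit the dataset under the policy."""


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

class TabularDataset:
    """Wide-format dataset: one row per instance, one outcome column.

    Categorical feature columns are one-hot encoded up front; missing values
    are left as NaN and imputed inside each model pipeline, so allocation and
    feature selection always see a fixed numeric matrix.
    """

    def __init__(self, features: pd.DataFrame, y: pd.Series, task: str):
        if task not in ("classification", "regression"):
            raise ValueError(f"unknown task {task!r}")
        self.features = features.reset_index(drop=True)
        self.y = y.reset_index(drop=True)
        self.task = task

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str, task: str,
                       categorical: Sequence[str] = ()) -> "TabularDataset":
        if target not in df.columns:
            raise KeyError(f"target column {target!r} not in dataset")
        y = df[target]
        X = df.drop(columns=[target])
        cat = [c for c in X.columns if c in set(categorical) or X[c].dtype == object]
        if cat:
            X = pd.get_dummies(X, columns=cat, dtype=float)
        X = X.astype(float)
        if task == "classification":
            y = pd.Series(pd.factorize(y, sort=True)[0], name=y.name)
        else:
            y = y.astype(float)
        return cls(X, y, task)

    @classmethod
    def from_csv(cls, path, target: str, task: str,
                 categorical: Sequence[str] = ()) -> "TabularDataset":
        return cls.from_dataframe(pd.read_csv(path), target, task, categorical)

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def materialize(self, aggregation_assignment: Mapping | None = None):
        """Return the (X, y) pair a configuration trains on.  Plain tabular
        data ignores the aggregation assignment; the longitudinal dataset
        class overrides this hook."""
        return self.features, self.y


# ---------------------------------------------------------------------------
# sample allocation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplePlan:
    stage_index: int
    train_ids: np.ndarray
    val1_ids: np.ndarray
    val2_ids: np.ndarray
    policy: str

    def __post_init__(self):
        t, v1, v2 = map(set, (self.train_ids.tolist(), self.val1_ids.tolist(), self.val2_ids.tolist()))
        if t & v1 or t & v2:
            raise AllocationError("training and validation samples overlap")


def allocate_samples(n_instances: int, stage_schedule: Sequence[int], policy: str,
                     rng_seed: int, val_fraction: float = 0.2) -> list[SamplePlan]:
    """Build the per-stage train/validation split under one of three policies.

    Training samples are nested across stages (progressive sampling).  Under
    ``fixed_validation`` the two validation samples are drawn once, have equal
    size and no overlap, and are reused at every stage.  Under
    ``resampled_validation`` they are redrawn each stage from the instances
    outside that stage's training sample.  Under ``dynamic_allocation`` every
    non-training instance goes to validation, split evenly between the two
    samples.
    """
    sizes = [int(s) for s in stage_schedule]
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise AllocationError("training sizes must be strictly increasing")
    if sizes and sizes[-1] > n_instances:
        raise AllocationError("largest training size exceeds the dataset")
    if policy not in ("fixed_validation", "resampled_validation", "dynamic_allocation"):
        raise ValueError(f"unknown allocation policy {policy!r}")

    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n_instances)
    n_val_each = int(round(val_fraction * n_instances / 2))
    plans: list[SamplePlan] = []

    if policy == "fixed_validation":
        if sizes and sizes[-1] + 2 * n_val_each > n_instances:
            raise AllocationError(
                f"train size {sizes[-1]} plus validation {2 * n_val_each} exceeds n={n_instances}")
        val1, val2 = perm[:n_val_each], perm[n_val_each:2 * n_val_each]
        pool = perm[2 * n_val_each:]
        for k, size in enumerate(sizes, start=1):
            plans.append(SamplePlan(k, np.sort(pool[:size]), np.sort(val1), np.sort(val2), policy))
    elif policy == "resampled_validation":
        for k, size in enumerate(sizes, start=1):
            rest = perm[size:]
            if len(rest) < 2 * n_val_each:
                raise AllocationError("not enough instances outside the training sample")
            pick = np.random.default_rng(rng_seed + 1000 * k).permutation(rest)
            plans.append(SamplePlan(k, np.sort(perm[:size]),
                                    np.sort(pick[:n_val_each]),
                                    np.sort(pick[n_val_each:2 * n_val_each]), policy))
    else:  # dynamic_allocation
        for k, size in enumerate(sizes, start=1):
            rest = perm[size:]
            plans.append(SamplePlan(k, np.sort(perm[:size]),
                                    np.sort(rest[0::2]), np.sort(rest[1::2]), policy))
    return plans


# ---------------------------------------------------------------------------
# overfitting guard
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverfitGuardPolicy:
    """Dual-validation guard: a first-sample error in the worst
    ``stage_quantile`` tail of the stage's history is trusted as-is (it is bad
    enough to steer away from); otherwise a second-sample error more than
    ``gap_threshold`` error-rate points above the first signals overfitting to
    the first sample and the second sample's error is used."""

    stage_quantile: float = 0.50
    gap_threshold: float = 0.05

    def __post_init__(self):
        if not 0 < self.stage_quantile < 1:
            raise ValueError("stage_quantile must lie in (0, 1)")
        if self.gap_threshold <= 0:
            raise ValueError("gap_threshold must be positive")


def guarded_error(err1: float, err2: float, stage_history: Sequence[float],
                  policy: OverfitGuardPolicy = OverfitGuardPolicy()) -> float:
    """Guarded error estimate from the two validation-sample errors.

    With an empty history the first branch is skipped (a first evaluation can
    never be short-circuited).
    """
    if not 0 <= err1 <= 1 or not 0 <= err2 <= 1:
        raise ValueError("error rates must lie in [0, 1]")
    threshold = (np.quantile(np.asarray(stage_history, dtype=float), 1 - policy.stage_quantile)
                 if len(stage_history) else math.inf)
    if err1 > threshold:
        return err1
    if err2 - err1 < policy.gap_threshold:
        return err1
    return err2


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------

def _build_estimator(config: Configuration, task: str, seed: int):
    v = config.values
    aid = config.algorithm_id
    if aid == "logistic":
        unpenalized = v.get("penalty", "l2") == "none"
        return LogisticRegression(C=np.inf if unpenalized else v.get("C", 1.0),
                                  max_iter=500)
    if aid == "svm":
        return SVC(C=v.get("C", 1.0), kernel=v.get("kernel", "rbf"),
                   gamma=v.get("gamma", "scale"), degree=v.get("degree", 3),
                   tol=v.get("tol", 1e-3), random_state=seed)
    if aid == "decision_tree":
        cls = DecisionTreeClassifier if task == "classification" else DecisionTreeRegressor
        return cls(max_depth=v.get("max_depth"), min_samples_leaf=v.get("min_samples_leaf", 1),
                   random_state=seed)
    if aid == "random_forest":
        cls = RandomForestClassifier if task == "classification" else RandomForestRegressor
        return cls(n_estimators=v.get("n_trees", 100),
                   max_features=v.get("max_features_frac", 0.3),
                   min_samples_leaf=v.get("min_samples_leaf", 1), random_state=seed)
    if aid == "gradient_boosting":
        cls = GradientBoostingClassifier if task == "classification" else GradientBoostingRegressor
        return cls(n_estimators=v.get("n_trees", 100),
                   learning_rate=v.get("learning_rate", 0.1),
                   max_depth=v.get("max_depth", 3), random_state=seed)
    if aid == "knn":
        cls = KNeighborsClassifier if task == "classification" else KNeighborsRegressor
        return cls(n_neighbors=v.get("n_neighbors", 5), weights=v.get("weights", "uniform"))
    if aid == "ridge":
        return Ridge(alpha=v.get("alpha", 1.0))
    raise KeyError(f"no estimator factory for algorithm {aid!r}")


_SCALED_ALGORITHMS = {"logistic", "svm", "knn", "ridge"}


# ---------------------------------------------------------------------------
# feature scoring / selection
# ---------------------------------------------------------------------------

def _impute(X: np.ndarray) -> np.ndarray:
    if np.isnan(X).any():
        return SimpleImputer(strategy="median").fit_transform(X)
    return X


def _feature_scores(evaluator_id: str, X: np.ndarray, y: np.ndarray, task: str,
                    seed: int, n_trees: int = 50) -> np.ndarray:
    """Higher score = more promising.  NaN-safe (median imputation)."""
    X = _impute(np.asarray(X, dtype=float))
    if evaluator_id == "anova_f":
        f = f_classif if task == "classification" else f_regression
        scores = f(X, y)[0]
        return np.nan_to_num(scores, nan=0.0, posinf=np.finfo(float).max)
    if evaluator_id == "mutual_info":
        f = mutual_info_classif if task == "classification" else mutual_info_regression
        return f(X, y, random_state=seed)
    if evaluator_id == "correlation":
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        denom = Xc.std(axis=0) * yc.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc * yc[:, None]).mean(axis=0) / denom
        return np.abs(np.nan_to_num(r))
    if evaluator_id == "tree_importance":
        cls = RandomForestClassifier if task == "classification" else RandomForestRegressor
        model = cls(n_estimators=n_trees, random_state=seed, max_depth=8)
        model.fit(X, y)
        return model.feature_importances_
    raise KeyError(f"unknown feature evaluator {evaluator_id!r}")


def _select_features(fs_id: str, registry: Registry, config: Configuration,
                     X: np.ndarray, y: np.ndarray, task: str, seed: int) -> np.ndarray:
    """Column indices retained by the configuration's technique."""
    p = X.shape[1]
    if fs_id == "none":
        return np.arange(p)
    fs = registry.feature_selection(fs_id)
    v = config.values
    keep_fraction = v.get(f"fs:{fs_id}:keep_fraction", 0.5)
    n_trees = int(v.get(f"fs:{fs_id}:n_trees", 50))
    n_keep = max(1, int(math.ceil(keep_fraction * p)))
    scores = _feature_scores(fs.evaluator_id, X, y, task, seed, n_trees=n_trees)
    order = np.argsort(-scores, kind="stable")
    if fs.search_method_id == "rank_top":
        return np.sort(order[:n_keep])
    if fs.search_method_id == "greedy_forward":
        # greedy subset: walk down the ranking, admit a feature unless it is
        # nearly collinear (|r| > 0.95) with one already admitted
        Xi = _impute(X)
        chosen: list[int] = []
        for j in order:
            if len(chosen) >= n_keep:
                break
            ok = True
            for c in chosen:
                a, b = Xi[:, j], Xi[:, c]
                sa, sb = a.std(), b.std()
                if sa > 0 and sb > 0:
                    r = np.corrcoef(a, b)[0, 1]
                    if abs(r) > 0.95:
                        ok = False
                        break
            if ok:
                chosen.append(int(j))
        if not chosen:
            chosen = [int(order[0])]
        return np.sort(np.asarray(chosen))
    raise KeyError(f"unknown feature search method {fs.search_method_id!r}")


def prefilter_features(data: TabularDataset, techniques: Sequence[str],
                       keep_fraction: float, vote_threshold: int,
                       seed: int = 0) -> list[str]:
    """Consensus pre-filter: each ranking technique flags features outside its
    top ``keep_fraction`` as unpromising; a feature is dropped only when at
    least ``vote_threshold`` techniques flag it.  Never returns an empty set.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    if vote_threshold > len(techniques):
        raise ValueError("vote_threshold exceeds the number of techniques")
    X = data.features.to_numpy(dtype=float)
    y = data.y.to_numpy()
    p = X.shape[1]
    n_keep = max(1, int(math.ceil(keep_fraction * p)))
    votes = np.zeros(p, dtype=int)
    first_order = None
    for tech in techniques:
        scores = _feature_scores(tech, X, y, data.task, seed)
        order = np.argsort(-scores, kind="stable")
        if first_order is None:
            first_order = order
        flagged = np.ones(p, dtype=bool)
        flagged[order[:n_keep]] = False
        votes += flagged
    retained = np.flatnonzero(votes < vote_threshold)
    if retained.size == 0:
        retained = np.asarray([first_order[0]])
    return [data.feature_names[i] for i in retained]


# ---------------------------------------------------------------------------
# evaluation of one configuration
# ---------------------------------------------------------------------------

@dataclass
class EvaluationRecord:
    configuration: Configuration
    stage_index: int
    err1: float
    err2: float
    err_estimate: float
    n_train: int
    wall_clock: float
    seed: int
    failed: bool = False

    def to_dict(self) -> dict:
        return {"configuration": self.configuration.to_dict(),
                "stage_index": self.stage_index, "err1": self.err1, "err2": self.err2,
                "err_estimate": self.err_estimate, "n_train": self.n_train,
                "wall_clock": self.wall_clock, "seed": self.seed, "failed": self.failed}


def _error_rate(model, X: np.ndarray, y: np.ndarray, task: str) -> float:
    if task == "classification":
        return float(np.mean(model.predict(X) != y))
    pred = model.predict(X)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(np.clip(1.0 - r2, 0.0, 1.0))  # normalized loss for regression


def evaluate_configuration(config: Configuration, data: TabularDataset, plan: SamplePlan,
                           state_history: Sequence[float], seed: int,
                           registry: Registry,
                           guard: OverfitGuardPolicy = OverfitGuardPolicy()) -> EvaluationRecord:
    """Train the configuration's pipeline on the plan's training sample and
    score it on both validation samples.

    ``state_history`` is the list of first-validation-sample errors of all
    configurations already tested at this stage (the guard's reference
    distribution).  Training failures are absorbed: the record carries
    ``err_estimate = 1.0`` and a failure flag, so the search avoids the region
    instead of aborting.
    """
    t0 = time.perf_counter()
    task = data.task
    try:
        X_df, y_s = data.materialize(aggregation_plan(config))
        X = X_df.to_numpy(dtype=float)
        y = y_s.to_numpy()
        Xtr, ytr = X[plan.train_ids], y[plan.train_ids]
        cols = _select_features(config.fs_id, registry, config, Xtr, ytr, task, seed)
        steps = [("impute", SimpleImputer(strategy="median"))]
        if config.algorithm_id in _SCALED_ALGORITHMS:
            steps.append(("scale", StandardScaler()))
        steps.append(("model", _build_estimator(config, task, seed)))
        pipe = Pipeline(steps)
        pipe.fit(Xtr[:, cols], ytr)
        err1 = _error_rate(pipe, X[plan.val1_ids][:, cols], y[plan.val1_ids], task)
        err2 = _error_rate(pipe, X[plan.val2_ids][:, cols], y[plan.val2_ids], task)
        if not (np.isfinite(err1) and np.isfinite(err2)):
            raise FloatingPointError("non-finite validation error")
        est = guarded_error(err1, err2, state_history, guard)
        return EvaluationRecord(config, plan.stage_index, err1, err2, est,
                                len(plan.train_ids), time.perf_counter() - t0, seed)
    except Exception:
        return EvaluationRecord(config, plan.stage_index, 1.0, 1.0, 1.0,
                                len(plan.train_ids), time.perf_counter() - t0, seed,
                                failed=True)
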