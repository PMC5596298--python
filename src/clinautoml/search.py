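"""Staged progressive-sampling search over algorithms, feature-selection
techniques, and hyper-parameters.

The controller starts from cheap trials on a small training sample, discards
unpromising learning algorithms between stages, refines the survivors with
response-surface (Bayesian-optimization-style) rounds under a minimum-distance
spacing constraint, shares the best feature-selection combinations across
algorithms, and finishes with final tests at the full training size.  The
user-facing surface follows the Model/Results convention:

    >>> res = ModelSelection.from_dataframe(df, target="y", task="classification").fit(seed=7)
    >>> res.best_configuration, res.best_error
    >>> print(res.summary())
"""

from __future__ import annotations

import json
import math
import time
import zlib
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.ensemble import RandomForestRegressor
from scipy.stats import norm

from .evaluation import (
    DYNAMIC_ALLOCATION_MAX_N, EvaluationRecord, OverfitGuardPolicy, SamplePlan,
    TabularDataset, allocate_samples, evaluate_configuration,
)
from .search_space import (
    Configuration, Registry, config_distance, default_configuration,
    default_registry, encode_configuration, enumerate_configurations,
    sample_configuration,
)

__all__ = [
    "StageSchedule", "SharingPolicy", "SearchState",
    "ModelSelection", "ModelSelectionResults",
    "run_stage1", "eliminate_algorithms", "propose_candidates",
    "share_top_combinations", "run_search", "progress_curve",
    "evaluation_seed", "default_train_sizes",
]


# ---------------------------------------------------------------------------
# schedule / policies / state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSchedule:
    """Knobs of the staged search.

    ``train_sizes`` is the strictly increasing progressive-sampling schedule
    (derived from the dataset when None: geometric x2 growth from
    max(500, 5% of the training pool) to the full training size).
    ``min_distance`` is the spacing constraint on proposed candidates in
    normalized configuration-distance units; it decays by
    ``min_distance_decay`` per stage so late stages may refine locally.
    """

    train_sizes: tuple | None = None
    stage1_random_per_algorithm: int = 20
    bo_rounds_per_stage: int = 2
    bo_batch: int = 5
    bo_pool_size: int = 500
    min_tests_per_component: int = 3
    elimination_keep_fraction: float = 0.5
    min_distance: float = 0.1
    min_distance_decay: float = 0.8
    final_top_f: int = 5
    val_fraction: float = 0.2
    allocation_policy: str | None = None  # None = dynamic for small n, else fixed
    guard: OverfitGuardPolicy = OverfitGuardPolicy()

    def __post_init__(self):
        for name in ("stage1_random_per_algorithm", "bo_rounds_per_stage", "bo_batch",
                     "min_tests_per_component", "final_top_f"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.elimination_keep_fraction <= 1:
            raise ValueError("elimination_keep_fraction must lie in (0, 1]")

    def stage_min_distance(self, stage_index: int) -> float:
        return self.min_distance * self.min_distance_decay ** (stage_index - 1)


@dataclass(frozen=True)
class SharingPolicy:
    """Share the feature-selection side of the ``n1`` best full combinations
    with every surviving algorithm at the next stage."""

    n1: int = 3


@dataclass
class SearchState:
    surviving_algorithm_ids: list = field(default_factory=list)
    history: list = field(default_factory=list)  # EvaluationRecord, evaluation order
    stage_index: int = 0
    threshold: float = math.inf  # promising-error threshold for the next stage
    curve: list = field(default_factory=list)  # (elapsed, best err) pairs
    budget_exhausted: bool = False
    shared_combinations: list = field(default_factory=list)  # (fs_id, fs_assignment)

    @property
    def incumbent(self) -> EvaluationRecord | None:
        best = None
        for rec in self.history:
            if best is None or _record_order(rec) < _record_order(best):
                best = rec
        return best

    def stage_records(self, stage_index: int) -> list:
        return [r for r in self.history if r.stage_index == stage_index]

    def stage_err1_history(self, stage_index: int) -> list:
        return [r.err1 for r in self.history if r.stage_index == stage_index]

    def algorithm_best(self, algorithm_id: str, stage_index: int | None = None) -> float:
        errs = [r.err_estimate for r in self.history
                if r.configuration.algorithm_id == algorithm_id
                and (stage_index is None or r.stage_index == stage_index)]
        return min(errs) if errs else math.inf


def _record_order(rec: EvaluationRecord):
    """Deterministic total order: lower error, then earlier stage, then
    canonical configuration key (evaluation order resolves the rest because
    sort is applied over the history list, which is append-ordered)."""
    return (rec.err_estimate, rec.stage_index, rec.configuration.key())


def evaluation_seed(base_seed: int, stage_index: int, config: Configuration) -> int:
    """Stable per-evaluation seed: a pure function of the base seed, the stage
    and the configuration, so any enumeration order reproduces identical
    records."""
    return zlib.crc32(f"{base_seed}|{stage_index}|{config.key()}".encode()) % (2 ** 31)


def default_train_sizes(n_instances: int, val_fraction: float = 0.2) -> tuple:
    pool = int(math.floor((1 - val_fraction) * n_instances))
    start = int(max(500, round(0.05 * n_instances)))
    if start >= pool:
        return (pool,)
    sizes = [start]
    while sizes[-1] * 2 < pool:
        sizes.append(sizes[-1] * 2)
    sizes.append(pool)
    return tuple(sizes)


# ---------------------------------------------------------------------------
# budget clock
# ---------------------------------------------------------------------------

class _Clock:
    """Wall-clock budget by default; evaluation-count mode for reproducible
    tests (one tick per evaluation)."""

    def __init__(self, time_budget: float | None, max_evaluations: int | None):
        self.time_budget = time_budget
        self.max_evaluations = max_evaluations
        self.t0 = time.perf_counter()
        self.evals = 0

    def tick(self):
        self.evals += 1

    @property
    def elapsed(self) -> float:
        if self.max_evaluations is not None:
            return float(self.evals)
        return time.perf_counter() - self.t0

    @property
    def exhausted(self) -> bool:
        if self.max_evaluations is not None and self.evals >= self.max_evaluations:
            return True
        return self.time_budget is not None and (time.perf_counter() - self.t0) >= self.time_budget


# ---------------------------------------------------------------------------
# stage 1
# ---------------------------------------------------------------------------

def _dedupe(configs: Sequence[Configuration]) -> list:
    seen, out = set(), []
    for c in configs:
        if c.key() not in seen:
            seen.add(c.key())
            out.append(c)
    return out


def _stage1_candidates(algorithm, fs_pool, schedule: StageSchedule,
                       rng: np.random.Generator) -> list:
    """Default configuration plus random draws; fully enumerable spaces are
    enumerated exhaustively (in canonical order) when they fit the stage-1
    budget, which also makes tiny spaces exactly comparable to brute force."""
    budget = schedule.stage1_random_per_algorithm + 1
    enumerated = enumerate_configurations(algorithm, fs_pool, max_size=budget)
    if enumerated is not None:
        return enumerated
    none_fs = next((f for f in fs_pool if f.id == "none"), fs_pool[0])
    candidates = [default_configuration(algorithm, none_fs)]
    for _ in range(schedule.stage1_random_per_algorithm):
        candidates.append(sample_configuration(algorithm, fs_pool, rng))
    return _dedupe(candidates)


def _component_topup(algorithm, fs_pool, candidates, schedule: StageSchedule,
                     rng: np.random.Generator) -> list:
    """Guarantee a minimum number of stage-1 tests per feature evaluator and
    per feature search method for this algorithm."""
    candidates = list(candidates)
    for attr in ("evaluator_id", "search_method_id"):
        for component in sorted({getattr(f, attr) for f in fs_pool}):
            group = [f for f in fs_pool if getattr(f, attr) == component]
            enumerable = all(
                enumerate_configurations(algorithm, [f], max_size=10 ** 6) is not None
                for f in group)
            want = schedule.min_tests_per_component
            for _ in range(200):  # top-up budget
                count = sum(1 for c in candidates
                            if getattr(_fs_of(c, fs_pool), attr) == component)
                if count >= want:
                    break
                extra = sample_configuration(algorithm, group, rng)
                if extra.key() not in {c.key() for c in candidates}:
                    candidates.append(extra)
                elif enumerable:
                    break  # finite space already saturated
    return candidates


def _fs_of(config: Configuration, fs_pool):
    for f in fs_pool:
        if f.id == config.fs_id:
            return f
    raise KeyError(config.fs_id)


def run_stage1(data: TabularDataset, registry: Registry, schedule: StageSchedule,
               seed: int, plan: SamplePlan, clock: _Clock | None = None,
               state: SearchState | None = None) -> SearchState:
    """First stage: per algorithm, the default configuration plus a fixed
    number of random ones, topped up so every feature evaluator and feature
    search method gets a minimum number of tests."""
    state = state or SearchState()
    clock = clock or _Clock(None, None)
    algorithms = sorted(registry.algorithms(data.task), key=lambda a: a.id)
    if not algorithms:
        raise ValueError(f"registry has no algorithm for task {data.task!r}")
    fs_pool = sorted(registry.feature_selections(), key=lambda f: f.id)
    state.stage_index = 1
    state.surviving_algorithm_ids = [a.id for a in algorithms]
    for i, algorithm in enumerate(algorithms):
        rng = np.random.default_rng([seed % (2 ** 31), 1, i])
        candidates = _stage1_candidates(algorithm, fs_pool, schedule, rng)
        candidates = _component_topup(algorithm, fs_pool, candidates, schedule, rng)
        _evaluate_batch(candidates, data, plan, state, seed, registry, schedule, clock)
        if state.budget_exhausted:
            break
    return state


def _evaluate_batch(candidates, data, plan, state: SearchState, seed, registry,
                    schedule: StageSchedule, clock: _Clock):
    for config in candidates:
        if clock.exhausted:
            state.budget_exhausted = True
            return
        rec = evaluate_configuration(
            config, data, plan, state.stage_err1_history(plan.stage_index),
            evaluation_seed(seed, plan.stage_index, config), registry, schedule.guard)
        state.history.append(rec)
        clock.tick()
        inc = state.incumbent
        state.curve.append((clock.elapsed, inc.err_estimate))


# ---------------------------------------------------------------------------
# elimination / sharing / proposal
# ---------------------------------------------------------------------------

def eliminate_algorithms(state: SearchState, schedule: StageSchedule) -> SearchState:
    """Keep the best fraction of surviving algorithms, ranked by their best
    guarded error among the just-completed stage's records; the incumbent's
    algorithm is always protected (it may rank low at the current stage while
    holding the overall best from an earlier one).  The promising-error
    threshold for the next stage becomes the worst surviving best."""
    stage = state.stage_index
    if not any(r.stage_index == stage for r in state.history):
        stage = None  # fall back to all history (degenerate call order)

    def best_at_stage(a):
        b = state.algorithm_best(a, stage)
        return b if math.isfinite(b) else state.algorithm_best(a)

    k = len(state.surviving_algorithm_ids)
    ranked = sorted(state.surviving_algorithm_ids, key=lambda a: (best_at_stage(a), a))
    keep = max(1, math.ceil(schedule.elimination_keep_fraction * k))
    survivors = ranked[:keep]
    inc = state.incumbent
    if inc is not None and inc.configuration.algorithm_id not in survivors:
        survivors.append(inc.configuration.algorithm_id)
    state.surviving_algorithm_ids = survivors
    state.threshold = max(best_at_stage(a) for a in survivors)
    return state


def share_top_combinations(state: SearchState, policy: SharingPolicy = SharingPolicy()):
    """Extract the distinct feature-selection combinations (technique plus its
    hyper-parameter values) behind the n1 best full combinations so far."""
    if not state.history:
        raise ValueError("history is empty")
    ranked = sorted(state.history, key=_record_order)
    shared, seen = [], set()
    for rec in ranked[:policy.n1]:
        cfg = rec.configuration
        fs_assignment = tuple(sorted((k, v) for k, v in cfg.assignment
                                     if k.startswith("fs:")))
        key = (cfg.fs_id, fs_assignment)
        if key not in seen:
            seen.add(key)
            shared.append(key)
    state.shared_combinations = shared
    return shared


def _with_fs_combo(algorithm, registry: Registry, base_assignment: Mapping,
                   fs_id: str, fs_assignment) -> Configuration:
    """Attach a shared fs combination (verbatim) to an algorithm's
    hyper-parameter assignment."""
    assignment = {k: v for k, v in base_assignment.items() if not k.startswith("fs:")}
    assignment.update(dict(fs_assignment))
    return Configuration.make(algorithm.id, fs_id, assignment)


def inject_shared(state: SearchState, data, registry, schedule, plan, seed,
                  clock: _Clock) -> None:
    """Guarantee every surviving algorithm one evaluation per shared
    combination at this stage, adding tests only where needed."""
    for algorithm_id in sorted(state.surviving_algorithm_ids):
        algorithm = registry.algorithm(algorithm_id)
        algo_best = min((r for r in state.history
                         if r.configuration.algorithm_id == algorithm_id),
                        key=_record_order, default=None)
        base = algo_best.configuration.values if algo_best else {}
        todo = []
        for fs_id, fs_assignment in state.shared_combinations:
            already = any(
                r.configuration.algorithm_id == algorithm_id
                and r.configuration.fs_id == fs_id
                and tuple(sorted((k, v) for k, v in r.configuration.assignment
                                 if k.startswith("fs:"))) == fs_assignment
                and r.stage_index == plan.stage_index
                for r in state.history)
            if not already:
                todo.append(_with_fs_combo(algorithm, registry, base, fs_id, fs_assignment))
        _evaluate_batch(_dedupe(todo), data, plan, state, seed, registry, schedule, clock)
        if state.budget_exhausted:
            return


def propose_candidates(state: SearchState, algorithm_id: str, schedule: StageSchedule,
                       seed: int, registry: Registry) -> list:
    """Response-surface proposal round for one algorithm.

    Fits a tree-ensemble surrogate from encoded configurations to guarded
    errors, draws a random pool, greedily enforces the stage's minimum
    spacing between retained pool members (and against configurations already
    tested this stage), and ranks the survivors by expected improvement using
    the ensemble spread as the predictive uncertainty.
    """
    algorithm = registry.algorithm(algorithm_id)
    fs_pool = sorted(registry.feature_selections(), key=lambda f: f.id)
    rng = np.random.default_rng([seed % (2 ** 31), 97, state.stage_index,
                                 zlib.crc32(algorithm_id.encode())])
    records = [r for r in state.history if r.configuration.algorithm_id == algorithm_id]
    if len(records) < 2:
        return [sample_configuration(algorithm, fs_pool, rng)
                for _ in range(schedule.bo_batch)]

    X = np.vstack([encode_configuration(r.configuration, algorithm, registry)
                   for r in records])
    y = np.asarray([r.err_estimate for r in records])
    surrogate = RandomForestRegressor(n_estimators=50, random_state=int(rng.integers(2 ** 31)))
    surrogate.fit(X, y)

    pool = _dedupe(sample_configuration(algorithm, fs_pool, rng)
                   for _ in range(schedule.bo_pool_size))
    min_dist = schedule.stage_min_distance(state.stage_index)
    anchors = [r.configuration for r in records if r.stage_index == state.stage_index]
    retained = []
    for cand in pool:
        others = anchors + retained
        if all(config_distance(cand, o, registry) >= min_dist for o in others):
            retained.append(cand)
    if not retained:
        return []

    Xp = np.vstack([encode_configuration(c, algorithm, registry) for c in retained])
    per_tree = np.stack([t.predict(Xp) for t in surrogate.estimators_])
    mu, sigma = per_tree.mean(axis=0), per_tree.std(axis=0)
    best = y.min()
    ei = np.empty(len(retained))
    for i, (m, s) in enumerate(zip(mu, sigma)):
        if s > 1e-12:
            z = (best - m) / s
            ei[i] = (best - m) * norm.cdf(z) + s * norm.pdf(z)
        else:
            ei[i] = max(best - m, 0.0)
    ranked = sorted(range(len(retained)), key=lambda i: (-ei[i], retained[i].key()))
    return [retained[i] for i in ranked[:schedule.bo_batch]]


# ---------------------------------------------------------------------------
# progress curve and forecast
# ---------------------------------------------------------------------------

def progress_curve(state: SearchState, horizon: float | None = None):
    """Running best-error curve plus an inverse-power-law forecast
    e(t) = a + b * t^(-c) fitted by least squares (a constrained nonnegative).

    Returns ``(curve, forecast)`` where forecast is None when fewer than three
    distinct curve points exist, else a dict with the fitted parameters, a
    predict(t) callable, the residual scale, and the horizon value.
    """
    if not state.curve:
        raise ValueError("no evaluations recorded")
    curve = list(state.curve)
    pts = sorted({(t, e) for t, e in curve if t > 0})
    if len(pts) < 3:
        return curve, None
    t = np.asarray([p[0] for p in pts], dtype=float)
    e = np.asarray([p[1] for p in pts], dtype=float)

    def model(t, a, b, c):
        return a + b * np.power(t, -c)

    try:
        p0 = (max(e.min() * 0.9, 1e-6), max(e[0] - e.min(), 1e-3), 0.5)
        popt, _ = curve_fit(model, t, e, p0=p0,
                            bounds=([0, 0, 1e-4], [1.0, np.inf, 10.0]), maxfev=20000)
    except Exception:
        return curve, None
    resid = e - model(t, *popt)
    band = float(np.sqrt(np.mean(resid ** 2)))
    forecast = {
        "a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2]),
        "residual_scale": band,
        "predict": lambda tt, _p=popt: model(np.asarray(tt, dtype=float), *_p),
        "horizon": horizon,
        "value_at_horizon": float(model(horizon, *popt)) if horizon else None,
    }
    return curve, forecast


# ---------------------------------------------------------------------------
# full search
# ---------------------------------------------------------------------------

def run_search(data: TabularDataset, registry: Registry | None = None,
               schedule: StageSchedule | None = None,
               sharing: SharingPolicy = SharingPolicy(),
               time_budget: float | None = None,
               max_evaluations: int | None = None,
               seed: int = 0):
    """Execute the full staged search; returns (best configuration, fitted
    final pipeline, state).  Prefer the :class:`ModelSelection` front end."""
    registry = registry or default_registry()
    schedule = schedule or StageSchedule()
    sizes = schedule.train_sizes or default_train_sizes(data.n, schedule.val_fraction)
    policy = schedule.allocation_policy or (
        "dynamic_allocation" if data.n < DYNAMIC_ALLOCATION_MAX_N else "fixed_validation")
    plans = allocate_samples(data.n, sizes, policy, rng_seed=seed % (2 ** 31),
                             val_fraction=schedule.val_fraction)
    clock = _Clock(time_budget, max_evaluations)

    state = run_stage1(data, registry, schedule, seed, plans[0], clock)

    for plan in plans[1:-1]:
        if state.budget_exhausted:
            break
        eliminate_algorithms(state, schedule)  # judged on the completed stage
        state.stage_index = plan.stage_index
        share_top_combinations(state, sharing)
        inject_shared(state, data, registry, schedule, plan, seed, clock)
        for _ in range(schedule.bo_rounds_per_stage):
            if state.budget_exhausted:
                break
            for algorithm_id in sorted(state.surviving_algorithm_ids):
                batch = propose_candidates(state, algorithm_id, schedule, seed, registry)
                _evaluate_batch(batch, data, plans[plans.index(plan)], state, seed,
                                registry, schedule, clock)
                if state.budget_exhausted:
                    break

    if len(plans) > 1 and not state.budget_exhausted:
        final_plan = plans[-1]
        eliminate_algorithms(state, schedule)
        state.stage_index = final_plan.stage_index
        ranked = sorted(state.history, key=_record_order)
        finalists, seen = [], set()
        for rec in ranked:
            if rec.configuration.key() not in seen:
                seen.add(rec.configuration.key())
                finalists.append(rec.configuration)
            if len(finalists) >= schedule.final_top_f:
                break
        _evaluate_batch(finalists, data, final_plan, state, seed, registry, schedule, clock)
        final_records = state.stage_records(final_plan.stage_index)
        best = min(final_records, key=_record_order) if final_records \
            else state.incumbent
    else:
        best = state.incumbent

    if best is None:
        raise RuntimeError("budget exhausted before any evaluation completed")
    model = _fit_final(best.configuration, data, registry, schedule, seed)
    return best.configuration, model, state


def _fit_final(config: Configuration, data: TabularDataset, registry, schedule, seed):
    """Deployable model: the chosen pipeline refitted on the whole dataset."""
    from .evaluation import _build_estimator, _select_features, _SCALED_ALGORITHMS
    from sklearn.impute import SimpleImputer
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    from .search_space import aggregation_plan
    X_df, y_s = data.materialize(aggregation_plan(config))
    X, y = X_df.to_numpy(dtype=float), y_s.to_numpy()
    fit_seed = evaluation_seed(seed, 0, config)
    cols = _select_features(config.fs_id, registry, config, X, y, data.task, fit_seed)
    steps = [("impute", SimpleImputer(strategy="median"))]
    if config.algorithm_id in _SCALED_ALGORITHMS:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", _build_estimator(config, data.task, fit_seed)))
    pipe = Pipeline(steps)
    try:
        pipe.fit(X[:, cols], y)
    except Exception:
        return None
    pipe.selected_columns_ = cols
    return pipe


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------

class ModelSelection:
    """Automated model selection for one prediction problem.

    Parameters
    ----------
    data : TabularDataset
        Wide-format dataset (see :class:`TabularDataset`); longitudinal
        problems enter through
        :class:`clinautoml.temporal.LongitudinalDataset`.
    registry : Registry, optional
        Algorithm/feature-selection catalog; defaults to the built-in one.
    schedule : StageSchedule, optional
    sharing : SharingPolicy, optional
    """

    def __init__(self, data: TabularDataset, registry: Registry | None = None,
                 schedule: StageSchedule | None = None,
                 sharing: SharingPolicy = SharingPolicy()):
        self.data = data
        self.registry = registry or default_registry()
        self.schedule = schedule or StageSchedule()
        self.sharing = sharing

    @classmethod
    def from_dataframe(cls, df, target: str, task: str, categorical=(),
                       **kwargs) -> "ModelSelection":
        return cls(TabularDataset.from_dataframe(df, target, task, categorical), **kwargs)

    def fit(self, time_budget: float | None = None,
            max_evaluations: int | None = None, seed: int = 0) -> "ModelSelectionResults":
        config, model, state = run_search(
            self.data, self.registry, self.schedule, self.sharing,
            time_budget=time_budget, max_evaluations=max_evaluations, seed=seed)
        return ModelSelectionResults(self, config, model, state, seed)


class ModelSelectionResults:
    """Outcome of a staged search: the chosen configuration, the refitted
    model, the full evaluation history, and the anytime progress curve."""

    def __init__(self, parent: ModelSelection, config: Configuration, model,
                 state: SearchState, seed: int):
        self.model_selection = parent
        self.best_configuration = config
        self.model = model
        self.state = state
        self.seed = seed

    @property
    def best_error(self) -> float:
        final = [r for r in self.state.history
                 if r.configuration.key() == self.best_configuration.key()]
        return min(r.err_estimate for r in final)

    @property
    def history(self) -> list:
        return self.state.history

    def progress_curve(self, horizon: float | None = None):
        return progress_curve(self.state, horizon)

    def summary(self) -> str:
        inc = self.state.incumbent
        task = self.model_selection.data.task
        metric = "error rate" if task == "classification" else "1 - R^2"
        lines = [
            "Automated model selection results",
            "=" * 42,
            f"task:                    {task}",
            f"instances:               {self.model_selection.data.n}",
            f"evaluations:             {len(self.state.history)}",
            f"stages completed:        {self.state.stage_index}",
            f"surviving algorithms:    {', '.join(sorted(self.state.surviving_algorithm_ids))}",
            f"budget exhausted early:  {self.state.budget_exhausted}",
            "-" * 42,
            f"best algorithm:          {self.best_configuration.algorithm_id}",
            f"feature selection:       {self.best_configuration.fs_id}",
            f"validation {metric}: {self.best_error:.4f}",
            "hyper-parameters:",
        ]
        for k, v in self.best_configuration.assignment:
            vv = f"{v:.6g}" if isinstance(v, float) else str(v)
            lines.append(f"    {k} = {vv}")
        for a, p in self.best_configuration.aggregation_assignment:
            lines.append(f"    aggregate[{a}] = ({p.operator_id}, {p.period_days} d)")
        return "\n".join(lines)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.state.history:
                fh.write(json.dumps(rec.to_dict()) + "\n")

    def curve_frame(self):
        import pandas as pd
        return pd.DataFrame(self.state.curve, columns=["elapsed_seconds", "best_error"])

    def plot_progress(self, ax=None, horizon: float | None = None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        curve, forecast = self.progress_curve(horizon)
        t = [p[0] for p in curve]
        e = [p[1] for p in curve]
        ax.step(t, e, where="post", label="best error so far")
        if forecast is not None and horizon is not None:
            tt = np.linspace(max(min(t), 1e-9), horizon, 200)
            pred = forecast["predict"](tt)
            ax.plot(tt, pred, "--", label="inverse-power-law forecast")
            ax.fill_between(tt, pred - forecast["residual_scale"],
                            pred + forecast["residual_scale"], alpha=0.2)
        ax.set_xlabel("elapsed")
        ax.set_ylabel("best validation error")
        ax.legend()
        return ax
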