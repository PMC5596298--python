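"""Declarative search space for combined algorithm / feature-selection / hyper-parameter choice.

The space is the cross product of a learning algorithm, a feature-selection
technique (represented as one special categorical hyper-parameter, so the
search treats it like any other dimension), and the active hyper-parameters
of both.  A :class:`Configuration` is one point in that space.  The module
also owns the geometry used by the staged search: uniform sampling on each
dimension's scale, a numeric encoding for surrogate regression, and a
normalized pseudometric between configurations of the same algorithm.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Condition",
    "HyperParameterSpec",
    "AlgorithmSpec",
    "FeatureSelectionSpec",
    "AggregationPair",
    "Configuration",
    "Registry",
    "default_registry",
    "default_configuration",
    "sample_configuration",
    "config_distance",
    "encode_configuration",
    "enumerate_configurations",
]

NONE_FS_ID = "none"


class RegistryError(KeyError):
    """Unknown algorithm or feature-selection id."""


class SpecError(ValueError):
    """Malformed hyper-parameter specification."""


@dataclass(frozen=True)
class Condition:
    """Activates a hyper-parameter only when ``parent`` takes one of ``values``."""

    parent: str
    values: tuple

    def satisfied(self, assignment: Mapping[str, Any]) -> bool:
        return self.parent in assignment and assignment[self.parent] in self.values


@dataclass(frozen=True)
class HyperParameterSpec:
    """One tunable dimension.

    ``kind`` is one of ``continuous``, ``integer``, ``categorical``,
    ``boolean``.  Numeric kinds carry an inclusive interval ``domain=(low,
    high)`` and a ``scale`` (``linear`` or ``log``; log scale means the
    search works uniformly in log10).  Categorical/boolean kinds carry a
    finite choice tuple.
    """

    name: str
    kind: str
    domain: tuple
    default: Any
    scale: str = "linear"
    condition: Condition | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "integer", "categorical", "boolean"):
            raise SpecError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.is_numeric:
            lo, hi = self.domain
            if not lo <= hi:
                raise SpecError(f"empty domain for {self.name!r}")
            if self.scale == "log" and lo <= 0:
                raise SpecError(f"log scale needs a positive interval ({self.name!r})")
            if self.scale not in ("linear", "log"):
                raise SpecError(f"unknown scale {self.scale!r}")
        elif len(self.domain) == 0:
            raise SpecError(f"empty choice set for {self.name!r}")
        if not self.contains(self.default):
            raise SpecError(f"default {self.default!r} outside domain of {self.name!r}")

    @property
    def is_numeric(self) -> bool:
        return self.kind in ("continuous", "integer")

    def contains(self, value: Any) -> bool:
        if self.kind == "continuous":
            lo, hi = self.domain
            return lo <= value <= hi
        if self.kind == "integer":
            lo, hi = self.domain
            return lo <= value <= hi and float(value).is_integer()
        return value in self.domain

    def sample(self, rng: np.random.Generator) -> Any:
        if self.kind == "continuous":
            lo, hi = self.domain
            if self.scale == "log":
                return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))
            return float(rng.uniform(lo, hi))
        if self.kind == "integer":
            lo, hi = self.domain
            if self.scale == "log":
                return int(round(10 ** rng.uniform(math.log10(lo), math.log10(hi))))
            return int(rng.integers(lo, hi + 1))
        return self.domain[int(rng.integers(len(self.domain)))]

    def position(self, value: Any) -> float:
        """Map a numeric value to [0, 1] on the spec's scale."""
        lo, hi = self.domain
        if self.scale == "log":
            lo, hi, value = math.log10(lo), math.log10(hi), math.log10(value)
        span = hi - lo
        if span == 0:
            return 0.0
        return (value - lo) / span


@dataclass(frozen=True)
class AlgorithmSpec:
    id: str
    task: str  # classification | regression | both
    hyper_parameters: tuple = ()

    def __post_init__(self):
        if self.task not in ("classification", "regression", "both"):
            raise SpecError(f"unknown task {self.task!r}")
        _check_acyclic(self.hyper_parameters, self.id)

    def supports(self, task: str) -> bool:
        return self.task in (task, "both")

    def spec(self, name: str) -> HyperParameterSpec:
        for hp in self.hyper_parameters:
            if hp.name == name:
                return hp
        raise RegistryError(f"{self.id} has no hyper-parameter {name!r}")


@dataclass(frozen=True)
class FeatureSelectionSpec:
    """A feature-selection technique = feature evaluator x feature search method."""

    id: str
    evaluator_id: str
    search_method_id: str
    hyper_parameters: tuple = ()

    def __post_init__(self):
        if self.id == NONE_FS_ID and self.hyper_parameters:
            raise SpecError('"none" technique takes no hyper-parameters')
        _check_acyclic(self.hyper_parameters, self.id)


@dataclass(frozen=True)
class AggregationPair:
    """An (operator, lookback period) choice for one longitudinal attribute."""

    operator_id: str
    period_days: int

    def __post_init__(self):
        if self.period_days <= 0:
            raise SpecError("period_days must be positive")


def pair_token(pair: AggregationPair) -> str:
    """Compact token for an aggregation pair, usable as a categorical choice."""
    return f"{pair.operator_id}@{pair.period_days}"


def parse_pair_token(token: str) -> list[AggregationPair]:
    """Inverse of :func:`pair_token`; '+'-joined tokens give a multi-pair plan."""
    out = []
    for part in token.split("+"):
        op, period = part.split("@")
        out.append(AggregationPair(op, int(period)))
    return out


def aggregation_plan(config: "Configuration") -> dict:
    """The aggregation plan a configuration implies: explicit
    ``aggregation_assignment`` entries plus any ``agg:<attribute>``
    hyper-parameter tokens."""
    plan: dict[str, list[AggregationPair]] = {
        a: [p] for a, p in config.aggregation_assignment}
    for k, v in config.assignment:
        if k.startswith("agg:"):
            plan[k[4:]] = parse_pair_token(v)
    return plan


def _check_acyclic(specs: Sequence[HyperParameterSpec], owner: str) -> None:
    names = {hp.name for hp in specs}
    parent = {hp.name: hp.condition.parent for hp in specs if hp.condition}
    for bad in set(parent.values()) - names:
        raise SpecError(f"{owner}: condition parent {bad!r} not a hyper-parameter")
    for start in parent:
        seen, node = set(), start
        while node in parent:
            if node in seen:
                raise SpecError(f"{owner}: conditional cycle through {node!r}")
            seen.add(node)
            node = parent[node]


def _topo_order(specs: Sequence[HyperParameterSpec]) -> list[HyperParameterSpec]:
    ordered: list[HyperParameterSpec] = []
    placed: set[str] = set()
    pending = list(specs)
    while pending:
        progressed = False
        for hp in list(pending):
            if hp.condition is None or hp.condition.parent in placed:
                ordered.append(hp)
                placed.add(hp.name)
                pending.remove(hp)
                progressed = True
        if not progressed:  # unreachable after _check_acyclic
            raise SpecError("conditional cycle")
    return ordered


@dataclass(frozen=True)
class Configuration:
    """One candidate pipeline: algorithm, feature-selection technique (a special
    hyper-parameter), concrete values for every *active* hyper-parameter, and an
    optional per-attribute temporal-aggregation assignment."""

    algorithm_id: str
    fs_id: str
    assignment: tuple = ()  # sorted ((name, value), ...) pairs
    aggregation_assignment: tuple = ()  # sorted ((attribute_id, AggregationPair), ...)

    @staticmethod
    def make(algorithm_id, fs_id, assignment: Mapping[str, Any],
             aggregation_assignment: Mapping[str, AggregationPair] | None = None) -> "Configuration":
        agg = tuple(sorted((aggregation_assignment or {}).items()))
        return Configuration(algorithm_id, fs_id, tuple(sorted(assignment.items())), agg)

    @property
    def values(self) -> dict:
        return dict(self.assignment)

    @property
    def aggregation(self) -> dict:
        return dict(self.aggregation_assignment)

    def key(self) -> str:
        """Canonical serialization, used for deterministic tie-breaking."""
        parts = [self.algorithm_id, self.fs_id]
        parts += [f"{k}={v!r}" for k, v in self.assignment]
        parts += [f"{a}={p.operator_id}@{p.period_days}" for a, p in self.aggregation_assignment]
        return "|".join(parts)

    def to_dict(self) -> dict:
        return {
            "algorithm_id": self.algorithm_id,
            "fs_id": self.fs_id,
            "assignment": dict(self.assignment),
            "aggregation_assignment": {
                a: {"operator_id": p.operator_id, "period_days": p.period_days}
                for a, p in self.aggregation_assignment
            },
        }

    @staticmethod
    def from_dict(d: Mapping) -> "Configuration":
        agg = {a: AggregationPair(v["operator_id"], int(v["period_days"]))
               for a, v in d.get("aggregation_assignment", {}).items()}
        return Configuration.make(d["algorithm_id"], d["fs_id"], d.get("assignment", {}), agg)


class Registry:
    """Holds the algorithm and feature-selection specs available to a search."""

    def __init__(self):
        self._algorithms: dict[str, AlgorithmSpec] = {}
        self._fs: dict[str, FeatureSelectionSpec] = {}

    # -- registration -------------------------------------------------
    def add_algorithm(self, spec: AlgorithmSpec) -> "Registry":
        if spec.id in self._algorithms:
            raise SpecError(f"duplicate algorithm id {spec.id!r}")
        self._algorithms[spec.id] = spec
        return self

    def add_feature_selection(self, spec: FeatureSelectionSpec) -> "Registry":
        if spec.id in self._fs:
            raise SpecError(f"duplicate feature-selection id {spec.id!r}")
        for other in self._fs.values():
            if (other.evaluator_id, other.search_method_id) == (spec.evaluator_id, spec.search_method_id):
                raise SpecError(
                    f"(evaluator, search method) pair of {spec.id!r} duplicates {other.id!r}")
        self._fs[spec.id] = spec
        return self

    # -- lookup -------------------------------------------------------
    def algorithm(self, algorithm_id: str) -> AlgorithmSpec:
        try:
            return self._algorithms[algorithm_id]
        except KeyError:
            raise RegistryError(f"unknown algorithm {algorithm_id!r}") from None

    def feature_selection(self, fs_id: str) -> FeatureSelectionSpec:
        try:
            return self._fs[fs_id]
        except KeyError:
            raise RegistryError(f"unknown feature-selection technique {fs_id!r}") from None

    def algorithms(self, task: str | None = None) -> list[AlgorithmSpec]:
        specs = list(self._algorithms.values())
        if task is not None:
            specs = [s for s in specs if s.supports(task)]
        return specs

    def feature_selections(self) -> list[FeatureSelectionSpec]:
        return list(self._fs.values())

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        def hp_dict(hp: HyperParameterSpec) -> dict:
            d = {"name": hp.name, "kind": hp.kind, "domain": list(hp.domain),
                 "default": hp.default, "scale": hp.scale}
            if hp.condition is not None:
                d["condition"] = {"parent": hp.condition.parent,
                                  "values": list(hp.condition.values)}
            return d

        return {
            "algorithms": [
                {"id": a.id, "task": a.task,
                 "hyper_parameters": [hp_dict(hp) for hp in a.hyper_parameters]}
                for a in self._algorithms.values()],
            "feature_selections": [
                {"id": f.id, "evaluator_id": f.evaluator_id,
                 "search_method_id": f.search_method_id,
                 "hyper_parameters": [hp_dict(hp) for hp in f.hyper_parameters]}
                for f in self._fs.values()],
        }

    @staticmethod
    def from_dict(d: Mapping) -> "Registry":
        def hp_from(h: Mapping) -> HyperParameterSpec:
            cond = None
            if "condition" in h and h["condition"] is not None:
                cond = Condition(h["condition"]["parent"], tuple(h["condition"]["values"]))
            return HyperParameterSpec(h["name"], h["kind"], tuple(h["domain"]),
                                      h["default"], h.get("scale", "linear"), cond)

        reg = Registry()
        for a in d.get("algorithms", []):
            reg.add_algorithm(AlgorithmSpec(
                a["id"], a["task"], tuple(hp_from(h) for h in a.get("hyper_parameters", []))))
        for f in d.get("feature_selections", []):
            reg.add_feature_selection(FeatureSelectionSpec(
                f["id"], f["evaluator_id"], f["search_method_id"],
                tuple(hp_from(h) for h in f.get("hyper_parameters", []))))
        return reg

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "Registry":
        return Registry.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# default registry
# ---------------------------------------------------------------------------

def _hp(name, kind, domain, default, scale="linear", condition=None):
    return HyperParameterSpec(name, kind, tuple(domain), default, scale, condition)


def default_registry() -> Registry:
    """Registry with a compact but representative catalog of learners and
    feature-selection techniques; user-extensible via YAML config."""
    reg = Registry()

    reg.add_algorithm(AlgorithmSpec("logistic", "classification", (
        _hp("C", "continuous", (1e-3, 1e3), 1.0, scale="log"),
        _hp("penalty", "categorical", ("l2", "none"), "l2"),
    )))
    reg.add_algorithm(AlgorithmSpec("svm", "classification", (
        _hp("C", "continuous", (1e-3, 1e3), 1.0, scale="log"),
        _hp("kernel", "categorical", ("rbf", "poly", "linear"), "rbf"),
        _hp("gamma", "continuous", (1e-4, 1e1), 0.1, scale="log",
            condition=Condition("kernel", ("rbf", "poly"))),
        _hp("degree", "integer", (2, 5), 3, condition=Condition("kernel", ("poly",))),
        _hp("tol", "continuous", (1e-5, 1e-2), 1e-3, scale="log"),
    )))
    reg.add_algorithm(AlgorithmSpec("decision_tree", "both", (
        _hp("max_depth", "integer", (1, 20), 6),
        _hp("min_samples_leaf", "integer", (1, 50), 5),
    )))
    reg.add_algorithm(AlgorithmSpec("random_forest", "both", (
        _hp("n_trees", "integer", (10, 300), 100),
        _hp("max_features_frac", "continuous", (0.05, 1.0), 0.3),
        _hp("min_samples_leaf", "integer", (1, 20), 2),
    )))
    reg.add_algorithm(AlgorithmSpec("gradient_boosting", "both", (
        _hp("n_trees", "integer", (10, 300), 100),
        _hp("learning_rate", "continuous", (1e-3, 1.0), 0.1, scale="log"),
        _hp("max_depth", "integer", (1, 8), 3),
    )))
    reg.add_algorithm(AlgorithmSpec("knn", "both", (
        _hp("n_neighbors", "integer", (1, 50), 5),
        _hp("weights", "categorical", ("uniform", "distance"), "uniform"),
    )))
    reg.add_algorithm(AlgorithmSpec("ridge", "regression", (
        _hp("alpha", "continuous", (1e-4, 1e4), 1.0, scale="log"),
    )))

    reg.add_feature_selection(FeatureSelectionSpec(NONE_FS_ID, "none", "none"))
    reg.add_feature_selection(FeatureSelectionSpec("univariate_rank", "anova_f", "rank_top", (
        _hp("keep_fraction", "continuous", (0.1, 1.0), 0.5),
    )))
    reg.add_feature_selection(FeatureSelectionSpec("mutual_info_rank", "mutual_info", "rank_top", (
        _hp("keep_fraction", "continuous", (0.1, 1.0), 0.5),
    )))
    reg.add_feature_selection(FeatureSelectionSpec("correlation_greedy", "correlation", "greedy_forward", (
        _hp("keep_fraction", "continuous", (0.1, 1.0), 0.5),
    )))
    reg.add_feature_selection(FeatureSelectionSpec("tree_importance_rank", "tree_importance", "rank_top", (
        _hp("keep_fraction", "continuous", (0.1, 1.0), 0.5),
        _hp("n_trees", "integer", (10, 100), 50),
    )))
    return reg


# ---------------------------------------------------------------------------
# configuration construction
# ---------------------------------------------------------------------------

def _resolve(specs: Sequence[HyperParameterSpec], choose: Callable[[HyperParameterSpec], Any]) -> dict:
    """Assign exactly the active hyper-parameters, respecting conditions."""
    assignment: dict[str, Any] = {}
    for hp in _topo_order(specs):
        if hp.condition is None or hp.condition.satisfied(assignment):
            assignment[hp.name] = choose(hp)
    return assignment


def _namespaced_fs_specs(fs: FeatureSelectionSpec) -> list[HyperParameterSpec]:
    """fs hyper-parameters live under 'fs:<fs_id>:' so techniques never collide."""
    out = []
    for hp in fs.hyper_parameters:
        cond = hp.condition
        if cond is not None:
            cond = Condition(f"fs:{fs.id}:{cond.parent}", cond.values)
        out.append(HyperParameterSpec(f"fs:{fs.id}:{hp.name}", hp.kind, hp.domain,
                                      hp.default, hp.scale, cond))
    return out


def _joint_specs(algorithm: AlgorithmSpec, fs: FeatureSelectionSpec) -> list[HyperParameterSpec]:
    return list(algorithm.hyper_parameters) + _namespaced_fs_specs(fs)


def default_configuration(algorithm: AlgorithmSpec, fs: FeatureSelectionSpec) -> Configuration:
    """Configuration carrying every active hyper-parameter's default value."""
    assignment = _resolve(_joint_specs(algorithm, fs), lambda hp: hp.default)
    return Configuration.make(algorithm.id, fs.id, assignment)


def sample_configuration(algorithm: AlgorithmSpec,
                         fs_pool: Sequence[FeatureSelectionSpec],
                         rng: np.random.Generator | int) -> Configuration:
    """Uniform draw: technique uniform over the pool, numeric values uniform on
    each spec's scale, categoricals uniform over choices; only active
    hyper-parameters are assigned."""
    if not fs_pool:
        raise SpecError("empty feature-selection pool")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    fs = fs_pool[int(rng.integers(len(fs_pool)))]
    assignment = _resolve(_joint_specs(algorithm, fs), lambda hp: hp.sample(rng))
    return Configuration.make(algorithm.id, fs.id, assignment)


def _spec_lookup(registry: Registry, config: Configuration) -> dict[str, HyperParameterSpec]:
    algo = registry.algorithm(config.algorithm_id)
    fs = registry.feature_selection(config.fs_id)
    return {hp.name: hp for hp in _joint_specs(algo, fs)}


def config_distance(a: Configuration, b: Configuration, registry: Registry) -> float:
    """Normalized distance in [0, 1] between two configurations of one algorithm.

    Mean over the union of active dimensions (plus the fs_id dimension) of
    per-dimension distances: numeric dims use |difference on the spec's scale|
    normalized by the span, categorical/boolean dims are 0/1, and a dimension
    active on only one side counts as maximally different (1).
    """
    if a.algorithm_id != b.algorithm_id:
        raise ValueError("config_distance is defined within one algorithm's space")
    specs_a, specs_b = _spec_lookup(registry, a), _spec_lookup(registry, b)
    va, vb = a.values, b.values
    dims = sorted(set(va) | set(vb))
    total = 0.0 if a.fs_id == b.fs_id else 1.0  # fs_id is a categorical dimension
    for name in dims:
        if name in va and name in vb:
            hp = specs_a.get(name) or specs_b[name]
            if hp.is_numeric:
                total += abs(hp.position(va[name]) - hp.position(vb[name]))
            else:
                total += 0.0 if va[name] == vb[name] else 1.0
        else:
            total += 1.0
    return total / (len(dims) + 1)


def encode_configuration(config: Configuration, algorithm: AlgorithmSpec,
                         registry: Registry) -> np.ndarray:
    """Fixed-length numeric encoding for surrogate regression.

    Numeric dims map to their [0, 1] scale position (-1 when inactive);
    categorical/boolean dims one-hot over the declared choices; the fs_id is
    one-hot over all registered techniques.
    """
    values = config.values
    features: list[float] = []
    all_fs = sorted(f.id for f in registry.feature_selections())
    features += [1.0 if config.fs_id == f else 0.0 for f in all_fs]
    specs: list[HyperParameterSpec] = list(algorithm.hyper_parameters)
    for f in sorted(registry.feature_selections(), key=lambda s: s.id):
        specs += _namespaced_fs_specs(f)
    for hp in specs:
        if hp.is_numeric:
            features.append(hp.position(values[hp.name]) if hp.name in values else -1.0)
        else:
            for choice in hp.domain:
                features.append(1.0 if values.get(hp.name) == choice else 0.0)
    return np.asarray(features, dtype=float)


def enumerate_configurations(algorithm: AlgorithmSpec,
                             fs_pool: Sequence[FeatureSelectionSpec],
                             max_size: int | None = None) -> list[Configuration] | None:
    """Full enumeration of a finite space (no continuous dims, small integer
    ranges).  Returns None when the space is not enumerable or exceeds
    ``max_size``.  Order is canonical (sorted by configuration key)."""
    configs: list[Configuration] = []
    for fs in sorted(fs_pool, key=lambda f: f.id):
        specs = _topo_order(_joint_specs(algorithm, fs))
        domains: list[tuple] = []
        for hp in specs:
            if hp.kind == "continuous":
                return None
            if hp.kind == "integer":
                lo, hi = hp.domain
                if hi - lo + 1 > 25:
                    return None
                domains.append(tuple(range(int(lo), int(hi) + 1)))
            else:
                domains.append(tuple(hp.domain))
        for combo in itertools.product(*domains) if specs else [()]:
            partial: dict[str, Any] = {}
            ok = True
            for hp, value in zip(specs, combo):
                if hp.condition is None or hp.condition.satisfied(partial):
                    partial[hp.name] = value
                # inactive dims: any value in the product collapses to the same
                # configuration; keep only the canonical (first) expansion
            configs.append(Configuration.make(algorithm.id, fs.id, partial))
        if max_size is not None and len(configs) > max_size:
            return None
    # collapsing inactive dims creates duplicates; deduplicate canonically
    uniq = sorted(set(configs), key=lambda c: c.key())
    if max_size is not None and len(uniq) > max_size:
        return None
    return uniq
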