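"""Temporal aggregation of longitudinal clinical attributes.

Clinical attributes (weight, lab values, diagnoses, ...) are recorded
repeatedly over time; prediction models need one value per patient.  Each
attribute is collapsed through an (operator, lookback period) pair — e.g.
"slope of weight over the 365 days before the index date".  The lookback
window is half-open, ``(index_date - period_days, index_date]``: a record
exactly ``period_days`` before the index date is excluded, a record on the
index date is included.

The input schema is a minimal long-format table (person, attribute, ISO
timestamp, value) with a per-patient index date — an OMOP-inspired shape
without the vocabulary layer.  The pair choice per attribute can be exposed
to the staged search as an ordinary categorical hyper-parameter, so operators
and periods are selected jointly with the algorithm and feature-selection
technique.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import TabularDataset
from .search_space import (
    AggregationPair, AlgorithmSpec, HyperParameterSpec, Registry,
    pair_token, parse_pair_token,
)

__all__ = [
    "LongitudinalTable", "AggregationOperator", "AggregationPair",
    "operator_catalog", "aggregate", "expand_features", "pair_search_space",
    "augment_registry", "LongitudinalDataset",
    "DEFAULT_PERIOD_GRID", "pair_token", "parse_pair_token",
]

DEFAULT_PERIOD_GRID = (30, 90, 180, 365, 730)


class SchemaError(ValueError):
    """Operator/value-type mismatch or malformed long-format input."""


# ---------------------------------------------------------------------------
# long-format container
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalTable:
    """Long-format records plus per-patient index dates.

    ``records`` columns: person_id, attribute_id, timestamp, value.
    ``index_dates``: Series mapping person_id -> index timestamp.
    Timestamps may be datetimes or plain numbers (interpreted as days).
    """

    records: pd.DataFrame
    index_dates: pd.Series

    def __post_init__(self):
        need = {"person_id", "attribute_id", "timestamp", "value"}
        missing = need - set(self.records.columns)
        if missing:
            raise SchemaError(f"records missing columns {sorted(missing)}")
        unknown = set(self.records["person_id"]) - set(self.index_dates.index)
        if unknown:
            raise SchemaError(f"records for patients without an index date: {sorted(unknown)[:5]}")
        self.records = self.records.copy()
        self.records["timestamp"] = _as_days(self.records["timestamp"])
        self.index_dates = pd.Series(_as_days(pd.Series(self.index_dates)),
                                     index=self.index_dates.index)

    @classmethod
    def from_csv(cls, records_path, index_path) -> "LongitudinalTable":
        rec = pd.read_csv(records_path)
        idx = pd.read_csv(index_path)
        return cls(rec, idx.set_index(idx.columns[0]).iloc[:, 0])

    @property
    def patients(self) -> list:
        return sorted(self.index_dates.index)

    def attribute_values(self, attribute_id: str) -> pd.Series:
        return self.records.loc[self.records["attribute_id"] == attribute_id, "value"]


def _as_days(s: pd.Series) -> np.ndarray:
    """Timestamps to float days on a common origin."""
    if np.issubdtype(np.asarray(s).dtype, np.number):
        return np.asarray(s, dtype=float)
    dt = pd.to_datetime(s)
    return (dt - pd.Timestamp("1970-01-01")).dt.total_seconds().to_numpy() / 86400.0


# ---------------------------------------------------------------------------
# operator catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AggregationOperator:
    """One aggregation operator.

    ``func(values, offsets)`` receives in-window values and their offsets in
    days before the index date (offsets in ``[0, period)``, most recent
    first), and returns a scalar or None (missing).  Operators are
    order-invariant given the (timestamp, value) multiset; inputs arrive
    canonically sorted.  ``empty_value`` is the result on an empty window
    (None = missing; the count family returns 0).
    """

    id: str
    applicability: str  # numeric | categorical | both
    func: Callable
    empty_value: float | None = None
    min_points: int = 1

    def apply(self, values: np.ndarray, offsets: np.ndarray):
        if len(values) == 0:
            return self.empty_value
        if len(values) < self.min_points:
            return None
        return self.func(values, offsets)


def _slope(values, offsets):
    # per-day OLS slope on calendar time (t = -offset so later = larger t)
    t = -offsets
    if len(np.unique(t)) < 2:
        return None
    t_c = t - t.mean()
    return float((t_c * (values - values.mean())).sum() / (t_c ** 2).sum())


def _increasing(values, offsets):
    order = np.argsort(-offsets, kind="stable")  # oldest -> newest
    v = values[order]
    return 1.0 if np.all(np.diff(v) >= 0) else 0.0


def _mode(values, offsets):
    ser = pd.Series(values).astype(str)
    counts = ser.value_counts()
    top = counts[counts == counts.max()].index
    return sorted(top)[0]


def operator_catalog(fraction_threshold: float = 0.0) -> list[AggregationOperator]:
    """The catalog of regularly used temporal-aggregation operators.

    ``fraction_threshold`` parameterizes ``fraction_above`` (fraction of
    in-window values strictly above the threshold).
    """
    num = "numeric"
    ops = [
        AggregationOperator("count", "both", lambda v, o: float(len(v)), empty_value=0.0),
        AggregationOperator("exists", "both", lambda v, o: 1.0, empty_value=0.0),
        AggregationOperator("mean", num, lambda v, o: float(np.mean(v))),
        AggregationOperator("maximum", num, lambda v, o: float(np.max(v))),
        AggregationOperator("minimum", num, lambda v, o: float(np.min(v))),
        AggregationOperator("sum", num, lambda v, o: float(np.sum(v))),
        # sample SD; a single point has no spread -> missing
        AggregationOperator("std", num, lambda v, o: float(np.std(v, ddof=1)), min_points=2),
        AggregationOperator("range", num, lambda v, o: float(np.max(v) - np.min(v))),
        AggregationOperator("most_recent", "both", lambda v, o: v[np.argmin(o)]),
        AggregationOperator("earliest", "both", lambda v, o: v[np.argmax(o)]),
        AggregationOperator("time_since_last", "both", lambda v, o: float(np.min(o))),
        AggregationOperator("slope", num, _slope, min_points=2),
        # 1 iff non-decreasing in time with >= 2 points; a singleton is 0
        AggregationOperator("increasing_trend", num,
                            lambda v, o: 0.0 if len(v) < 2 else _increasing(v, o)),
        AggregationOperator("fraction_above", num,
                            lambda v, o, thr=fraction_threshold: float(np.mean(v > thr))),
        AggregationOperator("distinct_count", "both",
                            lambda v, o: float(len(pd.unique(pd.Series(v).astype(str)))),
                            empty_value=0.0),
        AggregationOperator("mode", "categorical", _mode),
    ]
    assert len({op.id for op in ops}) == len(ops)
    return ops


_CATALOG = {op.id: op for op in operator_catalog()}

_NUMERIC_ONLY = {op.id for op in operator_catalog() if op.applicability == "numeric"}
_CATEGORICAL_ONLY = {op.id for op in operator_catalog() if op.applicability == "categorical"}


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _window(table: LongitudinalTable, attribute_id, patient_id, period_days: int):
    idx = table.index_dates.loc[patient_id]
    rec = table.records
    mask = ((rec["person_id"] == patient_id)
            & (rec["attribute_id"] == attribute_id)
            & (rec["timestamp"] > idx - period_days)
            & (rec["timestamp"] <= idx))
    sub = rec.loc[mask, ["timestamp", "value"]]
    # canonical order: by (timestamp, value) so permuting input rows is a no-op
    sub = sub.sort_values(["timestamp", "value"], kind="stable")
    offsets = (idx - sub["timestamp"].to_numpy(dtype=float))
    return sub["value"].to_numpy(), offsets


def _check_applicable(op: AggregationOperator, values) -> None:
    numeric = len(values) == 0 or np.issubdtype(np.asarray(values).dtype, np.number)
    if op.applicability == "numeric" and not numeric:
        raise SchemaError(f"operator {op.id!r} needs numeric values")
    if op.applicability == "categorical" and numeric and len(values):
        raise SchemaError(f"operator {op.id!r} expects categorical values")


def aggregate(table: LongitudinalTable, attribute_id: str, pair: AggregationPair,
              patient_id) -> float | str | None:
    """Apply one (operator, period) pair to one patient's attribute records.

    Empty window -> missing (None), except the count family which returns 0.
    """
    op = _CATALOG.get(pair.operator_id)
    if op is None:
        raise SchemaError(f"unknown operator {pair.operator_id!r}")
    values, offsets = _window(table, attribute_id, patient_id, pair.period_days)
    _check_applicable(op, values)
    if len(values) and op.applicability == "numeric":
        values = values.astype(float)
    return op.apply(values, offsets)


def _aggregate_column(table: LongitudinalTable, attribute_id: str,
                      pair: AggregationPair) -> dict:
    """All patients' aggregates for one (attribute, pair) in one grouped pass
    (same semantics as :func:`aggregate`)."""
    op = _CATALOG.get(pair.operator_id)
    if op is None:
        raise SchemaError(f"unknown operator {pair.operator_id!r}")
    rec = table.records[table.records["attribute_id"] == attribute_id]
    out = {pid: op.empty_value for pid in table.patients}
    for pid, sub in rec.groupby("person_id", sort=False):
        idx = table.index_dates.loc[pid]
        sub = sub[(sub["timestamp"] > idx - pair.period_days) & (sub["timestamp"] <= idx)]
        sub = sub.sort_values(["timestamp", "value"], kind="stable")
        values = sub["value"].to_numpy()
        _check_applicable(op, values)
        if len(values) and op.applicability == "numeric":
            values = values.astype(float)
        out[pid] = op.apply(values, idx - sub["timestamp"].to_numpy(dtype=float))
    return out


def expand_features(table: LongitudinalTable,
                    plan: Mapping[str, Sequence[AggregationPair]]) -> pd.DataFrame:
    """Wide per-patient feature matrix: one column per (attribute, pair).

    Columns are named ``{attribute}__{operator}__{period}d`` and ordered by
    (attribute, operator, period); rows are patients with an index date in
    sorted order.  Missing aggregates are NaN.
    """
    patients = table.patients
    columns: dict[str, list] = {}
    for attr in sorted(plan):
        pairs = sorted(set(plan[attr]), key=lambda p: (p.operator_id, p.period_days))
        for pair in pairs:
            name = f"{attr}__{pair.operator_id}__{pair.period_days}d"
            col = _aggregate_column(table, attr, pair)
            columns[name] = [np.nan if col[pid] is None else col[pid] for pid in patients]
    return pd.DataFrame(columns, index=pd.Index(patients, name="person_id"))


# ---------------------------------------------------------------------------
# search integration: pairs as hyper-parameters
# ---------------------------------------------------------------------------

def pair_search_space(attributes: Sequence[str],
                      operators: Sequence[str] = ("mean", "maximum", "count", "slope"),
                      periods: Sequence[int] = DEFAULT_PERIOD_GRID,
                      choose_k: int = 1) -> list[HyperParameterSpec]:
    """One categorical hyper-parameter per longitudinal attribute whose domain
    enumerates the (operator, period) choices (k-subsets under choose-k), so
    the staged search selects aggregation pairs jointly with the algorithm and
    feature-selection choices."""
    if not periods:
        raise ValueError("periods must be nonempty")
    specs = []
    singles = [pair_token(AggregationPair(op, p))
               for op in operators for p in periods]
    for attr in attributes:
        if choose_k == 1:
            domain = tuple(singles)
        else:
            domain = tuple("+".join(sorted(c))
                           for c in itertools.combinations(sorted(singles), choose_k))
        specs.append(HyperParameterSpec(f"agg:{attr}", "categorical", domain, domain[0]))
    return specs


def augment_registry(registry: Registry, agg_specs: Sequence[HyperParameterSpec]) -> Registry:
    """Return a registry whose every algorithm carries the aggregation
    hyper-parameters, making pair choice part of each configuration."""
    out = Registry.from_dict(registry.to_dict())
    new = Registry()
    for a in out.algorithms():
        new.add_algorithm(AlgorithmSpec(a.id, a.task,
                                        tuple(a.hyper_parameters) + tuple(agg_specs)))
    for f in out.feature_selections():
        new.add_feature_selection(f)
    return new


def aggregation_from_assignment(values: Mapping) -> dict[str, list[AggregationPair]]:
    """Parse ``agg:<attribute>`` hyper-parameter tokens into a plan."""
    plan = {}
    for k, v in values.items():
        if k.startswith("agg:"):
            plan[k[4:]] = parse_pair_token(v)
    return plan


class LongitudinalDataset(TabularDataset):
    """Dataset whose features are built on demand from a longitudinal table.

    ``materialize`` turns a configuration's aggregation choice (either an
    explicit assignment or ``agg:`` hyper-parameter tokens resolved upstream)
    into the wide matrix, concatenated with any static features.  Expanded
    columns are cached per (attribute, pair) so a search re-uses work across
    configurations.
    """

    def __init__(self, table: LongitudinalTable, y: pd.Series, task: str,
                 static_features: pd.DataFrame | None = None,
                 default_plan: Mapping[str, Sequence[AggregationPair]] | None = None):
        self.table = table
        patients = table.patients
        y = pd.Series(np.asarray(y), name=getattr(y, "name", "y"))
        if len(y) != len(patients):
            raise SchemaError("one outcome per patient with an index date required")
        self.default_plan = dict(default_plan or {})
        self.static_features = (static_features.reset_index(drop=True)
                                if static_features is not None else None)
        self._cache: dict[str, pd.Series] = {}
        feats = self._build(self.default_plan)
        super().__init__(feats, y, task)

    def _build(self, plan: Mapping[str, Sequence[AggregationPair]]) -> pd.DataFrame:
        pieces = []
        if self.static_features is not None:
            pieces.append(self.static_features)
        cols = {}
        for attr in sorted(plan):
            for pair in sorted(set(plan[attr]), key=lambda p: (p.operator_id, p.period_days)):
                name = f"{attr}__{pair.operator_id}__{pair.period_days}d"
                if name not in self._cache:
                    col = _aggregate_column(self.table, attr, pair)
                    self._cache[name] = pd.Series(
                        [np.nan if col[pid] is None else col[pid]
                         for pid in self.table.patients], name=name)
                cols[name] = self._cache[name].reset_index(drop=True)
        if cols:
            pieces.append(pd.DataFrame(cols))
        if not pieces:
            raise SchemaError("no features: empty plan and no static features")
        return pd.concat(pieces, axis=1).astype(float)

    def materialize(self, aggregation_assignment: Mapping | None = None):
        if not aggregation_assignment:
            return self.features, self.y
        plan = {a: (p if isinstance(p, (list, tuple)) else [p])
                for a, p in aggregation_assignment.items()}
        return self._build(plan), self.y
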