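"""Aggregation operators, lookback-window semantics, feature expansion, and
the pair-as-hyper-parameter search integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clinautoml.search_space import AggregationPair, parse_pair_token
from clinautoml.temporal import (
    DEFAULT_PERIOD_GRID, LongitudinalDataset, LongitudinalTable, SchemaError,
    aggregate, expand_features, operator_catalog, pair_search_space, pair_token,
)


def _table(rows, index=None):
    rec = pd.DataFrame(rows, columns=["person_id", "attribute_id", "timestamp", "value"])
    patients = sorted({r[0] for r in rows}) or ["p1"]
    idx = pd.Series(index if index is not None else 730.0,
                    index=sorted(set(patients) | {"p1"}))
    return LongitudinalTable(rec, idx)


@pytest.fixture(scope="module")
def weights_table():
    # weights at 300, 200, 10 days before the index date: 70, 72, 75
    return _table([("p1", "w", 430.0, 70.0), ("p1", "w", 530.0, 72.0),
                   ("p1", "w", 720.0, 75.0)])


class TestCatalog:
    def test_size_and_named_operators(self):
        ops = operator_catalog()
        ids = {op.id for op in ops}
        assert len(ops) >= 14
        assert {"increasing_trend", "mean", "count", "maximum"} <= ids
        assert len(ids) == len(ops)

    def test_applicability_declared(self):
        ops = {op.id: op for op in operator_catalog()}
        assert ops["mean"].applicability == "numeric"
        assert ops["mode"].applicability == "categorical"
        assert ops["count"].applicability == "both"


class TestAggregate:
    def test_rising_weight_example(self, weights_table):
        t = weights_table
        assert aggregate(t, "w", AggregationPair("increasing_trend", 365), "p1") == 1.0
        assert aggregate(t, "w", AggregationPair("count", 365), "p1") == 3.0
        assert aggregate(t, "w", AggregationPair("mean", 365), "p1") == pytest.approx(72.3333, abs=1e-3)

    def test_slope_needs_two_points(self, weights_table):
        # only the 10-days-ago point falls in a 30-day window
        assert aggregate(weights_table, "w", AggregationPair("slope", 30), "p1") is None
        assert aggregate(weights_table, "w", AggregationPair("count", 30), "p1") == 1.0

    def test_window_half_open_at_far_end(self):
        t = _table([("p1", "w", 365.0, 1.0)])  # exactly period_days before index 730
        assert aggregate(t, "w", AggregationPair("count", 365), "p1") == 0.0
        t2 = _table([("p1", "w", 730.0, 1.0)])  # on the index date: included
        assert aggregate(t2, "w", AggregationPair("count", 365), "p1") == 1.0

    def test_empty_window_missing_except_count_family(self):
        t = _table([("p1", "w", 10.0, 1.0)])
        for op in ("mean", "maximum", "slope", "most_recent"):
            assert aggregate(t, "w", AggregationPair(op, 30), "p1") is None
        assert aggregate(t, "w", AggregationPair("count", 30), "p1") == 0.0
        assert aggregate(t, "w", AggregationPair("exists", 30), "p1") == 0.0
        assert aggregate(t, "w", AggregationPair("distinct_count", 30), "p1") == 0.0

    def test_slope_value(self):
        # values rise 1 unit per 100 days
        t = _table([("p1", "w", 530.0, 1.0), ("p1", "w", 630.0, 2.0),
                    ("p1", "w", 730.0, 3.0)])
        assert aggregate(t, "w", AggregationPair("slope", 365), "p1") == pytest.approx(0.01)

    def test_time_since_last_and_recency(self, weights_table):
        t = weights_table
        assert aggregate(t, "w", AggregationPair("time_since_last", 365), "p1") == 10.0
        assert aggregate(t, "w", AggregationPair("most_recent", 365), "p1") == 75.0
        assert aggregate(t, "w", AggregationPair("earliest", 365), "p1") == 70.0

    def test_mode_with_lexicographic_tie_break(self):
        t = _table([("p1", "c", 700.0, "b"), ("p1", "c", 710.0, "a"),
                    ("p1", "c", 720.0, "a"), ("p1", "c", 725.0, "b")])
        assert aggregate(t, "c", AggregationPair("mode", 365), "p1") == "a"

    def test_type_mismatch_rejected(self):
        t = _table([("p1", "c", 720.0, "high")])
        with pytest.raises(SchemaError):
            aggregate(t, "c", AggregationPair("mean", 365), "p1")
        tn = _table([("p1", "w", 720.0, 1.0)])
        with pytest.raises(SchemaError):
            aggregate(tn, "w", AggregationPair("mode", 365), "p1")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(values=st.lists(st.floats(-100, 100), min_size=1, max_size=12),
           offsets_seed=st.integers(0, 10_000))
    def test_numeric_invariants_on_random_tables(self, values, offsets_seed):
        rng = np.random.default_rng(offsets_seed)
        times = 730.0 - rng.uniform(0, 364, len(values))
        rows = [("p1", "w", float(t), float(v)) for t, v in zip(times, values)]
        t = _table(rows)
        pair = lambda op: AggregationPair(op, 365)
        mean = aggregate(t, "w", pair("mean"), "p1")
        lo = aggregate(t, "w", pair("minimum"), "p1")
        hi = aggregate(t, "w", pair("maximum"), "p1")
        assert lo - 1e-9 <= mean <= hi + 1e-9
        assert aggregate(t, "w", pair("count"), "p1") == len(values)
        assert aggregate(t, "w", pair("increasing_trend"), "p1") in (0.0, 1.0)
        assert aggregate(t, "w", pair("range"), "p1") == pytest.approx(hi - lo)


class TestExpandFeatures:
    def test_column_count_and_order(self, weights_table):
        plan = {"w": [AggregationPair("mean", 365), AggregationPair("count", 90),
                      AggregationPair("count", 365)]}
        wide = expand_features(weights_table, plan)
        assert list(wide.columns) == ["w__count__90d", "w__count__365d", "w__mean__365d"]

    def test_record_order_permutation_invariance(self):
        rng = np.random.default_rng(4)
        rows = [("p%d" % (i % 5), "w", float(rng.uniform(0, 730)), float(rng.normal()))
                for i in range(60)]
        plan = {"w": [AggregationPair(op, per) for op in ("mean", "slope", "count")
                      for per in (90, 365)]}
        base = expand_features(_table(rows), plan)
        for seed in (1, 2):
            shuffled = [rows[i] for i in np.random.default_rng(seed).permutation(len(rows))]
            again = expand_features(_table(shuffled), plan)
            pd.testing.assert_frame_equal(base, again)

    def test_patient_without_records(self):
        t = _table([("p1", "w", 720.0, 1.0)], index=730.0)
        t.index_dates = pd.Series({"p1": 730.0, "p2": 730.0})
        wide = expand_features(t, {"w": [AggregationPair("mean", 365),
                                         AggregationPair("count", 365)]})
        assert wide.loc["p2", "w__count__365d"] == 0.0
        assert np.isnan(wide.loc["p2", "w__mean__365d"])


class TestPairSearchSpace:
    def test_product_count(self):
        specs = pair_search_space(["w"], operators=("mean", "slope", "count", "maximum"),
                                  periods=DEFAULT_PERIOD_GRID)
        assert len(specs) == 1
        assert specs[0].name == "agg:w"
        assert len(specs[0].domain) == 20

    def test_choose_all_equals_full_plan(self, weights_table):
        ops, periods = ("mean", "count"), (90, 365)
        specs = pair_search_space(["w"], operators=ops, periods=periods, choose_k=4)
        assert len(specs[0].domain) == 1
        pairs = parse_pair_token(specs[0].domain[0])
        full = expand_features(weights_table, {"w": pairs})
        direct = expand_features(weights_table,
                                 {"w": [AggregationPair(o, p) for o in ops for p in periods]})
        pd.testing.assert_frame_equal(full, direct)

    def test_empty_periods_rejected(self):
        with pytest.raises(ValueError):
            pair_search_space(["w"], periods=())

    def test_token_roundtrip(self):
        pair = AggregationPair("slope", 180)
        assert parse_pair_token(pair_token(pair)) == [pair]


class TestLongitudinalDataset:
    def test_materialize_switches_plan(self, weights_table):
        y = pd.Series([0] * len(weights_table.patients))
        ds = LongitudinalDataset(weights_table, y, "classification",
                                 default_plan={"w": [AggregationPair("mean", 365)]})
        X0, _ = ds.materialize()
        assert list(X0.columns) == ["w__mean__365d"]
        X1, _ = ds.materialize({"w": [AggregationPair("count", 365)]})
        assert list(X1.columns) == ["w__count__365d"]

    def test_outcome_length_checked(self, weights_table):
        with pytest.raises(SchemaError):
            LongitudinalDataset(weights_table, pd.Series([0, 1, 0, 1]), "classification",
                                default_plan={"w": [AggregationPair("mean", 365)]})

    def test_record_without_index_date_rejected(self):
        rec = pd.DataFrame([("p9", "w", 1.0, 2.0)],
                           columns=["person_id", "attribute_id", "timestamp", "value"])
        with pytest.raises(SchemaError):
            LongitudinalTable(rec, pd.Series({"p1": 730.0}))

    def test_datetime_timestamps_supported(self):
        rec = pd.DataFrame([("p1", "w", "2023-06-01", 70.0),
                            ("p1", "w", "2023-12-01", 75.0)],
                           columns=["person_id", "attribute_id", "timestamp", "value"])
        t = LongitudinalTable(rec, pd.Series({"p1": "2024-01-01"}))
        assert aggregate(t, "w", AggregationPair("count", 365), "p1") == 2.0
        assert aggregate(t, "w", AggregationPair("increasing_trend", 365), "p1") == 1.0
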