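"""Monte-Carlo simulation of the national outcome impact of adopting an
automated model-selection tool.

The scenario: a health-care unit (emergency department, dialysis facility,
...) can use machine learning for a prediction problem only if a model can be
built there (probability ``p1``) and then deployed (probability ``p2``); the
adoption likelihood is ``L = p1 * p2``.  In adopting units the outcome rate
improves — a binary outcome (e.g. 30-day mortality) by an odds ratio, a count
outcome (e.g. annual hospitalization days) by a multiplicative reduction.
Unit totals are scaled by survey/discharge weights and summed to national
estimates; the with-tool and without-tool arms are compared by a paired test
(McNemar for binary outcomes) and a 5x5 sensitivity grid over (p1, p2)
levels.

Arms are paired by patient index.  The without-tool arm consumes its own
dedicated random stream, so it is bit-invariant to (p1, p2, effect size)
under a fixed seed; outcome draws are independent between arms (comonotone
draws would empty the discordant cells the McNemar test lives on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "ImpactScenario", "ImpactResults", "ImpactSimulation",
    "effective_rate", "simulate_scenario", "simulate_count_scenario",
    "paired_outcome_test", "sensitivity_grid", "probability_levels",
]


def effective_rate(r0: float, odds_ratio: float) -> float:
    """Outcome probability after applying an odds ratio to baseline ``r0``.

    r1 = OR*odds0 / (1 + OR*odds0) with odds0 = r0/(1-r0).  For rare outcomes
    r1/r0 -> OR (risk ratio ~ odds ratio).  Boundary rates return unchanged.
    """
    if not 0 <= r0 <= 1:
        raise ValueError("r0 must lie in [0, 1]")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if r0 in (0.0, 1.0):
        return r0
    odds = odds_ratio * r0 / (1 - r0)
    return odds / (1 + odds)


def probability_levels(p_min: float, p_max: float, n_levels: int = 5) -> np.ndarray:
    """Evenly spaced sensitivity levels from the minimum to the maximum value;
    the middle level is the default for hypothesis testing."""
    return np.linspace(p_min, p_max, n_levels)


def p1_levels_from_trial(successes: int, n: int, n_levels: int = 5) -> np.ndarray:
    """Convert an observed success proportion into sensitivity levels by a
    normal fit: min/max are the 2.5/97.5 percentile points of the sampling
    distribution, clipped to [0, 1]."""
    phat = successes / n
    se = math.sqrt(max(phat * (1 - phat), 1e-12) / n)
    lo = max(0.0, phat - 1.959964 * se)
    hi = min(1.0, phat + 1.959964 * se)
    return probability_levels(lo, hi, n_levels)


@dataclass
class ImpactScenario:
    """One simulation scenario.

    ``units`` needs columns ``unit_id``, ``n_patients``, ``weight``; an
    optional ``rate`` column gives unit-specific baseline rates for the binary
    model (else the national ``baseline_rate`` applies everywhere), and an
    optional ``days_mean`` column gives per-patient Poisson means for the
    count model (else ``total_days / n_patients`` per unit if ``total_days``
    exists, else ``baseline_mean``).
    """

    p1: float
    p2: float
    units: pd.DataFrame
    outcome: str = "binary"  # binary | count
    baseline_rate: float = 0.05  # placeholder default, a scenario parameter
    odds_ratio: float = 0.53
    baseline_mean: float = 10.0
    reduction_fraction: float = 0.15
    n_runs: int = 10
    seed: int = 0
    p1_levels: Sequence[float] | None = None
    p2_levels: Sequence[float] | None = None

    def __post_init__(self):
        for name in ("p1", "p2"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if not 0 <= self.reduction_fraction < 1:
            raise ValueError("reduction_fraction must lie in [0, 1)")
        need = {"unit_id", "n_patients", "weight"}
        if not need <= set(self.units.columns):
            raise ValueError(f"units table needs columns {sorted(need)}")
        if (self.units["weight"] <= 0).any():
            raise ValueError("weights must be positive")
        if self.outcome not in ("binary", "count"):
            raise ValueError("outcome must be 'binary' or 'count'")

    @property
    def L(self) -> float:
        return self.p1 * self.p2

    def unit_rates(self) -> np.ndarray:
        if "rate" in self.units.columns:
            return self.units["rate"].to_numpy(dtype=float)
        return np.full(len(self.units), self.baseline_rate)

    def unit_means(self) -> np.ndarray:
        if "days_mean" in self.units.columns:
            return self.units["days_mean"].to_numpy(dtype=float)
        if "total_days" in self.units.columns:
            return (self.units["total_days"] / self.units["n_patients"]).to_numpy(dtype=float)
        return np.full(len(self.units), self.baseline_mean)


@dataclass
class ImpactResults:
    """Per-run weighted national totals for both arms, the paired test on the
    first run's patient-level outcomes, and scenario metadata."""

    scenario: ImpactScenario
    per_run: pd.DataFrame  # run, with_total, without_total, adopted_units
    statistic: float
    p_value: float
    test_flag: str | None
    sensitivity: pd.DataFrame | None = None

    @property
    def with_total(self) -> float:
        return float(self.per_run["with_total"].mean())

    @property
    def without_total(self) -> float:
        return float(self.per_run["without_total"].mean())

    @property
    def difference(self) -> float:
        """Expected national events averted (without - with)."""
        return self.without_total - self.with_total

    def summary(self) -> str:
        sc = self.scenario
        kind = "30-day deaths" if sc.outcome == "binary" else "hospitalization days"
        lines = [
            "Adoption impact simulation",
            "=" * 42,
            f"units: {len(sc.units)}   runs: {sc.n_runs}   seed: {sc.seed}",
            f"p1 = {sc.p1:.3f}, p2 = {sc.p2:.3f}, L = {sc.L:.3f}",
            (f"baseline rate = {sc.baseline_rate:.4f}, odds ratio = {sc.odds_ratio:.2f}"
             if sc.outcome == "binary"
             else f"baseline mean = {sc.baseline_mean:.2f}, reduction = {sc.reduction_fraction:.0%}"),
            "-" * 42,
            f"weighted national {kind}, without tool: {self.without_total:,.0f}",
            f"weighted national {kind}, with tool:    {self.with_total:,.0f}",
            f"events averted:                         {self.difference:,.0f}",
            f"paired test: statistic = {self.statistic:.3f}, p = {self.p_value:.3g}"
            + (f" [{self.test_flag}]" if self.test_flag else ""),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _simulate_run(scenario: ImpactScenario, run: int, seed: int, collect_pairs: bool):
    units = scenario.units
    n_units = len(units)
    rng_adopt = np.random.default_rng([seed % (2 ** 31), 7, run])
    rng_with = np.random.default_rng([seed % (2 ** 31), 13, run])
    rng_without = np.random.default_rng([seed % (2 ** 31), 29, run])  # arm-dedicated

    adopted = rng_adopt.random(n_units) < scenario.L
    weights = units["weight"].to_numpy(dtype=float)
    sizes = units["n_patients"].to_numpy(dtype=int)

    with_total = without_total = 0.0
    pairs_with, pairs_without = [], []
    if scenario.outcome == "binary":
        rates = scenario.unit_rates()
        for i in range(n_units):
            n = sizes[i]
            if n <= 0:
                continue
            r_wo = rates[i]
            r_w = effective_rate(r_wo, scenario.odds_ratio) if adopted[i] else r_wo
            out_wo = rng_without.random(n) < r_wo
            out_w = rng_with.random(n) < r_w
            without_total += weights[i] * out_wo.sum()
            with_total += weights[i] * out_w.sum()
            if collect_pairs:
                pairs_without.append(out_wo)
                pairs_with.append(out_w)
    else:
        means = scenario.unit_means()
        for i in range(n_units):
            n = sizes[i]
            if n <= 0:
                continue  # zero-patient unit skipped
            m_wo = means[i]
            m_w = m_wo * (1 - scenario.reduction_fraction) if adopted[i] else m_wo
            out_wo = rng_without.poisson(m_wo, n)
            out_w = rng_with.poisson(m_w, n)
            without_total += weights[i] * out_wo.sum()
            with_total += weights[i] * out_w.sum()
            if collect_pairs:
                pairs_without.append(out_wo)
                pairs_with.append(out_w)
    pw = np.concatenate(pairs_with) if pairs_with else np.empty(0)
    pwo = np.concatenate(pairs_without) if pairs_without else np.empty(0)
    return with_total, without_total, int(adopted.sum()), pw, pwo


def paired_outcome_test(with_arm: np.ndarray, without_arm: np.ndarray,
                        kind: str = "mcnemar"):
    """Paired comparison of per-patient outcomes.

    ``mcnemar``: continuity-corrected chi-square on the discordant cells of
    the paired 2x2 table (cross-checked against statsmodels); zero discordant
    pairs returns p = 1 with a flag.  ``paired_count``: paired t test on
    per-patient counts.
    Returns (statistic, p_value, flag).
    """
    w = np.asarray(with_arm)
    wo = np.asarray(without_arm)
    if w.shape != wo.shape:
        raise ValueError("arms must share patient indexing")
    if kind == "mcnemar":
        w, wo = w.astype(bool), wo.astype(bool)
        b = int(np.sum(w & ~wo))
        c = int(np.sum(~w & wo))
        if b + c == 0:
            return 0.0, 1.0, "no discordant pairs"
        table = [[int(np.sum(w & wo)), b], [c, int(np.sum(~w & ~wo))]]
        res = _sm_mcnemar(table, exact=False, correction=True)
        return float(res.statistic), float(res.pvalue), None
    if kind == "paired_count":
        diff = w.astype(float) - wo.astype(float)
        if np.allclose(diff, 0):
            return 0.0, 1.0, "identical arms"
        res = stats.ttest_rel(w.astype(float), wo.astype(float))
        return float(res.statistic), float(res.pvalue), None
    raise ValueError(f"unknown test kind {kind!r}")


def simulate_scenario(scenario: ImpactScenario, seed: int | None = None) -> ImpactResults:
    """Run the scenario ``n_runs`` times and average the arms across runs.

    The paired hypothesis test uses the first run's patient-level outcomes
    (unweighted pairs; the weights enter the national totals only).
    """
    seed = scenario.seed if seed is None else seed
    rows, first_pairs = [], None
    for run in range(scenario.n_runs):
        wt, wot, n_adopt, pw, pwo = _simulate_run(scenario, run, seed, collect_pairs=(run == 0))
        if run == 0:
            first_pairs = (pw, pwo)
        rows.append({"run": run, "with_total": wt, "without_total": wot,
                     "adopted_units": n_adopt})
    per_run = pd.DataFrame(rows)
    kind = "mcnemar" if scenario.outcome == "binary" else "paired_count"
    stat, p, flag = paired_outcome_test(first_pairs[0], first_pairs[1], kind)
    return ImpactResults(scenario, per_run, stat, p, flag)


def simulate_count_scenario(scenario: ImpactScenario, seed: int | None = None) -> ImpactResults:
    """Count-outcome variant (per-patient Poisson hospitalization days)."""
    if scenario.outcome != "count":
        raise ValueError("scenario.outcome must be 'count'")
    return simulate_scenario(scenario, seed)


def sensitivity_grid(scenario: ImpactScenario, n_levels: int = 5,
                     n_runs: int | None = None) -> pd.DataFrame:
    """Expected outcome difference (without - with) over a (p1, p2) level
    grid, with common random numbers across cells (shared seed)."""
    import dataclasses
    p1_levels = np.asarray(scenario.p1_levels if scenario.p1_levels is not None
                           else probability_levels(0.0, scenario.p1, n_levels))
    p2_levels = np.asarray(scenario.p2_levels if scenario.p2_levels is not None
                           else probability_levels(0.0, scenario.p2, n_levels))
    grid = np.empty((len(p1_levels), len(p2_levels)))
    for i, p1 in enumerate(p1_levels):
        for j, p2 in enumerate(p2_levels):
            cell = dataclasses.replace(scenario, p1=float(p1), p2=float(p2),
                                       n_runs=n_runs or scenario.n_runs)
            res = simulate_scenario(cell, seed=scenario.seed)
            grid[i, j] = res.difference
    return pd.DataFrame(grid,
                        index=pd.Index(np.round(p1_levels, 6), name="p1"),
                        columns=pd.Index(np.round(p2_levels, 6), name="p2"))


class ImpactSimulation:
    """Model-style front end: ``ImpactSimulation(scenario).run()``."""

    def __init__(self, scenario: ImpactScenario):
        self.scenario = scenario

    def run(self, seed: int | None = None, sensitivity: bool = False,
            sensitivity_runs: int | None = None) -> ImpactResults:
        res = simulate_scenario(self.scenario, seed)
        if sensitivity:
            res.sensitivity = sensitivity_grid(self.scenario,
                                               n_runs=sensitivity_runs)
        return res
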