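"""Seeded synthetic-data generators with planted ground truth.

These emulate the input shapes of the rest of the package — wide tabular
prediction problems, long-format longitudinal records with a per-patient
index date, and a survey-weighted unit table for the impact simulator — with
known signal structure so recovery tests can assert against the truth.
Effect sizes are parameterized in AUC units: an internal calibration search
finds the logit scale whose latent AUC matches the target, so tests can state
target AUCs directly.  All generators are pure functions of their arguments
(seed included).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd

from .temporal import LongitudinalTable

__all__ = ["make_tabular", "make_longitudinal", "make_unit_table",
           "calibrate_logit_scale"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@lru_cache(maxsize=64)
def calibrate_logit_scale(target_auc: float, _n: int = 200_000) -> float:
    """Logit scale gamma such that for z ~ N(0,1), y ~ Bern(sigmoid(gamma z)),
    the AUC of z for y is approximately ``target_auc``.  Bisection on a large
    internally-seeded Monte-Carlo estimate."""
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target_auc must lie in (0.5, 1)")
    rng = np.random.default_rng(123456789)
    z = rng.standard_normal(_n)
    u = rng.random(_n)

    def auc_at(gamma: float) -> float:
        y = u < _sigmoid(gamma * z)
        pos, neg = z[y], z[~y]
        if len(pos) == 0 or len(neg) == 0:
            return 1.0
        order = np.argsort(np.concatenate([pos, neg]), kind="stable")
        ranks = np.empty(len(order))
        ranks[order] = np.arange(1, len(order) + 1)
        r_pos = ranks[: len(pos)].sum()
        return (r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))

    lo, hi = 1e-3, 50.0
    for _ in range(40):
        mid = math.sqrt(lo * hi)
        if auc_at(mid) < target_auc:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


# ---------------------------------------------------------------------------
# tabular
# ---------------------------------------------------------------------------

def make_tabular(n: int = 1000, p: int = 20, n_informative: int = 5,
                 task: str = "classification", signal: str = "linear",
                 target_auc: float = 0.85, noise_sd: float = 1.0,
                 class_balance: float = 0.5, missing_fraction: float = 0.0,
                 seed: int = 0):
    """Gaussian-feature dataset with a planted signal.

    ``signal='linear'`` plants a linear logit (classification) or linear mean
    (regression) on the informative subset; ``signal='xor'`` plants the XOR
    of the signs of the first two informative features (invisible to
    univariate screens).  ``target_auc=1.0`` with classification gives a
    noiseless threshold rule (achievable error ~0).  Returns
    ``(DataFrame with outcome column 'y', info)`` where ``info`` lists the
    informative feature names and the coefficients.
    """
    if n_informative > p:
        raise ValueError("n_informative cannot exceed p")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    names = [f"x{i:03d}" for i in range(p)]
    beta = np.zeros(p)
    if n_informative:
        b = rng.uniform(0.5, 1.5, n_informative)
        beta[:n_informative] = b / np.linalg.norm(b)
    if signal == "linear":
        margin = X @ beta
    elif signal == "xor":
        margin = np.sign(X[:, 0]) * np.sign(X[:, 1] if n_informative > 1 else 1.0)
    else:
        raise ValueError(f"unknown signal {signal!r}")
    if n_informative == 0:
        margin = np.zeros(n)

    if task == "classification":
        if n_informative == 0:
            y = (rng.random(n) < class_balance).astype(int)
        elif target_auc >= 1.0:
            thresh = np.quantile(margin, 1 - class_balance)
            y = (margin > thresh).astype(int)
        else:
            gamma = calibrate_logit_scale(target_auc)
            ms = (margin - margin.mean()) / (margin.std() or 1.0)
            offset = math.log(class_balance / (1 - class_balance))
            y = (rng.random(n) < _sigmoid(gamma * ms + offset)).astype(int)
    elif task == "regression":
        y = margin + noise_sd * rng.standard_normal(n)
    else:
        raise ValueError(f"unknown task {task!r}")

    df = pd.DataFrame(X, columns=names)
    if missing_fraction > 0:
        mask = rng.random((n, p)) < missing_fraction
        df = df.mask(mask)
    df["y"] = y
    info = {"informative": names[:n_informative], "beta": beta[:n_informative].tolist(),
            "signal": signal, "task": task}
    return df, info


# ---------------------------------------------------------------------------
# longitudinal
# ---------------------------------------------------------------------------

def make_longitudinal(n_patients: int = 300, n_distractors: int = 3,
                      planted_period: int = 180, target_auc: float = 0.85,
                      visits_mean: float = 16.0, span_days: float = 730.0,
                      slope_sd: float = 0.05, base_sd: float = 8.0,
                      measurement_sd: float = 0.5, seed: int = 0):
    """Longitudinal family with a planted (slope, period) signal.

    Each patient has irregular visits over ``span_days`` ending at the index
    date.  One attribute ('weight') is flat before the planted lookback
    window and ramps linearly inside it with a patient-specific slope; the
    outcome logit depends only on that slope (calibrated to ``target_auc``).
    Patient mean level is independent of the outcome, so a (mean, 365)
    aggregation carries little signal by construction.  Distractor attributes
    are pure noise.  Returns ``(LongitudinalTable, y, truth)`` with
    ``truth = {'attribute': 'weight', 'operator': 'slope',
    'period_days': planted_period}``.
    """
    rng = np.random.default_rng(seed)
    index_day = span_days
    rows = []
    slopes = rng.normal(0.0, slope_sd, n_patients)
    bases = rng.normal(70.0, base_sd, n_patients)
    for i in range(n_patients):
        pid = f"p{i:04d}"
        n_visits = max(3, rng.poisson(visits_mean))
        times = np.sort(rng.uniform(0.0, index_day, n_visits))
        ramp = np.maximum(0.0, times - (index_day - planted_period))
        values = bases[i] + slopes[i] * ramp + rng.normal(0, measurement_sd, n_visits)
        for t, v in zip(times, values):
            rows.append((pid, "weight", float(t), float(v)))
        for d in range(n_distractors):
            nd = max(2, rng.poisson(visits_mean / 2))
            td = np.sort(rng.uniform(0.0, index_day, nd))
            vd = rng.normal(100.0 + 10 * d, 5.0, nd)
            for t, v in zip(td, vd):
                rows.append((pid, f"distractor{d}", float(t), float(v)))
    records = pd.DataFrame(rows, columns=["person_id", "attribute_id", "timestamp", "value"])
    index_dates = pd.Series(index_day, index=[f"p{i:04d}" for i in range(n_patients)])

    gamma = calibrate_logit_scale(target_auc)
    z = (slopes - slopes.mean()) / (slopes.std() or 1.0)
    y = (rng.random(n_patients) < _sigmoid(gamma * z)).astype(int)
    table = LongitudinalTable(records, index_dates)
    truth = {"attribute": "weight", "operator": "slope", "period_days": planted_period}
    return table, pd.Series(y, name="y"), truth


# ---------------------------------------------------------------------------
# unit table
# ---------------------------------------------------------------------------

def make_unit_table(n_units: int = 200, patients_mean: float = 500.0,
                    sampling_fraction: float = 0.2,
                    national_patient_count: float | None = None,
                    national_rate: float = 0.05, rate_sd_logit: float = 0.2,
                    national_mean_days: float = 10.0, days_sd_log: float = 0.2,
                    seed: int = 0) -> pd.DataFrame:
    """Survey-weighted unit table emulating a ~``sampling_fraction`` national
    sample: unit sizes log-normal, weight = inverse sampling fraction,
    per-unit baseline rates and Poisson day-means dispersed around national
    values.  When ``national_patient_count`` is given, sizes are rescaled so
    weighted size totals match it (up to integer rounding)."""
    rng = np.random.default_rng(seed)
    sizes = rng.lognormal(mean=0.0, sigma=0.6, size=n_units)
    sizes *= patients_mean / sizes.mean()
    weight = 1.0 / sampling_fraction
    if national_patient_count is not None:
        sizes *= national_patient_count * sampling_fraction / sizes.sum()
    n_patients = np.maximum(1, np.round(sizes)).astype(int)
    logit = math.log(national_rate / (1 - national_rate))
    rates = _sigmoid(logit + rng.normal(0, rate_sd_logit, n_units))
    means = national_mean_days * np.exp(rng.normal(0, days_sd_log, n_units)
                                        - days_sd_log ** 2 / 2)
    return pd.DataFrame({
        "unit_id": [f"u{i:04d}" for i in range(n_units)],
        "n_patients": n_patients,
        "weight": np.full(n_units, weight),
        "rate": rates,
        "days_mean": means,
    })
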