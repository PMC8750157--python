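"""Clinical risk calculators, tertile-style risk groups, and Kaplan-Meier
stratification.

A risk calculator is a published linear-logistic score: Y = intercept +
sum(coef_i * x_i) and risk p = 1/(1 + exp(-Y)).  Three calculators for 2-year
endpoints ship as module constants: locoregional recurrence (LRFFS), distant
metastasis (DMFS) and death (OS).  The calculators are applied to whatever
predictor scale they are given — the affine map is printed as-is and the
pipeline records which scaling produced the inputs (see docs/methods.md).

Patients are grouped by predicted risk at fixed probability cut points:
low < 0.33, medium in [0.33, 0.66), high >= 0.66 (cohort-tertile grouping is
available as an option).  Group separation is assessed by Kaplan-Meier
curves and the log-rank test, and the high-vs-rest split is summarised as a
sensitivity/specificity pair for the event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RiskCalculator",
    "RiskGroups",
    "LRFFS_CALCULATOR",
    "DMFS_CALCULATOR",
    "OS_CALCULATOR",
    "CALCULATORS",
    "apply_calculator",
    "stratify",
    "km_estimator",
    "log_rank",
    "high_risk_sens_spec",
]


@dataclass(frozen=True)
class RiskCalculator:
    """Intercept plus named coefficients of a linear-logistic risk score."""

    name: str
    intercept: float
    coefficients: dict  # ordered feature name -> coefficient

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in self.coefficients.values()):
            raise ValueError("coefficients must be finite")


# The three published 2-year risk calculators.  Predictor naming follows the
# analysis-table columns: PRE_*/delta_* imaging features plus binary
# clinical covariates (gender 1 = male, HPV 1 = positive, N_stage 1 = N2-3).
LRFFS_CALCULATOR = RiskCalculator(
    name="LRFFS",
    intercept=-2.173498,
    coefficients={
        "PRE_ADC_kurtosis": 0.317326,
        "PRE_kep": 0.168844,
        "PRE_SUV_peak": 1.469971,
        "delta_ADC_skewness": 0.010764,
        "delta_f": -0.036035,
        "delta_SUV_peak": -0.190617,
        "delta_TLG": -0.008579,
    },
)

DMFS_CALCULATOR = RiskCalculator(
    name="DMFS",
    intercept=-5.950312,
    coefficients={
        "PRE_ADC_kurtosis": 1.233603,
        "PRE_SUV_peak": 0.167255,
    },
)

OS_CALCULATOR = RiskCalculator(
    name="OS",
    intercept=-1.387043,
    coefficients={
        "gender": -0.685436,
        "HPV": -3.196345,
        "N_stage": 0.908168,
        "PRE_ADC_skewness": 0.925759,
        "PRE_D": -0.138775,
        "PRE_f": -0.277885,
        "PRE_MATV": 8.640004,
        "PRE_SUV_mean": -0.836001,
        "PRE_SUV_peak": 1.885920,
    },
)

CALCULATORS = {"LRFFS": LRFFS_CALCULATOR, "DMFS": DMFS_CALCULATOR, "OS": OS_CALCULATOR}


@dataclass
class RiskGroups:
    probability: pd.Series
    group: pd.Series  # "low" | "medium" | "high"
    cut_points: tuple


def apply_calculator(calculator: RiskCalculator, predictors) -> float | pd.Series:
    """Event probability 1/(1+exp(-Y)) with Y = intercept + sum(coef * x).

    ``predictors`` is a mapping or DataFrame holding every named predictor
    (missing names raise).  Scalar input gives a scalar probability.
    """
    if isinstance(predictors, pd.DataFrame):
        missing = set(calculator.coefficients) - set(predictors.columns)
        if missing:
            raise KeyError(f"missing predictors: {sorted(missing)}")
        y = pd.Series(calculator.intercept, index=predictors.index, dtype=float)
        for name, coef in calculator.coefficients.items():
            y = y + coef * predictors[name].astype(float)
        return 1.0 / (1.0 + np.exp(-y))
    missing = set(calculator.coefficients) - set(predictors)
    if missing:
        raise KeyError(f"missing predictors: {sorted(missing)}")
    y = calculator.intercept + sum(
        coef * float(predictors[name]) for name, coef in calculator.coefficients.items()
    )
    return float(1.0 / (1.0 + np.exp(-y)))


def stratify(probabilities, cut_points: tuple = (0.33, 0.66), mode: str = "fixed") -> RiskGroups:
    """Partition patients into low/medium/high risk groups.

    ``mode="fixed"`` uses probability cut points (low < 0.33 <= medium
    < 0.66 <= high: both intervals left-closed).  ``mode="tertile"`` cuts at
    the cohort's empirical 33rd/66th percentiles instead.
    """
    p = pd.Series(probabilities, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 patients to stratify")
    lo, hi = cut_points
    if mode == "tertile":
        lo, hi = np.quantile(p, [1 / 3, 2 / 3])
    elif mode != "fixed":
        raise ValueError(f"unknown mode {mode!r}")
    group = pd.Series(np.where(p < lo, "low", np.where(p < hi, "medium", "high")),
                      index=p.index)
    return RiskGroups(probability=p, group=group, cut_points=(float(lo), float(hi)))


def km_estimator(time, event, group=None) -> dict:
    """Product-limit survival estimate, optionally per group.

    Returns ``{group_label: DataFrame(time, survival)}`` with steps at event
    times (``None`` key for ungrouped input).
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if len(t) == 0:
        raise ValueError("no subjects")
    groups = pd.Series(["all"] * len(t)) if group is None else pd.Series(list(group))
    out = {}
    for g in groups.unique():
        sel = (groups == g).to_numpy()
        if sel.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        sf = kmf.survival_function_
        out[g] = pd.DataFrame({"time": sf.index.to_numpy(),
                               "survival": sf.iloc[:, 0].to_numpy()})
    return out


def survival_at(km: pd.DataFrame, t: float) -> float:
    """Step-function lookup of a KM curve at time t."""
    sel = km["time"] <= t
    return float(km.loc[sel, "survival"].iloc[-1]) if sel.any() else 1.0


def log_rank(time, event, group) -> tuple[float, float]:
    """Multigroup log-rank test; returns (chi-square, p) with df = groups-1."""
    from lifelines.statistics import multivariate_logrank_test

    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = pd.Series(list(group))
    if g.nunique() < 2:
        raise ValueError("need >= 2 groups")
    if e.sum() == 0:
        raise ValueError("no events")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def high_risk_sens_spec(groups, events) -> tuple[float, float]:
    """High-vs-rest risk grouping as a diagnostic test for the event.

    sensitivity = P(high | event), specificity = P(not high | no event).
    """
    g = np.asarray([x == "high" for x in groups])
    e = np.asarray(events, dtype=int).astype(bool)
    if e.sum() == 0 or (~e).sum() == 0:
        raise ValueError("need at least one event and one non-event")
    sensitivity = float((g & e).sum() / e.sum())
    specificity = float((~g & ~e).sum() / (~e).sum())
    return sensitivity, specificity
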