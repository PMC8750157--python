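"""Per-patient analysis table assembly and univariate prognostic statistics.

Fifteen imaging features are carried per timepoint — four ADC-map features
(GTV volume, median, skewness, Pearson kurtosis), three IVIM parameters
(D, D*, f), four DCE pharmacokinetic features (GTV volume, Ktrans, ve, kep)
and four PET features (MATV, SUVmean, SUVpeak, TLG).  Continuous map features
enter as the mean over two observers of each observer's ROI median; delta
features are the fractional intratreatment change (intra - pre)/pre.  Seven
clinical covariates (age, gender, tobacco, HPV, site, T-stage, N-stage) and
the three censored endpoints (locoregional recurrence-free, distant
metastasis-free and overall survival) complete the record.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IMAGING_FEATURES",
    "CLINICAL_FEATURES",
    "OUTCOMES",
    "observer_average",
    "delta_feature",
    "interobserver_correlation",
    "mann_whitney",
    "univariate_cox",
    "assemble_feature_table",
    "two_year_binary",
    "feature_columns",
]

IMAGING_FEATURES = (
    "ADC_GTV", "ADC_median", "ADC_skewness", "ADC_kurtosis",
    "D", "D_star", "f",
    "DCE_GTV", "Ktrans", "ve", "kep",
    "MATV", "SUV_mean", "SUV_peak", "TLG",
)
CLINICAL_FEATURES = ("age", "gender", "tobacco", "HPV", "site", "T_stage", "N_stage")
OUTCOMES = ("LRFFS", "DMFS", "OS")


def observer_average(value_obs1: float | None, value_obs2: float | None) -> tuple[float, bool]:
    """Patient-level feature: mean of the two observers' per-ROI values.

    Returns ``(value, single_observer)``; when one observer is missing the
    other's value is used and the fallback flag is set.
    """
    v1 = None if value_obs1 is None or (isinstance(value_obs1, float) and np.isnan(value_obs1)) else value_obs1
    v2 = None if value_obs2 is None or (isinstance(value_obs2, float) and np.isnan(value_obs2)) else value_obs2
    if v1 is None and v2 is None:
        raise ValueError("both observers missing")
    if v1 is None:
        return float(v2), True
    if v2 is None:
        return float(v1), True
    return (float(v1) + float(v2)) / 2.0, False


def delta_feature(pre: float, intra: float) -> float:
    """Fractional intratreatment change (intra - pre)/pre; NaN when pre == 0."""
    if pre == 0 or not np.isfinite(pre) or not np.isfinite(intra):
        return float("nan")
    return (intra - pre) / pre


def interobserver_correlation(values_obs1, values_obs2) -> tuple[float, float]:
    """Pearson r (and p) between the two observers' per-patient values."""
    a = np.asarray(values_obs1, dtype=float)
    b = np.asarray(values_obs2, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired values for >= 3 patients")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one observer's values")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (of group A) with two-sided p.

    Exact null distribution when both groups have n <= 8 and no ties;
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    method = "exact" if (a.size <= 8 and b.size <= 8
                         and len(np.unique(np.concatenate([a, b]))) == a.size + b.size) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _cox_loglik(beta: float, x: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    """Breslow log partial likelihood of a single covariate."""
    ll = 0.0
    for i in np.where(e == 1)[0]:
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def _monotone_likelihood(df: pd.DataFrame, beta: float) -> bool:
    """Detect quasi-separation: the partial likelihood keeps rising past beta."""
    x = df["x"].to_numpy()
    t = df["time"].to_numpy()
    e = df["event"].to_numpy()
    step = 2.0 * (1 if beta >= 0 else -1)
    with np.errstate(over="ignore"):
        return _cox_loglik(beta + step, x, t, e) > _cox_loglik(beta, x, t, e) + 1e-8


def univariate_cox(feature, time, event) -> dict:
    """Single-covariate Cox proportional-hazards fit (Efron ties, Wald p).

    Returns ``{"coef", "hr", "p", "separation"}``; monotone likelihood
    (quasi-perfect ordering of events by the feature) sets the separation
    flag rather than raising.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = pd.DataFrame({"x": np.asarray(feature, dtype=float),
                       "time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int)})
    if df["event"].sum() < 1:
        raise ValueError("need at least one event")
    cph = CoxPHFitter(penalizer=0.0)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError:
            # monotone partial likelihood: refit with a tiny ridge and flag
            separation = True
            cph = CoxPHFitter(penalizer=1e-6)
            cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["x"])
    if abs(beta) > 10 or _monotone_likelihood(df, beta):
        separation = True
    return {
        "coef": beta,
        "hr": float(np.exp(beta)),
        "p": float(cph.summary.loc["x", "p"]),
        "separation": separation,
    }


def feature_columns(feature_names=IMAGING_FEATURES) -> list[str]:
    """The 45 imaging columns: PRE_*, INTRA_* and delta_* per feature."""
    cols = []
    for prefix in ("PRE", "INTRA", "delta"):
        cols += [f"{prefix}_{n}" for n in feature_names]
    return cols


def assemble_feature_table(per_patient: dict, clinical: pd.DataFrame | None = None,
                           feature_names=IMAGING_FEATURES) -> pd.DataFrame:
    """Build the cohort analysis table from per-patient feature dicts.

    ``per_patient`` maps patient_id to
    ``{"PRE": {feature: value}, "INTRA": {feature: value}}`` (values already
    observer-averaged).  Produces 15 features x {PRE, INTRA, delta} = 45
    imaging columns, joined with the clinical table when given.
    """
    rows = {}
    for pid, tps in per_patient.items():
        row = {}
        for tp in ("PRE", "INTRA"):
            vals = tps.get(tp, {})
            for name in feature_names:
                row[f"{tp}_{name}"] = vals.get(name, np.nan)
        for name in feature_names:
            row[f"delta_{name}"] = delta_feature(row[f"PRE_{name}"], row[f"INTRA_{name}"])
        rows[pid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")[feature_columns(feature_names)]
    df.index.name = "patient_id"
    if clinical is not None:
        df = df.join(clinical, how="left")
    return df


def two_year_binary(time, event, horizon_years: float = 2.0) -> np.ndarray:
    """Dichotomise censored outcomes at a horizon for logistic modelling.

    1 = event by the horizon; 0 = event-free with follow-up past the
    horizon; NaN = censored before the horizon without an event (these
    patients are excluded from logistic fits).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    out = np.full(t.shape, np.nan)
    out[t >= horizon_years] = 0.0          # followed past the horizon event-free
    out[(e == 1) & (t <= horizon_years)] = 1.0
    return out
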