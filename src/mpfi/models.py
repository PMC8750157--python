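"""LASSO prognostic models with repeated cross-validation.

Two model families are built over a patient-by-feature table:

* L1-penalised logistic regression for 2-year dichotomised endpoints,
  scored by the cross-validated area under the ROC curve (AUC);
* L1-penalised Cox regression for censored endpoints, scored by the
  cross-validated Harrell concordance index.

Validation is repeated stratified 5-fold cross-validation (500 repeats by
default; tests and small runs scale this down).  Within every training fold
features are standardised to zero mean and unit variance and the penalty
strength is chosen by an inner 5-fold CV, so the held-out fold never touches
either the scaling or the lambda choice.  Held-out predictions are pooled
per repeat; the reported metric is the mean over repeats with its SD across
repeats.  Final coefficients come from a refit on the full data at the
inner-CV-chosen penalty.

The AUC and concordance primitives are implemented here by their
rank/pair-counting definitions (ties count one half) so they can be verified
against exhaustive pair enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ModelConfig",
    "CVResult",
    "auc",
    "harrell_c",
    "lasso_logistic_cv",
    "lasso_cox_cv",
    "run_model_grid",
    "FEATURE_SETS",
]

FEATURE_SETS = ("PRE", "INTRA", "DELTA", "ALL")


@dataclass
class ModelConfig:
    outcome: str = "LRFFS"
    feature_set: str = "ALL"
    include_clinical: bool = False
    folds: int = 5
    repeats: int = 500
    inner_folds: int = 5
    seed: int = 0
    lambda_rule: str = "min"  # "min" | "1se"
    c_grid: tuple = tuple(np.logspace(-2, 2, 13))
    n_alphas: int = 30

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")


@dataclass
class CVResult:
    metric: str  # "AUC" | "C-index"
    mean: float
    sd: float
    per_repeat: np.ndarray
    selection_frequency: pd.Series
    coefficients: pd.Series
    intercept: float | None = None
    n_patients: int = 0
    n_events: int = 0
    notes: list = field(default_factory=list)


def auc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formulation.

    Equals the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(s)  # average ranks handle ties exactly
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def harrell_c(linear_predictor, time, event) -> float:
    """Harrell's concordance index over usable pairs.

    A pair is usable when the shorter observed time carries an event; it is
    concordant when the higher-risk prediction belongs to that earlier
    event, ties in the predictor counting one half.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    # pair (i, j) usable iff t_i < t_j and e_i == 1 (and symmetric case)
    ti, tj = t[:, None], t[None, :]
    usable = (ti < tj) & (e[:, None] == 1)
    if not usable.any():
        raise ValueError("no comparable pairs")
    li, lj = lp[:, None], lp[None, :]
    concordant = (usable & (li > lj)).sum()
    tied = (usable & (li == lj)).sum()
    return float((concordant + 0.5 * tied) / usable.sum())


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _choose_c(X: np.ndarray, y: np.ndarray, config: ModelConfig, rng_seed: int) -> float:
    """Inner-CV choice of the inverse penalty C for L1 logistic regression."""
    grid = np.asarray(config.c_grid, dtype=float)
    inner = StratifiedKFold(n_splits=min(config.inner_folds, int(y.sum()), int((1 - y).sum()), 5),
                            shuffle=True, random_state=rng_seed)
    if inner.n_splits < 2:
        return 1.0
    losses = np.zeros((inner.n_splits, grid.size))
    for k, (tr, te) in enumerate(inner.split(X, y)):
        Xtr, Xte = _standardize(X[tr], X[te])
        for g, c in enumerate(grid):
            clf = LogisticRegression(C=c, l1_ratio=1.0, solver="liblinear", max_iter=2000,
                                     random_state=0)
            clf.fit(Xtr, y[tr])
            p = np.clip(clf.predict_proba(Xte)[:, 1], 1e-12, 1 - 1e-12)
            losses[k, g] = -np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
    mean_loss = losses.mean(axis=0)
    best = int(np.argmin(mean_loss))
    if config.lambda_rule == "1se":
        se = losses.std(axis=0, ddof=1) / np.sqrt(inner.n_splits)
        # strongest penalty (smallest C) within one SE of the minimum
        ok = np.where(mean_loss <= mean_loss[best] + se[best])[0]
        best = int(ok[np.argmin(grid[ok])])
    return float(grid[best])


def lasso_logistic_cv(features: pd.DataFrame, outcome, config: ModelConfig) -> CVResult:
    """Repeated nested-CV LASSO logistic regression scored by pooled AUC.

    ``outcome`` is a binary 0/1 vector aligned to ``features``; rows with a
    missing outcome are dropped.  Deterministic under ``config.seed``.
    """
    y_all = np.asarray(outcome, dtype=float)
    keep = np.isfinite(y_all) & np.isfinite(features.to_numpy(dtype=float)).all(axis=1)
    X = features.loc[keep].to_numpy(dtype=float)
    y = y_all[keep].astype(int)
    names = list(features.columns)
    n_events = int(y.sum())
    if n_events < 5 or (len(y) - n_events) < 5:
        raise ValueError("need >= 5 events and >= 5 non-events")

    per_repeat = np.zeros(config.repeats)
    selected = np.zeros(len(names))
    n_fits = 0
    notes: list = []
    for r in range(config.repeats):
        fold_seed = config.seed * 100003 + r
        probs = np.zeros(len(y))
        for attempt in range(5):
            skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                                  random_state=(fold_seed + attempt * 7919) % (2**31))
            try:
                for tr, te in skf.split(X, y):
                    if len(np.unique(y[tr])) < 2:
                        raise RuntimeError("single-class fold")
                    Xtr, Xte = _standardize(X[tr], X[te])
                    c = _choose_c(X[tr], y[tr], config, (fold_seed + 13) % (2**31))
                    clf = LogisticRegression(C=c, l1_ratio=1.0, solver="liblinear", max_iter=2000,
                                     random_state=0)
                    clf.fit(Xtr, y[tr])
                    probs[te] = clf.predict_proba(Xte)[:, 1]
                    selected += (clf.coef_[0] != 0).astype(float)
                    n_fits += 1
                break
            except RuntimeError:
                notes.append(f"repeat {r}: single-class fold, re-randomised")
                continue
        per_repeat[r] = auc(probs, y)

    # final refit on all data at the inner-CV-chosen penalty
    Xs, _ = _standardize(X, X)
    c_final = _choose_c(X, y, config, config.seed % (2**31))
    final = LogisticRegression(C=c_final, l1_ratio=1.0, solver="liblinear", max_iter=2000,
                               random_state=0)
    final.fit(Xs, y)
    return CVResult(
        metric="AUC",
        mean=float(per_repeat.mean()),
        sd=float(per_repeat.std(ddof=1)) if config.repeats > 1 else 0.0,
        per_repeat=per_repeat,
        selection_frequency=pd.Series(selected / max(n_fits, 1), index=names),
        coefficients=pd.Series(final.coef_[0], index=names),
        intercept=float(final.intercept_[0]),
        n_patients=len(y),
        n_events=n_events,
        notes=notes,
    )


def _coxnet_alphas(X: np.ndarray, y_struct, n_alphas: int):
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    m = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m.fit(X, y_struct)
    return np.asarray(m.alphas_)


def _choose_alpha_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                      config: ModelConfig, rng_seed: int) -> float:
    """Inner-CV alpha choice for LASSO Cox, scored by held-out concordance."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    Xs, _ = _standardize(X, X)
    y_struct = Surv.from_arrays(event.astype(bool), time)
    alphas = _coxnet_alphas(Xs, y_struct, config.n_alphas)
    inner = StratifiedKFold(n_splits=min(config.inner_folds, int(event.sum())),
                            shuffle=True, random_state=rng_seed)
    if inner.n_splits < 2:
        return float(alphas[len(alphas) // 2])
    scores = np.full((inner.n_splits, len(alphas)), np.nan)
    for k, (tr, te) in enumerate(inner.split(X, event)):
        if event[te].sum() == 0 or event[tr].sum() == 0:
            continue
        Xtr, Xte = _standardize(X[tr], X[te])
        ytr = Surv.from_arrays(event[tr].astype(bool), time[tr])
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas), fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                m.fit(Xtr, ytr)
            except Exception:
                continue
        for g, a in enumerate(np.asarray(m.alphas_)):
            lp = m.predict(Xte, alpha=a)
            try:
                scores[k, g] = harrell_c(lp, time[te], event[te])
            except ValueError:
                scores[k, g] = 0.5
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean_c = np.nanmean(scores, axis=0)
    if np.all(np.isnan(mean_c)):
        return float(alphas[len(alphas) // 2])
    return float(alphas[int(np.nanargmax(mean_c))])


def lasso_cox_cv(features: pd.DataFrame, time, event, config: ModelConfig) -> CVResult:
    """Repeated nested-CV LASSO Cox regression scored by pooled Harrell's C."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    t_all = np.asarray(time, dtype=float)
    e_all = np.asarray(event, dtype=int)
    keep = np.isfinite(t_all) & np.isfinite(features.to_numpy(dtype=float)).all(axis=1)
    X = features.loc[keep].to_numpy(dtype=float)
    t = t_all[keep]
    e = e_all[keep]
    names = list(features.columns)
    if e.sum() < 5:
        raise ValueError("need >= 5 events")

    per_repeat = np.zeros(config.repeats)
    selected = np.zeros(len(names))
    n_fits = 0
    notes: list = []
    for r in range(config.repeats):
        fold_seed = config.seed * 100003 + r
        lp_pooled = np.zeros(len(t))
        for attempt in range(5):
            skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                                  random_state=(fold_seed + attempt * 7919) % (2**31))
            try:
                for tr, te in skf.split(X, e):
                    if e[tr].sum() == 0:
                        raise RuntimeError("event-free training fold")
                    Xtr, Xte = _standardize(X[tr], X[te])
                    a = _choose_alpha_cox(X[tr], t[tr], e[tr], config, (fold_seed + 13) % (2**31))
                    m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[a], fit_baseline_model=False)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        m.fit(Xtr, Surv.from_arrays(e[tr].astype(bool), t[tr]))
                    lp_pooled[te] = m.predict(Xte)
                    selected += (np.ravel(m.coef_) != 0).astype(float)
                    n_fits += 1
                break
            except RuntimeError:
                notes.append(f"repeat {r}: degenerate fold, re-randomised")
                continue
        per_repeat[r] = harrell_c(lp_pooled, t, e)

    Xs, _ = _standardize(X, X)
    a_final = _choose_alpha_cox(X, t, e, config, config.seed % (2**31))
    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[a_final], fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(Xs, Surv.from_arrays(e.astype(bool), t))
    return CVResult(
        metric="C-index",
        mean=float(per_repeat.mean()),
        sd=float(per_repeat.std(ddof=1)) if config.repeats > 1 else 0.0,
        per_repeat=per_repeat,
        selection_frequency=pd.Series(selected / max(n_fits, 1), index=names),
        coefficients=pd.Series(np.ravel(final.coef_), index=names),
        intercept=None,
        n_patients=len(t),
        n_events=int(e.sum()),
        notes=notes,
    )


def select_feature_columns(table: pd.DataFrame, feature_set: str,
                           include_clinical: bool,
                           clinical_names=None) -> list[str]:
    """Columns of the analysis table belonging to a feature-set cell."""
    from .features import CLINICAL_FEATURES

    prefix = {"PRE": ("PRE_",), "INTRA": ("INTRA_",), "DELTA": ("delta_",),
              "ALL": ("PRE_", "INTRA_", "delta_")}[feature_set]
    cols = [c for c in table.columns if c.startswith(prefix)]
    if include_clinical:
        clin = clinical_names or CLINICAL_FEATURES
        cols += [c for c in clin if c in table.columns]
    return cols


def run_model_grid(table: pd.DataFrame, outcomes: pd.DataFrame,
                   repeats: int = 500, folds: int = 5, seed: int = 0,
                   outcome_names=("LRFFS", "DMFS", "OS"),
                   horizon_years: float = 2.0,
                   metrics=("AUC", "C-index")) -> pd.DataFrame:
    """The full model-comparison grid: outcomes x feature sets x clinical modes.

    For each of the 3 outcomes, 4 feature sets and with/without clinical
    covariates (24 cells), fits the LASSO logistic model on the
    horizon-dichotomised endpoint (AUC) and/or the LASSO Cox model on the
    censored endpoint (Harrell's C).
    """
    from .features import two_year_binary

    rows = []
    for outcome in outcome_names:
        t = outcomes[f"{outcome}_time"]
        e = outcomes[f"{outcome}_event"]
        y_bin = two_year_binary(t, e, horizon_years)
        for feature_set in FEATURE_SETS:
            for include_clinical in (False, True):
                cfg = ModelConfig(outcome=outcome, feature_set=feature_set,
                                  include_clinical=include_clinical,
                                  folds=folds, repeats=repeats, seed=seed)
                cols = select_feature_columns(table, feature_set, include_clinical)
                row = {
                    "outcome": outcome, "feature_set": feature_set,
                    "clinical": include_clinical, "n_features": len(cols),
                }
                sub = table[cols]
                # cells a small cohort cannot support (too few events) are
                # reported as NaN rather than aborting the grid
                if "AUC" in metrics:
                    try:
                        res = lasso_logistic_cv(sub, pd.Series(y_bin, index=table.index), cfg)
                        row.update(auc_mean=res.mean, auc_sd=res.sd, n_logistic=res.n_patients)
                    except ValueError as exc:
                        row.update(auc_mean=np.nan, auc_sd=np.nan, note=str(exc))
                if "C-index" in metrics:
                    try:
                        res_c = lasso_cox_cv(sub, t, e, cfg)
                        row.update(c_mean=res_c.mean, c_sd=res_c.sd, n_cox=res_c.n_patients)
                    except ValueError as exc:
                        row.update(c_mean=np.nan, c_sd=np.nan, note=str(exc))
                rows.append(row)
    return pd.DataFrame(rows)
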