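"""Risk-stratification pipeline: LASSO selection, multivariate Cox-PH,
significant-coefficient risk score, median split, Kaplan–Meier and log-rank.

The selection stage is an L1-penalized *linear* regression of the observed
survival time on the predictors (censoring enters only at the Cox/KM
stages); the regularization strength is chosen by cross-validated grid
search.  Cox models use the Breslow tie convention.  A sample's risk score
is sum(X_i * Coef_i) over the Cox predictors with Wald p < 0.05, and the
cohort is split at the median score (score <= median -> low risk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.linear_model import Lasso
from sklearn.model_selection import GridSearchCV
from statsmodels.duration.hazard_regression import PHReg

from .io import OmicsValidationError, SurvivalTable, logger

DEFAULT_ALPHA_GRID = (0.001, 0.002, 0.005, 0.01, 0.05, 1.0)


@dataclass
class CoxModel:
    """Fitted Cox proportional hazards coefficients."""

    predictors: list[str]
    coef: np.ndarray               # log hazard ratios
    p_values: np.ndarray           # Wald p per predictor

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if not (len(self.predictors) == len(self.coef) == len(self.p_values)):
            raise OmicsValidationError("Cox model fields must align")

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)


@dataclass
class RiskScores:
    sample_ids: list[str]
    score: np.ndarray
    group: list[str]               # "low" | "high"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.score, "group": self.group},
                            index=self.sample_ids)


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray              # distinct event times, ascending
    survival: np.ndarray           # S(t) just after each event time
    at_risk: np.ndarray            # risk-set size just before each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _as_frame(features, sample_ids=None) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    values = np.asarray(features, dtype=float)
    idx = sample_ids if sample_ids is not None else range(values.shape[0])
    return pd.DataFrame(values, index=idx,
                        columns=[f"x{j}" for j in range(values.shape[1])])


def lasso_select(features, survival: SurvivalTable,
                 alpha_grid=DEFAULT_ALPHA_GRID, cv: int = 5,
                 seed: int = 0) -> list[str]:
    """Predictors with nonzero LASSO coefficients at the CV-chosen alpha."""
    X = _as_frame(features, survival.sample_ids)
    if X.shape[0] < 10:
        raise OmicsValidationError("LASSO selection needs at least 10 samples")
    alphas = [float(a) for a in alpha_grid]
    if any(a <= 0 for a in alphas):
        raise OmicsValidationError("LASSO alpha values must be positive")
    search = GridSearchCV(Lasso(max_iter=5000), {"alpha": alphas},
                          cv=cv, scoring="neg_mean_squared_error")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X.to_numpy(), survival.time)
    best = search.best_estimator_
    keep = np.flatnonzero(best.coef_ != 0)
    logger.info("survival: LASSO (alpha=%g) kept %d/%d predictors",
                search.best_params_["alpha"], len(keep), X.shape[1])
    return [X.columns[j] for j in keep]


def fit_coxph(features, survival: SurvivalTable, maxiter: int = 100) -> CoxModel:
    """Multivariate Cox-PH (Breslow ties) with Wald p-values."""
    X = _as_frame(features, survival.sample_ids)
    if survival.event.sum() < 1:
        raise OmicsValidationError("Cox-PH requires at least one observed event")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise OmicsValidationError(f"constant predictors not allowed: {const[:5]}")
    xs = X.to_numpy()
    rank = np.linalg.matrix_rank(xs - xs.mean(axis=0))
    if rank < xs.shape[1]:
        raise OmicsValidationError(
            "predictor matrix is rank-deficient (duplicate or collinear columns) "
            "— singular information matrix")
    model = PHReg(survival.time, xs, status=survival.event, ties="breslow")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=maxiter)
    params = np.asarray(res.params, dtype=float)
    pvals = np.asarray(res.pvalues, dtype=float)
    if not np.isfinite(params).all():
        bad = [X.columns[j] for j in np.flatnonzero(~np.isfinite(params))]
        raise OmicsValidationError(
            f"Cox-PH failed to converge; offending predictor(s): {bad[:5]}")
    return CoxModel(list(X.columns), params, pvals)


def compute_risk_scores(model: CoxModel, features,
                        p_threshold: float = 0.05,
                        sample_ids=None) -> RiskScores:
    """Risk score = sum(X_i * Coef_i) over predictors with p < threshold;
    samples at or below the median score form the low-risk group."""
    X = _as_frame(features, sample_ids)
    keep = np.flatnonzero(model.p_values < p_threshold)
    if keep.size == 0:
        raise OmicsValidationError(
            f"no predictor reaches p < {p_threshold}; consider relaxing the threshold")
    cols = [model.predictors[j] for j in keep]
    score = X[cols].to_numpy() @ model.coef[keep]
    med = float(np.median(score))
    group = ["low" if s <= med else "high" for s in score]
    if all(g == "low" for g in group):
        logger.warning("survival: degenerate median split — all scores tie at "
                       "the median, every sample is low-risk")
    return RiskScores(list(X.index.astype(str)), score, group)


def km_estimate(survival: SurvivalTable) -> KMCurve:
    """Kaplan–Meier product-limit estimator S(t) = prod (1 - d_i/n_i)."""
    if len(survival.sample_ids) == 0:
        raise OmicsValidationError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(survival.time, event_observed=survival.event)
    event_times = np.unique(survival.time[survival.event == 1])
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0])
                     for t in event_times])
    order = np.sort(survival.time)
    at_risk = np.array([(order >= t).sum() for t in event_times], dtype=int)
    return KMCurve(event_times, surv, at_risk)


def _univariate_cox_hr(group_indicator: np.ndarray,
                       survival: SurvivalTable) -> float:
    model = PHReg(survival.time, group_indicator.reshape(-1, 1),
                  status=survival.event, ties="breslow")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    return float(np.exp(res.params[0]))


def logrank_test(group_a: SurvivalTable, group_b: SurvivalTable):
    """Two-group log-rank test; returns (chi_square, p_value, hazard_ratio).

    The hazard ratio (B vs A) comes from a univariate Cox fit on the group
    indicator.
    """
    if len(group_a.sample_ids) == 0 or len(group_b.sample_ids) == 0:
        raise OmicsValidationError("both groups must be non-empty")
    if group_a.event.sum() + group_b.event.sum() == 0:
        raise OmicsValidationError("log-rank test requires at least one event")
    res = _ll_logrank(group_a.time, group_b.time,
                      event_observed_A=group_a.event,
                      event_observed_B=group_b.event)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    indicator = np.r_[np.zeros(len(group_a.sample_ids)),
                      np.ones(len(group_b.sample_ids))]
    merged = SurvivalTable(
        [f"a_{s}" for s in group_a.sample_ids] + [f"b_{s}" for s in group_b.sample_ids],
        np.r_[group_a.time, group_b.time], np.r_[group_a.event, group_b.event])
    try:
        hr = _univariate_cox_hr(indicator, merged)
    except Exception:   # monotone likelihood on fully separated fixtures
        hr = float("nan")
    return chi2, p, hr


def _split_survival(survival: SurvivalTable, risk: RiskScores):
    df = survival.to_frame()
    low_ids = [s for s, g in zip(risk.sample_ids, risk.group) if g == "low"]
    high_ids = [s for s, g in zip(risk.sample_ids, risk.group) if g == "high"]
    mk = lambda ids: SurvivalTable(ids, df.loc[ids, "time"].to_numpy(),
                                   df.loc[ids, "event"].to_numpy())
    return mk(low_ids), mk(high_ids)


def risk_stratify(features, survival: SurvivalTable,
                  alpha_grid=DEFAULT_ALPHA_GRID, p_threshold: float = 0.05,
                  seed: int = 0) -> dict:
    """Full chain: LASSO -> Cox-PH -> risk score -> median split -> KM/log-rank.

    Returns a summary dict; if no predictor survives selection or the
    significance threshold, stratification is impossible and the summary
    reports p_value 1.0 with empty groups.
    """
    X = _as_frame(features, survival.sample_ids)
    if X.shape[1] == 0:
        raise OmicsValidationError("empty feature matrix")
    out = {"n_initial": X.shape[1], "n_lasso": 0, "n_significant": 0,
           "chi_square": 0.0, "p_value": 1.0, "hazard_ratio": float("nan"),
           "n_low": 0, "n_high": 0, "risk": None, "km_low": None, "km_high": None}
    try:
        selected = lasso_select(X, survival, alpha_grid, seed=seed)
        out["n_lasso"] = len(selected)
        if not selected:
            raise OmicsValidationError("LASSO selected no predictors")
        model = fit_coxph(X[selected], survival)
        out["n_significant"] = int((model.p_values < p_threshold).sum())
        risk = compute_risk_scores(model, X[selected], p_threshold)
    except OmicsValidationError as exc:
        logger.warning("survival: stratification not possible (%s); reporting "
                       "p=1.0", exc)
        return out
    low, high = _split_survival(survival, risk)
    out["risk"] = risk
    out["n_low"], out["n_high"] = len(low.sample_ids), len(high.sample_ids)
    if out["n_low"] and out["n_high"]:
        chi2, p, hr = logrank_test(low, high)
        out.update(chi_square=chi2, p_value=p, hazard_ratio=hr)
        out["km_low"], out["km_high"] = km_estimate(low), km_estimate(high)
    return out


def compare_feature_sets(raw, embeddings, survival: SurvivalTable,
                         alpha_grid=DEFAULT_ALPHA_GRID,
                         p_threshold: float = 0.05, seed: int = 0) -> dict:
    """Run the risk pipeline on raw features and embeddings independently."""
    raw_f = _as_frame(raw, survival.sample_ids)
    emb_f = _as_frame(embeddings, survival.sample_ids)
    if emb_f.shape[1] == 0 or raw_f.shape[1] == 0:
        raise OmicsValidationError("empty feature matrix")
    if list(raw_f.index) != list(emb_f.index):
        raise OmicsValidationError("raw and embedding matrices must share samples")
    return {"raw": risk_stratify(raw_f, survival, alpha_grid, p_threshold, seed),
            "embeddings": risk_stratify(emb_f, survival, alpha_grid, p_threshold, seed)}
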