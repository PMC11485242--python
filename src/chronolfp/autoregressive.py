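"""Linear and nonlinear autoregressive predictability of the 10-min stream.

The linear model is X_t = c + Σ_k φ_k X_{t−k} + ε_t with candidate lags up
to one full day (144 samples).  Lags are selected by a cross-validated
consensus: per contiguous fold, an OLS fit flags lags with coefficient
p < 0.05; lags flagged in at least four of five folds are refitted on the
whole series and iteratively pruned (all non-significant lags dropped each
round) until every remaining lag is significant.  Predictive accuracy is
reported as held-out R² from five contiguous folds within each clinical
state, aggregated to one R² per day.

The nonlinear variant replaces OLS with a small 144→32→1 ReLU network (see
:mod:`chronolfp._mlp`) that always uses the full previous day of lags; per
fold the best epoch by held-out R² is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import r2_score

from ._mlp import MLPRegressorNumpy
from .cosinor import contiguous_folds

MAX_LAG = 144  # one day of 10-min samples


def build_lag_matrix(series: np.ndarray, lags) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (targets, lagged design, target positions) from a 1-D series.

    ``series`` is the chronological z-scored stream with NaN for missing
    samples; lags cross day boundaries.  Rows are target positions where
    the target and every requested lag are non-missing.
    """
    x = np.asarray(series, dtype=float).reshape(-1)
    lags = np.asarray(sorted(set(int(k) for k in lags)), dtype=int)
    if len(lags) and (lags.min() < 1 or lags.max() > MAX_LAG):
        raise ValueError(f"lags must lie in 1..{MAX_LAG}")
    max_lag = int(lags.max()) if len(lags) else 1
    if len(x) < max_lag + 1:
        raise ValueError("series shorter than max lag + 1")
    pos = np.arange(max_lag, len(x))
    ok = np.isfinite(x[pos])
    for k in lags:
        ok &= np.isfinite(x[pos - k])
    pos = pos[ok]
    y = x[pos]
    X = np.column_stack([x[pos - k] for k in lags]) if len(lags) else \
        np.empty((len(pos), 0))
    return y, X, pos


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with intercept; returns (beta, pvalues, predictions_fn)."""
    D = np.column_stack([np.ones(len(y)), X])
    beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    dof = len(y) - D.shape[1]
    if dof <= 0:
        pvals = np.ones(D.shape[1])
    else:
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.pinv(D.T @ D)
        se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
        tstats = beta / se
        pvals = 2.0 * sps.t.sf(np.abs(tstats), dof)
    return beta, pvals


class LinearAR(BaseEstimator, RegressorMixin):
    """OLS autoregression on a fixed lag set (sklearn estimator surface).

    ``fit(X, y)`` consumes the lagged design from :func:`build_lag_matrix`.
    With ``hac=True`` the coefficient covariance is recomputed with a
    heteroskedasticity-and-autocorrelation-robust (HAC) estimator via
    statsmodels; point estimates and predictions are identical to the
    standard fit, only standard errors change.
    """

    def __init__(self, hac: bool = False, hac_maxlags: int = 6):
        self.hac = hac
        self.hac_maxlags = hac_maxlags

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        beta, pvals = _ols(X, y)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.pvalues_ = pvals
        if self.hac:
            import statsmodels.api as sm

            res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit(
                cov_type="HAC", cov_kwds={"maxlags": self.hac_maxlags})
            self.pvalues_hac_ = np.asarray(res.pvalues)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.coef_):
            raise ValueError("lag design width mismatch")
        return self.intercept_ + X @ self.coef_


@dataclass
class LagSelectionResult:
    lags: list[int]
    history: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"lags": self.lags, "history": self.history}


def select_significant_lags(series: np.ndarray, max_lag: int = MAX_LAG,
                            alpha: float = 0.05, n_folds: int = 5,
                            min_folds: int = 4) -> LagSelectionResult:
    """Cross-validated consensus lag selection with iterative full-data pruning.

    Runs on the patient's entire series (selection precedes per-state
    fitting).  May return an empty lag set.
    """
    y, X, _ = build_lag_matrix(series, range(1, max_lag + 1))
    if len(y) == 0:
        raise ValueError("no usable rows after lag alignment")
    if len(y) < 10 * max_lag:
        warnings.warn("fewer than 10 rows per candidate lag; selection may be unstable")
    candidates = np.arange(1, max_lag + 1)
    votes = np.zeros(max_lag, dtype=int)
    # each fold's OLS runs on that fold's own contiguous block: disjoint
    # blocks give (near-)independent per-fold p-values, which is what lets
    # the >=4-of-5 consensus suppress chance significances
    for fold in contiguous_folds(len(y), n_folds):
        _, pvals = _ols(X[fold], y[fold])
        votes += (pvals[1:] < alpha).astype(int)
    selected = candidates[votes >= min_folds].tolist()
    history = [{"stage": "fold_consensus", "lags": list(selected),
                "votes": votes[votes >= min_folds].tolist()}]
    # iterative pruning on the full dataset: drop all non-significant lags
    while selected:
        yf, Xf, _ = build_lag_matrix(series, selected)
        _, pvals = _ols(Xf, yf)
        keep = [k for k, p in zip(selected, pvals[1:]) if p < alpha]
        history.append({"stage": "full_refit", "lags": list(keep)})
        if keep == selected:
            break
        selected = keep
    return LagSelectionResult(lags=selected, history=history)


def _statewise_cv(series, day_of_sample, day_states, n_folds, min_day_points,
                  fit_predict):
    """Shared per-state contiguous-fold CV driver.

    ``fit_predict(train_idx, test_idx, rows)`` returns held-out predictions
    for ``test_idx`` within the state's row set.
    """
    state_map = dict(zip(day_states["day"], day_states["state"]))
    state_means: dict[str, float] = {}
    daily_rows = []
    for state in pd.unique(day_states["state"]):
        rows = np.flatnonzero([state_map.get(int(d)) == state for d in day_of_sample])
        if len(rows) == 0:
            continue
        y = series[rows]
        preds = np.full(len(rows), np.nan)
        fold_r2 = []
        try:
            for test in contiguous_folds(len(rows), n_folds):
                train = np.setdiff1d(np.arange(len(rows)), test, assume_unique=True)
                preds[test] = fit_predict(train, test, rows)
                fold_r2.append(r2_score(y[test], preds[test]))
        except _StateTooSmall as exc:
            warnings.warn(f"state {state!r} skipped: {exc}")
            continue
        state_means[state] = float(np.mean(fold_r2))
        days_here = day_of_sample[rows]
        for day in np.unique(days_here):
            m = days_here == day
            value = r2_score(y[m], preds[m]) if m.sum() >= min_day_points else np.nan
            daily_rows.append((int(day), value, state))
    daily = pd.DataFrame(daily_rows, columns=["day", "value", "state"])
    return state_means, daily.sort_values("day").reset_index(drop=True)


class _StateTooSmall(Exception):
    pass


def cv_daily_r2_linear(series: np.ndarray, lags, day_of_sample: np.ndarray,
                       day_states: pd.DataFrame, n_folds: int = 5,
                       min_day_points: int = 36, hac: bool = False
                       ) -> tuple[dict, pd.DataFrame]:
    """Per-state cross-validated linear-AR R² and the daily R² series.

    ``day_of_sample`` maps each sample of ``series`` to its day index.  An
    empty lag set degrades to the intercept-only model (held-out R² ≤ 0 by
    construction), logged prominently.
    """
    x = np.asarray(series, dtype=float).reshape(-1)
    day_of_sample = np.asarray(day_of_sample).reshape(-1)
    lags = sorted(set(int(k) for k in lags))
    if not lags:
        warnings.warn("empty lag set: reporting intercept-only held-out R2")
        pos = np.flatnonzero(np.isfinite(x))
        yv, Xv = x[pos], np.empty((len(pos), 0))
    else:
        yv, Xv, pos = build_lag_matrix(x, lags)
    targets_day = day_of_sample[pos]

    def fit_predict(train, test, rows):
        if len(train) < n_folds * (len(lags) + 1):
            raise _StateTooSmall(
                f"{len(train)} rows for {len(lags)} lags")
        if lags:
            model = LinearAR(hac=hac).fit(Xv[rows][train], yv[rows][train])
            return model.predict(Xv[rows][test])
        return np.full(len(test), yv[rows][train].mean())

    return _statewise_cv(yv, targets_day, day_states, n_folds, min_day_points,
                         fit_predict)


def cv_daily_r2_nonlinear(series: np.ndarray, day_of_sample: np.ndarray,
                          day_states: pd.DataFrame, n_folds: int = 5,
                          seed: int = 0, epochs: int = 50, hidden: int = 32,
                          lr: float = 1e-3, l1: float = 1e-5,
                          batch_size: int = 128, min_day_points: int = 36
                          ) -> tuple[dict, pd.DataFrame]:
    """Per-state cross-validated small-MLP R² and the daily R² series.

    Always uses the full previous day (144 lags) as inputs.  Per fold the
    network trains ``epochs`` epochs and the epoch with the best held-out
    R² supplies the fold's predictions.  Deterministic for a fixed seed.
    """
    x = np.asarray(series, dtype=float).reshape(-1)
    day_of_sample = np.asarray(day_of_sample).reshape(-1)
    yv, Xv, pos = build_lag_matrix(x, range(1, MAX_LAG + 1))
    targets_day = day_of_sample[pos]
    counter = {"fold": 0}

    def fit_predict(train, test, rows):
        if len(train) < n_folds * (MAX_LAG + 1):
            raise _StateTooSmall(f"{len(train)} rows for {MAX_LAG} lag inputs")
        counter["fold"] += 1
        net = MLPRegressorNumpy(hidden=hidden, epochs=epochs, lr=lr, l1=l1,
                                batch_size=batch_size,
                                random_state=seed + 1000 * counter["fold"])
        net.fit(Xv[rows][train], yv[rows][train],
                validation_data=(Xv[rows][test], yv[rows][test]))
        return net.predict(Xv[rows][test])

    return _statewise_cv(yv, targets_day, day_states, n_folds, min_day_points,
                         fit_predict)
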