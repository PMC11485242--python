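"""Multicomponent cosinor rhythmometry.

The cosinor model regresses a periodic signal on sine/cosine harmonics of a
fixed 24-h period,

    y(t) = M + Σ_j [ A_{j,1} sin(2πjt/P) + A_{j,2} cos(2πjt/P) ] + e(t),

fitted by ordinary least squares.  M is the MESOR (rhythm-adjusted mean);
each harmonic j has amplitude √(A_{j,1}² + A_{j,2}²); the acrophase is the
clock time of the primary (largest-amplitude) fitted peak.  Goodness of fit
is the coefficient of determination R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)².
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import r2_score

from .types import BINS_PER_DAY, DailyMatrix

PERIOD_H = 24.0  # fixed analysis period


def _design(t_hours: np.ndarray, n_components: int, period: float) -> np.ndarray:
    cols = [np.ones_like(t_hours)]
    for j in range(1, n_components + 1):
        w = 2.0 * np.pi * j * t_hours / period
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols)


class CosinorRegressor(BaseEstimator, RegressorMixin):
    """Sklearn-style multicomponent cosinor fit with a fixed period.

    Parameters
    ----------
    n_components : number of harmonics of the base period to fit.
    period : period in hours (24 for all circadian analyses here).

    Fitted attributes
    -----------------
    mesor_ : rhythm-adjusted mean.
    coef_sin_, coef_cos_ : per-harmonic sine/cosine coefficients.
    amplitudes_ : per-harmonic amplitudes (√(sin²+cos²)).
    acrophases_h_ : per-harmonic first peak time in hours.
    amplitude_, acrophase_h_, primary_component_ : the primary (largest-
        amplitude) harmonic's amplitude, peak clock time in [0, 24), and
        1-based harmonic index.
    pvalue_ : F-test p-value of the primary harmonic's sine/cosine pair
        (full model vs. the model without that pair).
    """

    def __init__(self, n_components: int = 2, period: float = PERIOD_H):
        self.n_components = n_components
        self.period = period

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        keep = np.isfinite(t) & np.isfinite(y)
        t, y = t[keep], y[keep]
        n_params = 2 * self.n_components + 1
        if len(t) < 2 * n_params:
            raise ValueError(
                f"need at least {2 * n_params} points for {self.n_components} components")
        D = _design(t, self.n_components, self.period)
        rank = np.linalg.matrix_rank(D)
        if rank < n_params:
            raise ValueError("rank-deficient cosinor design (degenerate sampling times)")
        beta, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
        self.t_ = t
        self.y_ = y
        self.mesor_ = beta[0]
        self.coef_sin_ = beta[1::2].copy()
        self.coef_cos_ = beta[2::2].copy()
        self.amplitudes_ = np.hypot(self.coef_sin_, self.coef_cos_)
        # A_s sin(wt) + A_c cos(wt) = amp·cos(wt − φ) with φ = atan2(A_s, A_c);
        # first peak of harmonic j at t = φ·P/(2πj)
        phis = np.arctan2(self.coef_sin_, self.coef_cos_)
        js = np.arange(1, self.n_components + 1)
        self.acrophases_h_ = (phis * self.period / (2 * np.pi * js)) % (self.period / js)
        self.primary_component_ = int(np.argmax(self.amplitudes_)) + 1
        self.amplitude_ = float(self.amplitudes_[self.primary_component_ - 1])
        self.acrophase_h_ = float(
            self.acrophases_h_[self.primary_component_ - 1] % self.period)
        self._fit_primary_ftest(D, y, beta)
        return self

    def _fit_primary_ftest(self, D, y, beta):
        resid_full = y - D @ beta
        ss_full = resid_full @ resid_full
        j = self.primary_component_
        keep = np.ones(D.shape[1], dtype=bool)
        keep[2 * j - 1] = keep[2 * j] = False
        beta_red, _, _, _ = np.linalg.lstsq(D[:, keep], y, rcond=None)
        resid_red = y - D[:, keep] @ beta_red
        ss_red = resid_red @ resid_red
        df2 = len(y) - D.shape[1]
        if df2 <= 0 or ss_full <= 0:
            self.pvalue_ = 0.0 if ss_red > ss_full else 1.0
            return
        f = ((ss_red - ss_full) / 2.0) / (ss_full / df2)
        self.pvalue_ = float(sps.f.sf(f, 2, df2))

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        D = _design(t, self.n_components, self.period)
        beta = np.empty(2 * self.n_components + 1)
        beta[0] = self.mesor_
        beta[1::2] = self.coef_sin_
        beta[2::2] = self.coef_cos_
        return D @ beta

    def score(self, X=None, y=None):
        """In-sample R² when called without arguments, else Eq.-2 R² on (X, y)."""
        if X is None:
            return r2_score(self.y_, self.predict(self.t_))
        return r2_score(np.asarray(y, dtype=float), self.predict(X))


def fit_cosinor(values, times_of_day_h, n_components: int = 2) -> CosinorRegressor:
    """Functional wrapper: OLS cosinor fit of ``values`` at hours ``times_of_day_h``."""
    return CosinorRegressor(n_components=n_components).fit(times_of_day_h, values)


# ---------------------------------------------------------------------------
# daily matrix helpers

def _matrix_timepoints(matrix: DailyMatrix, rows: np.ndarray):
    """Flatten selected rows chronologically → (day, hour-of-day, value)."""
    hours = np.arange(BINS_PER_DAY) / 6.0
    days = np.repeat(matrix.days[rows], BINS_PER_DAY)
    t = np.tile(hours, len(rows))
    v = matrix.values[rows].reshape(-1)
    keep = np.isfinite(v)
    return days[keep], t[keep], v[keep]


def windowed_daily_cosinor(matrix: DailyMatrix, window: int = 5,
                           n_components: int = 2, min_points: int = 48
                           ) -> pd.DataFrame:
    """Per-day cosinor amplitude/acrophase/p from a centred ±(window//2)-day pool.

    Each day's fit pools the samples of the ``window``-day window centred on
    it (edge days use the truncated window).  Days whose window holds fewer
    than ``min_points`` samples get missing outputs.
    """
    half = window // 2
    out = []
    for i, day in enumerate(matrix.days):
        rows = np.flatnonzero(np.abs(matrix.days - day) <= half)
        _, t, v = _matrix_timepoints(matrix, rows)
        if len(v) < max(min_points, 2 * (2 * n_components + 1)):
            out.append((day, np.nan, np.nan, np.nan))
            continue
        try:
            fit = fit_cosinor(v, t, n_components)
        except ValueError:
            out.append((day, np.nan, np.nan, np.nan))
            continue
        out.append((day, fit.amplitude_, fit.acrophase_h_, fit.pvalue_))
    return pd.DataFrame(out, columns=["day", "amplitude", "acrophase_h", "p"])


def contiguous_folds(n: int, n_folds: int) -> list[np.ndarray]:
    """Contiguous, unshuffled index blocks (shared CV scheme across metrics)."""
    return [b for b in np.array_split(np.arange(n), n_folds) if len(b)]


def statewise_cv_daily_r2(matrix: DailyMatrix, day_states: pd.DataFrame,
                          n_components: int = 2, n_folds: int = 5,
                          min_day_points: int = 36) -> tuple[dict, pd.DataFrame]:
    """State-level cross-validated cosinor R² and a per-day held-out R² series.

    Within each clinical state the state's 10-min timepoints are split into
    ``n_folds`` contiguous blocks; each block is predicted by a cosinor
    fitted on the remaining blocks.  Per-fold held-out R² values are
    averaged into the state mean; pooled held-out predictions grouped by
    day give the daily R² (missing when a day has fewer than
    ``min_day_points`` held-out points).  Held-out R² may be negative.
    """
    state_map = dict(zip(day_states["day"], day_states["state"]))
    state_means: dict[str, float] = {}
    daily_rows = []
    for state in pd.unique(day_states["state"]):
        rows = np.flatnonzero([state_map.get(d) == state for d in matrix.days])
        if len(rows) == 0:
            continue
        days, t, v = _matrix_timepoints(matrix, rows)
        n_params = 2 * n_components + 1
        if len(v) < n_folds * n_params:
            warnings.warn(f"state {state!r} has too few points; skipped")
            continue
        preds = np.full(len(v), np.nan)
        fold_r2 = []
        for test in contiguous_folds(len(v), n_folds):
            train = np.setdiff1d(np.arange(len(v)), test, assume_unique=True)
            fit = fit_cosinor(v[train], t[train], n_components)
            preds[test] = fit.predict(t[test])
            fold_r2.append(r2_score(v[test], preds[test]))
        state_means[state] = float(np.mean(fold_r2))
        for day in np.unique(days):
            m = days == day
            if m.sum() >= min_day_points:
                daily_rows.append((int(day), r2_score(v[m], preds[m]), state))
            else:
                daily_rows.append((int(day), np.nan, state))
    daily = pd.DataFrame(daily_rows, columns=["day", "value", "state"])
    return state_means, daily.sort_values("day").reset_index(drop=True)


# ---------------------------------------------------------------------------
# circularized-day construction

#: angular target of the acrophase after rotation: 3π/2 → bin 108 of 144
ROTATION_TARGET_BIN = int(BINS_PER_DAY * 3 / 4)


def rotate_smooth_day(day_row: np.ndarray, acrophase_h: float,
                      kernel_sd_bins: float = 3.0, smooth: bool = True
                      ) -> np.ndarray:
    """Circularly rotate a day so its acrophase sits at 3π/2, then blur.

    The bin nearest the acrophase is shifted to bin 108 (the 18:00 slot,
    pointing downwards on a polar plot).  Smoothing is a normalized circular
    Gaussian; missing entries stay missing and are excluded from their
    neighbours' averages.
    """
    v = np.asarray(day_row, dtype=float)
    if v.shape != (BINS_PER_DAY,):
        raise ValueError(f"day row must have {BINS_PER_DAY} bins")
    acro_bin = int(round(acrophase_h * BINS_PER_DAY / 24.0)) % BINS_PER_DAY
    rotated = np.roll(v, ROTATION_TARGET_BIN - acro_bin)
    if not smooth:
        return rotated
    offsets = np.arange(-3 * int(np.ceil(kernel_sd_bins)),
                        3 * int(np.ceil(kernel_sd_bins)) + 1)
    kernel = np.exp(-0.5 * (offsets / kernel_sd_bins) ** 2)
    kernel /= kernel.sum()
    finite = np.isfinite(rotated)
    num = np.zeros(BINS_PER_DAY)
    den = np.zeros(BINS_PER_DAY)
    for off, w in zip(offsets, kernel):
        shifted = np.roll(rotated, off)
        ok = np.roll(finite, off)
        num[ok] += w * shifted[ok]
        den[ok] += w
    out = np.full(BINS_PER_DAY, np.nan)
    ok = finite & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def average_circularized(days: np.ndarray) -> np.ndarray:
    """Bin-wise missing-aware mean over rotated days."""
    days = np.atleast_2d(np.asarray(days, dtype=float))
    if days.shape[0] < 1:
        raise ValueError("need at least one day")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(days, axis=0)
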