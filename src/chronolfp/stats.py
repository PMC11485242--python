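"""Effective-sample-size-corrected state comparisons.

Daily metric values are strongly autocorrelated, so a naive t-test at the
daily sample size overstates the evidence.  The effective sample size (ESS)
discounts N by the sample autocorrelations up to a 10-day lag,

    N_eff = N / (1 + 2 Σ_{k=1..m} ρ_k),

and Welch's t and Hedges' g are then computed with N_eff in place of N
(means and variances still come from the full samples).  Comparisons are
reported as the change from the first state to the second (mean₂ − mean₁).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.tsa.stattools import acf

ESS_MAX_LAG_DAYS = 10


@dataclass
class StateComparison:
    """One Welch/Hedges comparison row (uncorrected or ESS-corrected)."""

    metric: str
    patient: str
    state_a: str
    state_b: str
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    hedges_g: float
    g_ci_low: float
    g_ci_high: float
    n1: int
    n2: int
    neff1: int
    neff2: int
    corrected: bool

    def to_row(self) -> dict:
        return vars(self).copy()


def effective_sample_size(x, max_lag: int = ESS_MAX_LAG_DAYS,
                          positive_sequence: bool = True,
                          bias_correction: bool = True) -> int:
    """ESS of a day-ordered value sequence.

    Sample autocorrelations (biased 1/N normalisation) are summed up to
    min(max_lag, N−1) lags.  Two standard refinements are on by default:
    the lag sum stops at the first non-positive autocorrelation (the
    initial-positive-sequence rule used in Markov-chain ESS estimation),
    and the first-order downward bias of the sample ACF from mean
    estimation — E[ρ̂_k] ≈ ρ_k − (1 + 2Σρ)/N — is removed in closed form.
    Both can be disabled to obtain the plain plug-in.

    A non-positive denominator (strong negative autocorrelation) caps the
    result at N; the floor is 2 so downstream tests stay defined.  Rounded
    to the nearest integer.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    nlags = min(max_lag, n - 1)
    if np.std(x) == 0:
        return n
    rho = acf(x, nlags=nlags, fft=False, adjusted=False)[1:]
    if positive_sequence:
        neg = np.flatnonzero(rho <= 0)
        if len(neg):
            rho = rho[:neg[0]]
    k = len(rho)
    s = float(np.sum(rho))
    if bias_correction and k and n > 2 * k:
        s = (s + k / n) / (1.0 - 2.0 * k / n)
    denom = 1.0 + 2.0 * s
    if denom <= 0:
        return n
    return int(np.clip(round(n / denom), 2, n))


def welch_t(a, b, n1: int, n2: int) -> tuple[float, float, float, tuple[float, float]]:
    """Welch's two-sample two-tailed t-test at (possibly effective) sizes n1, n2.

    Means and variances come from the full samples ``a`` and ``b``; the
    standard error and Welch–Satterthwaite df use ``n1``/``n2``.  Returns
    (t, df, p, 95% CI of mean_b − mean_a).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if n1 < 2 or n2 < 2:
        raise ValueError("sample sizes must be >= 2")
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("zero variance in both samples")
    diff = float(np.mean(b) - np.mean(a))
    se = np.sqrt(v1 / n1 + v2 / n2)
    t = diff / se
    df = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    tcrit = sps.t.ppf(0.975, df)
    return float(t), float(df), p, (diff - tcrit * se, diff + tcrit * se)


def hedges_g(a, b, n1: int, n2: int) -> tuple[float, tuple[float, float]]:
    """Hedges' g (small-sample-corrected standardized difference mean_b − mean_a).

    The pooled SD and the correction factor J = 1 − 3/(4·(n1+n2−2)−1) use
    the supplied (possibly effective) sizes.  The CI is a normal
    approximation with variance (n1+n2)/(n1·n2) + g²/(2(n1+n2−2)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if n1 < 2 or n2 < 2:
        raise ValueError("sample sizes must be >= 2")
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    dof = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / dof)
    if sp == 0:
        raise ValueError("zero pooled variance")
    d = (np.mean(b) - np.mean(a)) / sp
    j = 1.0 - 3.0 / (4.0 * dof - 1.0)
    g = j * d
    var_g = (n1 + n2) / (n1 * n2) + g**2 / (2.0 * dof)
    half = 1.959963984540054 * np.sqrt(var_g)
    return float(g), (float(g - half), float(g + half))


def _state_values(daily: pd.DataFrame, state: str) -> np.ndarray:
    vals = daily.loc[daily["state"] == state].sort_values("day")["value"].to_numpy()
    return vals[np.isfinite(vals)]


def compare_states(daily: pd.DataFrame, state_a: str, state_b: str,
                   metric: str = "", patient: str = "", corrected: bool = False,
                   ess_max_lag: int = ESS_MAX_LAG_DAYS) -> StateComparison | None:
    """Welch/Hedges comparison of one metric's daily values between two states.

    ``daily`` has columns (day, value, state).  Returns None when either
    state is absent.  With ``corrected`` the per-state ESS replaces N in
    the test and effect size.
    """
    a = _state_values(daily, state_a)
    b = _state_values(daily, state_b)
    if len(a) < 2 or len(b) < 2:
        return None
    n1, n2 = len(a), len(b)
    neff1 = effective_sample_size(a, ess_max_lag)
    neff2 = effective_sample_size(b, ess_max_lag)
    use1, use2 = (neff1, neff2) if corrected else (n1, n2)
    t, df, p, ci = welch_t(a, b, use1, use2)
    g, gci = hedges_g(a, b, use1, use2)
    return StateComparison(metric=metric, patient=patient, state_a=state_a,
                           state_b=state_b, t=t, df=df, p=p,
                           ci_low=ci[0], ci_high=ci[1], hedges_g=g,
                           g_ci_low=gci[0], g_ci_high=gci[1],
                           n1=n1, n2=n2, neff1=neff1, neff2=neff2,
                           corrected=corrected)


def pooled_compare(per_patient: dict[str, pd.DataFrame], group_a: str,
                   group_b: str, metric: str = "", corrected: bool = False,
                   ess_max_lag: int = ESS_MAX_LAG_DAYS) -> StateComparison:
    """Cross-patient pooled comparison of two label groups.

    ``per_patient`` maps patient id → DataFrame(day, value, label); values
    are pooled across patients per group and the group ESS is the sum of
    each contributing patient's ESS (a patient needs ≥ 2 values in a group
    to contribute).
    """
    pooled = {group_a: [], group_b: []}
    neff = {group_a: 0, group_b: 0}
    for pid, df in per_patient.items():
        for grp in (group_a, group_b):
            vals = df.loc[df["label"] == grp].sort_values("day")["value"].to_numpy()
            vals = vals[np.isfinite(vals)]
            if len(vals) >= 2:
                pooled[grp].append(vals)
                neff[grp] += effective_sample_size(vals, ess_max_lag)
    if not pooled[group_a] or not pooled[group_b]:
        raise ValueError("a pooled group is empty")
    a = np.concatenate(pooled[group_a])
    b = np.concatenate(pooled[group_b])
    n1, n2 = len(a), len(b)
    use1, use2 = (neff[group_a], neff[group_b]) if corrected else (n1, n2)
    t, df_, p, ci = welch_t(a, b, use1, use2)
    g, gci = hedges_g(a, b, use1, use2)
    return StateComparison(metric=metric, patient="pooled", state_a=group_a,
                           state_b=group_b, t=t, df=df_, p=p,
                           ci_low=ci[0], ci_high=ci[1], hedges_g=g,
                           g_ci_low=gci[0], g_ci_high=gci[1],
                           n1=n1, n2=n2, neff1=neff[group_a],
                           neff2=neff[group_b], corrected=corrected)


def delta_metric(daily: pd.DataFrame, pre_mean: float) -> pd.DataFrame:
    """Per-day delta series: daily value minus the pre-DBS state mean."""
    if not np.isfinite(pre_mean):
        raise ValueError("pre-DBS mean is undefined")
    out = daily.copy()
    out["value"] = out["value"] - pre_mean
    return out


def max_margin_threshold(values, labels) -> tuple[bool, float, float]:
    """1-D max-margin separability of per-patient state means.

    Returns (separable, threshold, margin): separable iff the class ranges
    are disjoint; the threshold is the midpoint of the gap and the margin
    its width (0 when not separable, threshold NaN).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both classes must be non-empty")
    if a.max() < b.min():
        gap = b.min() - a.max()
        return True, float(a.max() + gap / 2), float(gap)
    if b.max() < a.min():
        gap = a.min() - b.max()
        return True, float(b.max() + gap / 2), float(gap)
    return False, float("nan"), 0.0
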