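"""Effective sample size, corrected Welch/Hedges comparisons, deltas, margins."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chronolfp.stats import (
    compare_states,
    delta_metric,
    effective_sample_size,
    hedges_g,
    max_margin_threshold,
    pooled_compare,
    welch_t,
)


def _ar1(n, phi, seed, mean=0.0):
    rng = np.random.default_rng(seed)
    x = np.zeros(n + 100)
    eps = rng.normal(0, 1, n + 100)
    for t in range(1, len(x)):
        x[t] = phi * x[t - 1] + eps[t]
    return mean + x[100:]


# ---------------------------------------------------------------------------
# effective sample size

def test_ess_of_iid_data_near_n():
    vals = [effective_sample_size(np.random.default_rng(s).standard_normal(200))
            for s in range(500)]
    assert abs(np.mean(vals) - 200) / 200 < 0.10


def test_ess_alternating_sequence_clamps_to_n():
    x = np.tile([1.0, -1.0], 50)
    assert effective_sample_size(x) == 100


def test_ess_ar1_matches_plugin_oracle():
    phi, n = 0.7, 200
    oracle = n / (1 + 2 * sum(phi**k for k in range(1, 11)))
    vals = [effective_sample_size(_ar1(n, phi, seed)) for seed in range(300)]
    assert abs(np.mean(vals) - oracle) / oracle < 0.15


def test_ess_bounds_and_errors():
    with pytest.raises(ValueError):
        effective_sample_size([1.0])
    x = _ar1(50, 0.95, 3)
    ess = effective_sample_size(x)
    assert 2 <= ess <= 50


# ---------------------------------------------------------------------------
# Welch t and Hedges g

def test_welch_identical_samples():
    a = np.random.default_rng(0).standard_normal(30)
    t, df, p, ci = welch_t(a, a, 30, 30)
    assert t == 0.0 and p == pytest.approx(1.0)
    assert ci[0] < 0 < ci[1]


def test_welch_antisymmetry():
    rng = np.random.default_rng(1)
    a, b = rng.standard_normal(25), rng.standard_normal(40) + 0.5
    t1, _, p1, _ = welch_t(a, b, 25, 40)
    t2, _, p2, _ = welch_t(b, a, 40, 25)
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)


def test_welch_with_ess_matches_surrogate_construction():
    """Substituting Neff must equal a reference Welch test fed surrogate
    samples of size Neff with the same means and variances."""
    rng = np.random.default_rng(2)
    a, b = rng.standard_normal(60) + 0.3, rng.standard_normal(80)
    neff1, neff2 = 20, 30

    def surrogate(x, n):
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std(ddof=1)
        return x.mean() + z * np.std(x, ddof=1)

    sa, sb = surrogate(a, neff1), surrogate(b, neff2)
    ref = sps.ttest_ind(sb, sa, equal_var=False)
    t, df, p, _ = welch_t(a, b, neff1, neff2)
    assert t == pytest.approx(ref.statistic, abs=1e-9)
    assert p == pytest.approx(ref.pvalue, abs=1e-9)


def test_hedges_identity_and_small_sample_shrinkage():
    a = np.array([1.0, 2.0, 3.0])
    g, _ = hedges_g(a, a, 3, 3)
    assert g == 0.0
    a2, b2 = np.array([0.0, 1.0]), np.array([1.5, 2.5])
    g2, _ = hedges_g(a2, b2, 2, 2)
    sp = np.sqrt((np.var(a2, ddof=1) + np.var(b2, ddof=1)) / 2)
    d = (b2.mean() - a2.mean()) / sp
    assert abs(g2) < abs(d)


def test_hedges_asymptotic_unit_shift():
    rng = np.random.default_rng(3)
    a = rng.standard_normal(200_000)
    b = rng.standard_normal(200_000) + 1.0
    g, _ = hedges_g(a, b, len(a), len(b))
    assert g == pytest.approx(1.0, abs=0.02)


# ---------------------------------------------------------------------------
# state comparisons

def _daily(values, states):
    return pd.DataFrame({"day": np.arange(len(values)), "value": values,
                         "state": states})


def test_corrected_df_never_exceeds_uncorrected():
    x = np.r_[_ar1(40, 0.6, 4, mean=1.0), _ar1(60, 0.6, 5)]
    daily = _daily(x, ["pre"] * 40 + ["post"] * 60)
    unc = compare_states(daily, "pre", "post", corrected=False)
    cor = compare_states(daily, "pre", "post", corrected=True)
    assert cor.df <= unc.df
    assert cor.neff1 <= cor.n1 and cor.neff2 <= cor.n2


def test_correction_never_increases_significance_under_positive_autocorr():
    x = np.r_[_ar1(60, 0.7, 6, mean=0.5), _ar1(60, 0.7, 7)]
    daily = _daily(x, ["pre"] * 60 + ["post"] * 60)
    unc = compare_states(daily, "pre", "post", corrected=False)
    cor = compare_states(daily, "pre", "post", corrected=True)
    assert cor.p >= unc.p


def test_comparison_sign_convention_is_change_from_first_state():
    daily = _daily(np.r_[np.full(10, 1.0) + np.arange(10) * 1e-3,
                         np.full(10, 2.0) - np.arange(10) * 1e-3],
                   ["pre"] * 10 + ["post"] * 10)
    cmp_ = compare_states(daily, "pre", "post")
    assert cmp_.t > 0 and cmp_.hedges_g > 0  # post mean is higher


def test_missing_state_returns_none():
    daily = _daily(np.arange(10.0), ["pre"] * 10)
    assert compare_states(daily, "pre", "post") is None


# ---------------------------------------------------------------------------
# pooled comparisons

def _patient_frame(values, labels):
    return pd.DataFrame({"day": np.arange(len(values)), "value": values,
                         "label": labels})


def test_pooled_single_patient_reduces_to_compare_states():
    x = np.r_[_ar1(30, 0.5, 8, mean=1.0), _ar1(30, 0.5, 9)]
    labels = ["burdened"] * 30 + ["unburdened"] * 30
    pooled = pooled_compare({"P1": _patient_frame(x, labels)},
                            "burdened", "unburdened", corrected=True)
    daily = _daily(x, labels)
    single = compare_states(daily, "burdened", "unburdened", corrected=True)
    assert pooled.t == pytest.approx(single.t)
    assert pooled.p == pytest.approx(single.p)
    assert (pooled.neff1, pooled.neff2) == (single.neff1, single.neff2)


def test_pooled_duplication_doubles_counts():
    x = np.r_[_ar1(30, 0.5, 10, mean=1.0), _ar1(30, 0.5, 11)]
    labels = ["burdened"] * 30 + ["unburdened"] * 30
    f = _patient_frame(x, labels)
    one = pooled_compare({"P1": f}, "burdened", "unburdened", corrected=True)
    two = pooled_compare({"P1": f, "P2": f.copy()}, "burdened", "unburdened",
                         corrected=True)
    assert two.n1 == 2 * one.n1 and two.n2 == 2 * one.n2
    assert two.neff1 == 2 * one.neff1 and two.neff2 == 2 * one.neff2


def test_pooled_empty_group_raises():
    f = _patient_frame(np.arange(10.0), ["burdened"] * 10)
    with pytest.raises(ValueError, match="empty"):
        pooled_compare({"P1": f}, "burdened", "unburdened")


# ---------------------------------------------------------------------------
# deltas and max margin

def test_delta_examples():
    daily = _daily(np.array([1.0, 1.5, 2.0]), ["post"] * 3)
    out = delta_metric(daily, pre_mean=1.5)
    np.testing.assert_allclose(out["value"], [-0.5, 0.0, 0.5])
    shifted = delta_metric(daily.assign(value=daily["value"] + 2.0), 1.5)
    np.testing.assert_allclose(shifted["value"] - out["value"], 2.0)
    with pytest.raises(ValueError):
        delta_metric(daily, float("nan"))


@pytest.mark.parametrize("a,b,sep,thr,margin", [
    ([1, 2], [5, 6], True, 3.5, 3.0),
    ([1, 5], [2, 6], False, None, 0.0),
    ([2.0], [3.0], True, 2.5, 1.0),
])
def test_max_margin_examples(a, b, sep, thr, margin):
    values = np.r_[a, b]
    labels = ["x"] * len(a) + ["y"] * len(b)
    got_sep, got_thr, got_margin = max_margin_threshold(values, labels)
    assert got_sep is sep
    if sep:
        assert got_thr == pytest.approx(thr)
    assert got_margin == pytest.approx(margin)


# ---------------------------------------------------------------------------
# fixture-based pipeline signs

def test_responder_linear_ar_drop_is_significant(responder_prepared,
                                                 responder_bundle):
    from chronolfp.pipeline import analyze_hemisphere

    r = analyze_hemisphere(responder_bundle.series["L"],
                           responder_bundle.trajectory,
                           include_nonlinear=False)
    d = r.daily[r.daily["metric"] == "linear_ar_r2"]
    cmp_ = compare_states(d, "severe_symptoms_preDBS", "clinical_response",
                          corrected=True)
    assert cmp_.hedges_g < 0
    assert cmp_.p < 0.05


def test_responder_ar_contrast_regression_constant():
    """Frozen end-to-end value: default responder, seed 0, linear-AR Hedges g.

    The pipeline is deterministic for a fixed seed; this pins the whole
    simulate → condition → lag-select → CV → compare chain.
    """
    import warnings

    from chronolfp.pipeline import analyze_hemisphere
    from chronolfp.simulate import ArtifactSpec, PatientSimParams, simulate_patient

    b = simulate_patient(PatientSimParams(patient_id="P", responder=True),
                         ArtifactSpec(), seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = analyze_hemisphere(b.series["L"], b.trajectory,
                               include_nonlinear=False)
    d = r.daily[r.daily["metric"] == "linear_ar_r2"]
    cmp_ = compare_states(d, "severe_symptoms_preDBS", "clinical_response",
                          corrected=False)
    assert cmp_.hedges_g < 0
    assert cmp_.hedges_g == pytest.approx(-2.349532074806, abs=1e-6)


def test_nonresponder_shows_no_corrected_change(nonresponder_bundle):
    from chronolfp.pipeline import analyze_hemisphere

    r = analyze_hemisphere(nonresponder_bundle.series["L"],
                           nonresponder_bundle.trajectory,
                           include_nonlinear=False)
    d = r.daily[r.daily["metric"] == "linear_ar_r2"]
    cmp_ = compare_states(d, "severe_symptoms_preDBS", "persistent_symptoms",
                          corrected=True)
    assert cmp_.p > 0.05
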