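"""Conditioning, binning, z-scoring and PSD behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import PchipInterpolator

from chronolfp.ingest import (
    bin_daily,
    condition_series,
    interpolate_gaps,
    read_sessions,
    replace_outliers,
    welch_psd,
    zscore_daily,
)
from chronolfp.simulate import make_test_sine
from chronolfp.types import BINS_PER_DAY, AmplitudeSeries, DailyMatrix


def _series(values, start="2023-01-01 00:00"):
    ts = pd.date_range(start, periods=len(values), freq="10min")
    return AmplitudeSeries("P", "L", ts, np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# outliers

def _inject_at_k_sd(v, idx, k):
    """Set v[idx] so it sits exactly k SDs above the chunk median *including itself*.

    The 30-SD rule uses the statistics of the chunk as recorded (spike
    included), so the spike must be placed relative to the post-injection
    median and SD; a short chunk inflates its own SD and needs a larger raw
    value.  Fixed-point iteration converges in a few steps.
    """
    v = v.copy()
    x = np.median(v) + k * np.std(v, ddof=1)
    for _ in range(200):
        v[idx] = x
        target = np.median(v) + k * np.std(v, ddof=1)
        if abs(target - x) < 1e-10:
            break
        x = target
    v[idx] = x
    return v


def test_outlier_just_above_threshold_is_replaced(rng):
    v = _inject_at_k_sd(rng.normal(0.0, 1.0, 5000), 100, 30.5)
    out, n = replace_outliers(_series(v))
    assert n == 1
    assert out.values[100] != v[100]
    lo = min(out.values[99], out.values[101])
    hi = max(out.values[99], out.values[101])
    assert lo - 1e-9 <= out.values[100] <= hi + 1e-9
    np.testing.assert_array_equal(np.delete(out.values, 100), np.delete(v, 100))


def test_outlier_below_threshold_untouched(rng):
    v = _inject_at_k_sd(rng.normal(0.0, 1.0, 5000), 100, 29.0)
    out, n = replace_outliers(_series(v))
    assert n == 0
    np.testing.assert_array_equal(out.values, v)


def test_adjacent_outliers_match_reference_pchip(rng):
    v = rng.normal(0.0, 1.0, 10_000)
    sd0 = np.std(v, ddof=1)
    v[200] = v[201] = np.median(v) + 45 * sd0  # still > 30 SD after inflation
    out, n = replace_outliers(_series(v))
    assert n == 2
    good = np.delete(np.arange(len(v)), [200, 201])
    ref = PchipInterpolator(good, v[good])
    np.testing.assert_allclose(out.values[[200, 201]], ref([200, 201]), atol=1e-12)


def test_short_chunk_left_alone_with_warning():
    v = np.array([1.0, np.nan, 2.0, 3.0, np.nan, 5.0, 6.0, 7.0, 8.0, 9.0])
    with pytest.warns(UserWarning):
        out, n = replace_outliers(_series(v))
    assert n == 0


# ---------------------------------------------------------------------------
# gap interpolation

@pytest.mark.parametrize("gap_len,filled", [(6, True), (7, False)])
def test_gap_length_rule_one_hour(gap_len, filled, rng):
    v = rng.normal(5.0, 1.0, 300)
    v[100:100 + gap_len] = np.nan
    out, n, _ = interpolate_gaps(_series(v))
    got = np.isfinite(out.values[100:100 + gap_len])
    assert got.all() == filled and got.any() == filled
    assert n == (gap_len if filled else 0)


def test_gap_in_linear_ramp_is_exact():
    v = np.arange(100, dtype=float)
    v[40:44] = np.nan
    out, _, _ = interpolate_gaps(_series(v))
    np.testing.assert_allclose(out.values, np.arange(100.0), atol=1e-9)


def test_leading_gap_stays_missing():
    v = np.r_[[np.nan] * 3, np.arange(50.0)]
    out, n, _ = interpolate_gaps(_series(v))
    assert np.isnan(out.values[:3]).all()
    assert n == 0


# ---------------------------------------------------------------------------
# binning and z-scoring

def test_bin_edges_and_day_assignment():
    ts = pd.DatetimeIndex([
        "2023-03-01 00:05", "2023-03-01 23:55", "2023-03-02 12:15"])
    s = AmplitudeSeries("P", "L", ts, [1.0, 2.0, 3.0])
    m = bin_daily(s, "2023-03-01")
    assert m.values.shape[1] == BINS_PER_DAY
    assert m.values[0, 0] == 1.0
    assert m.values[0, 143] == 2.0
    assert m.values[1, 73] == 3.0
    assert list(m.days) == [0, 1]


def test_thirty_complete_days_fill_the_matrix(rng):
    v = rng.normal(0, 1, 30 * BINS_PER_DAY)
    m = bin_daily(_series(v, "2023-03-01 00:00"), "2023-03-01")
    assert m.values.shape == (30, BINS_PER_DAY)
    assert np.isfinite(m.values).all()
    # binning preserves the sample count
    assert np.isfinite(m.values).sum() == np.isfinite(v).sum()


def test_zscore_rows_and_degenerate_days(rng):
    v = rng.normal(3.0, 2.0, 5 * BINS_PER_DAY).reshape(5, BINS_PER_DAY)
    v[2, :] = 7.0  # constant day
    m = DailyMatrix(np.arange(5), v)
    z = zscore_daily(m)
    for i in (0, 1, 3, 4):
        assert np.nanmean(z.values[i]) == pytest.approx(0.0, abs=1e-9)
        assert np.nanstd(z.values[i]) == pytest.approx(1.0, abs=1e-9)
    assert np.isnan(z.values[2]).all()


def test_zscore_affine_invariance(rng):
    v = rng.normal(0, 1, 4 * BINS_PER_DAY).reshape(4, BINS_PER_DAY)
    offsets = rng.normal(0, 5, 4)[:, None]
    scales = rng.uniform(0.5, 3.0, 4)[:, None]
    z1 = zscore_daily(DailyMatrix(np.arange(4), v))
    z2 = zscore_daily(DailyMatrix(np.arange(4), v * scales + offsets))
    np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)


def test_low_coverage_day_dropped(rng):
    v = np.full((2, BINS_PER_DAY), np.nan)
    v[0] = rng.normal(0, 1, BINS_PER_DAY)
    v[1, :60] = rng.normal(0, 1, 60)  # below the 72-bin floor
    z = zscore_daily(DailyMatrix(np.arange(2), v))
    assert np.isfinite(z.values[0]).all()
    assert np.isnan(z.values[1]).all()


# ---------------------------------------------------------------------------
# conditioning pipeline properties

def test_conditioning_touches_under_one_percent(responder_bundle):
    _, report = condition_series(responder_bundle.series["L"])
    frac = (report.n_outliers_replaced + report.n_interpolated) / report.n_samples
    assert frac < 0.01


def test_conditioning_idempotent_on_clean_input(clean_patient_series):
    once, r1 = condition_series(clean_patient_series.series["L"])
    twice, r2 = condition_series(once)
    np.testing.assert_array_equal(once.values, twice.values)
    assert r2.n_outliers_replaced == 0 and r2.n_interpolated == 0


# ---------------------------------------------------------------------------
# session reading errors

def test_conflicting_duplicates_raise(tmp_path):
    p = tmp_path / "a.json"
    p.write_text(
        '{"patient_id": "P", "hemisphere": "L", "samples": '
        '[["2023-01-01T00:00:00Z", 1.0], ["2023-01-01T00:00:00Z", 2.0]]}')
    with pytest.raises(ValueError, match="conflicting duplicate"):
        read_sessions([p])


def test_equal_duplicates_collapse(tmp_path):
    p = tmp_path / "a.json"
    p.write_text(
        '{"patient_id": "P", "hemisphere": "L", "samples": '
        '[["2023-01-01T00:00:00Z", 1.0], ["2023-01-01T00:00:00Z", 1.0],'
        ' ["2023-01-01T00:10:00Z", 2.0]]}')
    out = read_sessions([p])
    assert len(out[("P", "L")]) == 2


def test_schema_violation_names_field(tmp_path):
    p = tmp_path / "bad.json"
    p.write_text('{"patient_id": "P", "samples": []}')
    with pytest.raises(ValueError, match="hemisphere"):
        read_sessions([p])


def test_disjoint_files_merge_with_gap(tmp_path):
    a = tmp_path / "a.json"
    b = tmp_path / "b.json"
    a.write_text('{"patient_id": "P", "hemisphere": "L", "samples": '
                 '[["2023-01-01T00:00:00Z", 1.0], ["2023-01-01T00:10:00Z", 2.0]]}')
    b.write_text('{"patient_id": "P", "hemisphere": "L", "samples": '
                 '[["2023-01-01T01:00:00Z", 3.0]]}')
    s = read_sessions([a, b])[("P", "L")]
    assert len(s) == 7  # 00:00 .. 01:00 on the 10-min grid
    assert np.isnan(s.values[2:6]).all()
    assert s.values[6] == 3.0


# ---------------------------------------------------------------------------
# Welch PSD

def test_psd_peak_at_nearest_bin_to_9hz():
    # 8.789 Hz sits exactly on bin 9 of the 256-point grid at 250 Hz
    x = make_test_sine(9 * 250 / 256, duration_s=10.0)
    freqs, db = welch_psd(x)
    assert freqs[np.argmax(db)] == pytest.approx(9 * 250 / 256, abs=1e-9)


def test_psd_amplitude_doubling_adds_6db():
    x = make_test_sine(8.789, 10.0)
    _, db1 = welch_psd(x)
    _, db2 = welch_psd(2 * x)
    np.testing.assert_allclose(db2 - db1, 20 * np.log10(2), atol=1e-9)


def test_psd_white_noise_is_flat(rng):
    x = rng.standard_normal(250 * 120)
    freqs, db = welch_psd(x)
    inner = db[2:-2]  # edge bins carry window effects
    assert inner.max() - inner.min() < 3.0


def test_psd_too_short_segment_raises():
    with pytest.raises(ValueError):
        welch_psd(np.zeros(100))
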