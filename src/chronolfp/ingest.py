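"""Session ingestion, conditioning, daily binning/z-scoring and Welch PSD.

Conditioning follows the device-stream cleaning rules: within each
continuous chunk (maximal run without losses) samples more than 30 SD above
the chunk median are replaced by shape-preserving piecewise-cubic (PCHIP)
interpolation; gaps of at most six samples (1 h) are filled the same way,
longer gaps stay NaN.  Daily matrices are built on the 144-bin local-clock
grid and z-scored per day.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import welch
from scipy.signal.windows import hamming

from .types import BINS_PER_DAY, SAMPLE_MINUTES, AmplitudeSeries, DailyMatrix


@dataclass
class ConditioningReport:
    """Counts of conditioning interventions, for provenance."""

    n_samples: int = 0
    n_outliers_replaced: int = 0
    n_interpolated: int = 0
    mean_interp_run_length: float = float("nan")
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "n_samples": self.n_samples,
            "n_outliers_replaced": self.n_outliers_replaced,
            "n_interpolated": self.n_interpolated,
            "mean_interp_run_length": self.mean_interp_run_length,
            **self.extras,
        })


# ---------------------------------------------------------------------------
# reading session files

def _parse_json_session(path: Path) -> pd.DataFrame:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid session JSON: {exc}") from exc
    for key in ("patient_id", "hemisphere", "samples"):
        if key not in payload:
            raise ValueError(f"{path}: missing required field {key!r}")
    rows = payload["samples"]
    df = pd.DataFrame(rows, columns=["timestamp", "amplitude"]) if rows else \
        pd.DataFrame(columns=["timestamp", "amplitude"])
    df["patient_id"] = payload["patient_id"]
    df["hemisphere"] = payload["hemisphere"]
    df["band_center_hz"] = payload.get("band_center_hz", np.nan)
    return df


def _parse_csv_session(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("timestamp", "hemisphere", "amplitude"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    # CSV sessions carry the patient id in the filename: <patient>_<hemi>_...
    df["patient_id"] = path.stem.split("_")[0]
    df["band_center_hz"] = np.nan
    return df


def read_sessions(paths, tz_offset_min: int = 0,
                  regular_grid: bool = True) -> dict[tuple[str, str], AmplitudeSeries]:
    """Read session files into one merged series per (patient, hemisphere).

    UTC timestamps are converted to local time with ``tz_offset_min``.
    Duplicate timestamps with equal values collapse to one sample;
    conflicting duplicates raise.  With ``regular_grid`` the series is
    reindexed onto the full 10-min grid, gaps as NaN.
    """
    frames = []
    for p in map(Path, paths):
        if p.suffix == ".json":
            frames.append(_parse_json_session(p))
        elif p.suffix == ".csv":
            frames.append(_parse_csv_session(p))
        else:
            raise ValueError(f"{p}: unknown session file type")
    if not frames:
        raise ValueError("no session files given")
    df = pd.concat(frames, ignore_index=True)
    if len(df) and df["hemisphere"].map(lambda h: h not in ("L", "R")).any():
        bad = df.loc[~df["hemisphere"].isin(["L", "R"]), "hemisphere"].iloc[0]
        raise ValueError(f"invalid hemisphere field value {bad!r}")

    out: dict[tuple[str, str], AmplitudeSeries] = {}
    for (pid, hemi), g in df.groupby(["patient_id", "hemisphere"], sort=True):
        ts = pd.to_datetime(g["timestamp"], utc=True).dt.tz_localize(None)
        local = pd.DatetimeIndex(ts) + pd.Timedelta(minutes=tz_offset_min)
        s = pd.Series(g["amplitude"].to_numpy(dtype=float), index=local).sort_index()
        dup = s.index.duplicated(keep=False)
        if dup.any():
            per_stamp = s[dup].groupby(level=0).nunique()
            conflicts = per_stamp[per_stamp > 1]
            if len(conflicts):
                raise ValueError(
                    f"conflicting duplicate values at {conflicts.index[0]} "
                    f"for {pid}/{hemi}")
            s = s[~s.index.duplicated(keep="first")]
        series = AmplitudeSeries(pid, hemi, pd.DatetimeIndex(s.index),
                                 s.to_numpy(), tz_offset_min)
        out[(pid, hemi)] = series.to_regular_grid() if regular_grid else series
    return out


# ---------------------------------------------------------------------------
# conditioning

def _nan_runs(mask: np.ndarray):
    """Yield (start, stop) of each run of True in ``mask`` (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.r_[False, mask, False]))
    return list(zip(idx[::2], idx[1::2]))


def replace_outliers(series: AmplitudeSeries, k: float = 30.0,
                     two_sided: bool = False) -> tuple[AmplitudeSeries, int]:
    """Replace extreme samples per continuous chunk by PCHIP interpolation.

    A sample is an outlier when its value exceeds ``median + k·SD`` of its
    chunk (chunk = maximal run of consecutive non-missing samples); with
    ``two_sided`` the symmetric low threshold is applied too.  Chunks
    shorter than four samples are left untouched with a warning.
    """
    v = series.values.copy()
    n_replaced = 0
    for start, stop in _nan_runs(np.isfinite(v)):
        chunk = v[start:stop]
        if len(chunk) < 4:
            warnings.warn(f"chunk of length {len(chunk)} too short to condition")
            continue
        med = np.median(chunk)
        sd = np.std(chunk, ddof=1)
        if sd == 0:
            continue
        mask = chunk > med + k * sd
        if two_sided:
            mask |= chunk < med - k * sd
        if not mask.any() or mask.all():
            continue
        x = np.flatnonzero(~mask)
        interp = PchipInterpolator(x, chunk[x], extrapolate=True)
        bad = np.flatnonzero(mask)
        chunk[bad] = interp(bad)
        v[start:stop] = chunk
        n_replaced += len(bad)
    out = AmplitudeSeries(series.patient_id, series.hemisphere, series.timestamps,
                          v, series.tz_offset_min, series.band_center_hz)
    return out, n_replaced


def interpolate_gaps(series: AmplitudeSeries, max_gap: int = 6
                     ) -> tuple[AmplitudeSeries, int, float]:
    """Fill missing runs of at most ``max_gap`` samples by PCHIP.

    Longer runs and edge gaps (no flanking data on one side) stay NaN.
    Returns (series, number of samples filled, mean filled-run length).
    """
    v = series.values.copy()
    finite = np.isfinite(v)
    if finite.sum() < 2:
        return series, 0, float("nan")
    x = np.flatnonzero(finite)
    interp = PchipInterpolator(x, v[x], extrapolate=False)
    run_lengths = []
    for start, stop in _nan_runs(~finite):
        length = stop - start
        if length > max_gap:
            continue
        if start == 0 or stop == len(v):  # edge gap: no flanking data
            continue
        v[start:stop] = interp(np.arange(start, stop))
        run_lengths.append(length)
    out = AmplitudeSeries(series.patient_id, series.hemisphere, series.timestamps,
                          v, series.tz_offset_min, series.band_center_hz)
    n_filled = int(sum(run_lengths))
    mean_len = float(np.mean(run_lengths)) if run_lengths else float("nan")
    return out, n_filled, mean_len


def condition_series(series: AmplitudeSeries, k: float = 30.0, max_gap: int = 6,
                     two_sided: bool = False) -> tuple[AmplitudeSeries, ConditioningReport]:
    """Outlier replacement followed by short-gap interpolation."""
    series = series.to_regular_grid()
    conditioned, n_out = replace_outliers(series, k=k, two_sided=two_sided)
    conditioned, n_interp, mean_len = interpolate_gaps(conditioned, max_gap=max_gap)
    report = ConditioningReport(
        n_samples=len(series),
        n_outliers_replaced=n_out,
        n_interpolated=n_interp,
        mean_interp_run_length=mean_len,
    )
    return conditioned, report


# ---------------------------------------------------------------------------
# daily binning and z-scoring

def bin_daily(series: AmplitudeSeries, activation_date) -> DailyMatrix:
    """Reshape a chronological series into a days × 144 local-clock matrix.

    Day indices are relative to the local calendar date of DBS activation
    (activation date itself = day 0).  A sample at local time h:mm maps to
    bin ``floor((60h+mm)/10)``; if two samples land in one bin the later one
    is kept with a warning.
    """
    activation = pd.Timestamp(activation_date).normalize()
    ts = series.timestamps
    day_idx = (ts.normalize() - activation).days.astype(int)
    bin_idx = (ts.hour * 60 + ts.minute) // SAMPLE_MINUTES
    days = np.arange(day_idx.min(), day_idx.max() + 1)
    values = np.full((len(days), BINS_PER_DAY), np.nan)
    rows = day_idx - days[0]
    flat = rows * BINS_PER_DAY + np.asarray(bin_idx)
    if len(np.unique(flat)) < len(flat):
        warnings.warn("multiple samples mapped to one daily bin; keeping later")
    # chronological order means later samples overwrite earlier ones
    values[rows, bin_idx] = series.values
    return DailyMatrix(days, values, zscored=False,
                       patient_id=series.patient_id, hemisphere=series.hemisphere)


def zscore_daily(matrix: DailyMatrix, min_bins: int = 72) -> DailyMatrix:
    """Z-score each day with its own mean and SD over non-missing bins.

    Days with fewer than ``min_bins`` non-missing bins or zero SD become
    all-missing.
    """
    if matrix.zscored:
        raise ValueError("matrix is already z-scored")
    v = matrix.values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        counts = np.isfinite(v).sum(axis=1)
        means = np.nanmean(np.where(np.isfinite(v), v, np.nan), axis=1)
        sds = np.nanstd(v, axis=1, ddof=0)
    bad = (counts < min_bins) | (sds == 0) | ~np.isfinite(sds)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (v - means[:, None]) / sds[:, None]
    v[bad, :] = np.nan
    return DailyMatrix(matrix.days, v, zscored=True,
                       patient_id=matrix.patient_id, hemisphere=matrix.hemisphere)


# ---------------------------------------------------------------------------
# PSD of raw time-domain snippets (band selection)

def welch_psd(samples: np.ndarray, fs: float = 250.0) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with a 1-s Hamming window, 600-ms overlap, 256-point FFT, in dB."""
    samples = np.asarray(samples, dtype=float)
    nperseg = int(fs)  # 1-s window
    if len(samples) < nperseg:
        raise ValueError("segment shorter than one 1-s window")
    freqs, pxx = welch(samples, fs=fs, window=hamming(nperseg),
                       noverlap=int(0.6 * fs), nfft=256)
    return freqs, 10.0 * np.log10(pxx)
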