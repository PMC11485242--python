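"""Synthetic cohort generator.

Emulates the statistical structure of chronic sensing-DBS amplitude streams:
a multicomponent 24-h rhythm, within-day autoregressive noise, slow baseline
drift, a day-boundary-aligned state change at DBS activation (responders:
circadian amplitude shrinks and dispersion grows; non-responders: unchanged),
missing-data gaps and rare extreme outliers.  All randomness flows from a
single integer seed through :class:`numpy.random.SeedSequence`, so every
output is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    BAND_CENTER_HZ,
    BAND_HALFWIDTH_HZ,
    BINS_PER_DAY,
    PERSISTENT,
    PRE_DBS,
    RESPONSE,
    AmplitudeSeries,
    ClinicalTrajectory,
    StateInterval,
)


@dataclass
class PatientSimParams:
    """Generating parameters for one synthetic patient.

    The daily rhythm is ``mesor + Σ_j circadian_amps[j]·cos(2πj·t/24 −
    acrophases[j])`` (µVp, t in hours); AR noise with coefficients
    ``ar_coeffs`` is generated in z-units and scaled by ``noise_sd``; a
    linear baseline drift of ``drift_per_day`` µVp/day is added.  After DBS
    activation the circadian amplitudes are multiplied by
    ``responder_amp_factor`` and the noise scale by
    ``responder_noise_factor`` iff the patient is a responder.
    """

    patient_id: str
    responder: bool
    n_components: int = 2
    mesor: float = 50.0
    circadian_amps: tuple[float, ...] = (20.0, 8.0)
    acrophases: tuple[float, ...] = (0.0, 0.8)
    ar_coeffs: tuple[float, ...] = (0.55, 0.2)
    noise_sd: float = 6.0
    responder_amp_factor: float = 0.25
    responder_noise_factor: float = 1.5
    drift_per_day: float = 0.1
    pre_days: int = 30
    post_days: int = 90
    tz_offset_min: int = -360

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if len(self.circadian_amps) != self.n_components:
            raise ValueError("circadian_amps must have length n_components")
        if len(self.acrophases) != self.n_components:
            raise ValueError("acrophases must have length n_components")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.pre_days < 0 or self.post_days < 0:
            raise ValueError("day counts must be >= 0")
        if self.pre_days + self.post_days == 0:
            raise ValueError("total duration must be positive")
        _check_stationary(self.ar_coeffs)


def _check_stationary(ar_coeffs) -> None:
    """Raise if the AR characteristic roots are not inside the unit circle."""
    if len(ar_coeffs) == 0:
        return
    roots = np.roots(np.r_[1.0, -np.asarray(ar_coeffs, dtype=float)])
    if np.any(np.abs(roots) >= 1.0):
        raise ValueError("AR coefficients imply a non-stationary process")


@dataclass
class ArtifactSpec:
    """Rates for injected data-loss gaps and extreme outliers.

    ``outlier_magnitude`` is in multiples of the global SD above the global
    median and must exceed the 30-SD conditioning threshold so that injected
    outliers are detectable.  One long gap (``long_gap_len`` > 6 samples) is
    always injected when gaps are enabled, to exercise the NaN path.
    """

    gap_rate: float = 2.0            # expected short gaps per 30 days
    gap_mean_len: float = 2.0        # geometric mean gap length, samples
    long_gap_len: int = 8            # always-injected long gap (> 6 samples)
    outlier_rate: float = 3.0        # expected outliers per 10,000 samples
    outlier_magnitude: float = 35.0  # SD multiples above the global median

    def __post_init__(self) -> None:
        if self.gap_rate < 0 or self.outlier_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.outlier_rate > 0 and self.outlier_magnitude <= 30:
            raise ValueError("outlier_magnitude must exceed 30 SD")

    @classmethod
    def none(cls) -> "ArtifactSpec":
        """No gaps, no outliers (clean generator output)."""
        return cls(gap_rate=0.0, long_gap_len=0, outlier_rate=0.0)


@dataclass
class PatientBundle:
    """One patient: per-hemisphere series and clinical course.

    ``params`` holds the generating parameters for simulated patients and
    is None for cohorts loaded from session files.
    """

    series: dict[str, AmplitudeSeries]
    trajectory: ClinicalTrajectory
    params: PatientSimParams | None = None

    @property
    def patient_id(self) -> str:
        return self.trajectory.patient_id


@dataclass
class CohortConfig:
    """Cohort-level simulation settings."""

    n_patients: int = 8
    n_responders: int = 4
    pre_days: int = 30
    post_days: int = 90
    start_date: str = "2023-03-01"
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    param_overrides: dict = field(default_factory=dict)
    per_patient_days: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("cohort must contain at least one patient")
        if not 0 <= self.n_responders <= self.n_patients:
            raise ValueError("n_responders out of range")


def _ar_noise(rng: np.random.Generator, n: int, ar_coeffs) -> np.ndarray:
    """Unit-innovation AR series in z-units (burn-in discarded)."""
    eps = rng.standard_normal(n + 500)
    if len(ar_coeffs) == 0:
        return eps[500:]
    coeffs = np.asarray(ar_coeffs, dtype=float)
    p = len(coeffs)
    x = np.zeros(n + 500)
    for t in range(p, n + 500):
        x[t] = coeffs @ x[t - p:t][::-1] + eps[t]
    return x[500:]


def _circadian(t_hours: np.ndarray, amps, acros) -> np.ndarray:
    out = np.zeros_like(t_hours)
    for j, (a, phi) in enumerate(zip(amps, acros), start=1):
        out += a * np.cos(2 * np.pi * j * t_hours / 24.0 - phi)
    return out


def simulate_patient(
    params: PatientSimParams,
    artifacts: ArtifactSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    start_date: str | pd.Timestamp = "2023-03-01",
) -> PatientBundle:
    """Simulate both hemispheres of one patient plus the clinical trajectory.

    ``start_date`` is the local calendar date of DBS activation; the series
    starts at local midnight ``pre_days`` before it.  The state change is
    day-boundary aligned: samples on the activation date onwards are
    post-DBS.
    """
    artifacts = artifacts if artifacts is not None else ArtifactSpec()
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    ss_traj, ss_left, ss_right = ss.spawn(3)

    activation = pd.Timestamp(start_date).normalize()
    n = (params.pre_days + params.post_days) * BINS_PER_DAY
    t_hours = np.arange(n) / 6.0
    day = np.arange(n) // BINS_PER_DAY
    post = day >= params.pre_days

    series: dict[str, AmplitudeSeries] = {}
    for hemi, hss in (("L", ss_left), ("R", ss_right)):
        rng = np.random.default_rng(hss)
        amp_factor = np.where(post, params.responder_amp_factor if params.responder else 1.0, 1.0)
        noise_factor = np.where(post, params.responder_noise_factor if params.responder else 1.0, 1.0)
        # small per-hemisphere acrophase jitter keeps hemispheres distinct
        acros = np.asarray(params.acrophases) + rng.normal(0, 0.1, params.n_components)
        circ = _circadian(t_hours, params.circadian_amps, acros)
        y = (params.mesor
             + amp_factor * circ
             + params.drift_per_day * t_hours / 24.0
             + params.noise_sd * noise_factor * _ar_noise(rng, n, params.ar_coeffs))
        y = _inject_artifacts(y, artifacts, rng, params.pre_days)
        timestamps = pd.date_range(
            activation - pd.Timedelta(days=params.pre_days), periods=n, freq="10min")
        series[hemi] = AmplitudeSeries(params.patient_id, hemi, timestamps, y,
                                       params.tz_offset_min)

    trajectory = _make_trajectory(params, np.random.default_rng(ss_traj), activation)
    return PatientBundle(params=params, series=series, trajectory=trajectory)


def _inject_artifacts(y: np.ndarray, spec: ArtifactSpec,
                      rng: np.random.Generator, pre_days: int) -> np.ndarray:
    y = y.copy()
    n = len(y)
    if spec.outlier_rate > 0:
        k = rng.poisson(spec.outlier_rate * n / 10_000)
        if k > 0:
            pos = rng.choice(n, size=min(k, n), replace=False)
            med, sd = np.median(y), np.std(y)
            y[pos] = med + spec.outlier_magnitude * sd
    if spec.gap_rate > 0 or spec.long_gap_len > 0:
        days_total = n / BINS_PER_DAY
        k = rng.poisson(spec.gap_rate * days_total / 30.0)
        for _ in range(k):
            length = min(rng.geometric(1.0 / spec.gap_mean_len), 6)
            start = rng.integers(0, max(n - length, 1))
            y[start:start + length] = np.nan
        if spec.long_gap_len > 0 and n > spec.long_gap_len:
            # deterministic placement mid-way through the pre-DBS period
            start = max(pre_days // 2, 0) * BINS_PER_DAY + BINS_PER_DAY // 2
            start = min(start, n - spec.long_gap_len)
            y[start:start + spec.long_gap_len] = np.nan
    return y


def _make_trajectory(params: PatientSimParams, rng: np.random.Generator,
                     activation: pd.Timestamp) -> ClinicalTrajectory:
    initial = int(rng.integers(28, 39))
    if params.responder:
        reduction = rng.uniform(0.45, 0.75)
    else:
        reduction = rng.uniform(0.0, 0.20)
    final = int(round(initial * (1.0 - reduction)))
    # keep the >=35% criterion consistent with the flag after rounding
    if params.responder and 100.0 * (initial - final) / initial < 35.0:
        final = int(np.floor(initial * 0.6))
    if not params.responder and 100.0 * (initial - final) / initial >= 35.0:
        final = int(np.ceil(initial * 0.75))

    intervals = []
    if params.pre_days > 0:
        intervals.append(StateInterval(PRE_DBS, -params.pre_days, -1))
    if params.post_days > 0:
        post_state = RESPONSE if params.responder else PERSISTENT
        intervals.append(StateInterval(post_state, 0, params.post_days - 1))
    return ClinicalTrajectory(
        patient_id=params.patient_id,
        responder=params.responder,
        ybocs_initial=initial,
        ybocs_final=final,
        dbs_activation_date=activation,
        intervals=intervals,
    )


def simulate_cohort(config: CohortConfig, seed: int = 0) -> list[PatientBundle]:
    """Simulate a cohort; per-patient seeds are spawned from ``seed``.

    Responders are the first ``n_responders`` patient ids.  Output is
    deterministic for a fixed seed.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(config.n_patients)
    bundles = []
    for i in range(config.n_patients):
        pre, post = config.pre_days, config.post_days
        if config.per_patient_days is not None:
            pre, post = config.per_patient_days[i]
        params = PatientSimParams(
            patient_id=f"S{i + 1:03d}",
            responder=i < config.n_responders,
            pre_days=pre,
            post_days=post,
            **config.param_overrides,
        )
        bundles.append(simulate_patient(params, config.artifacts, children[i],
                                        config.start_date))
    return bundles


# ---------------------------------------------------------------------------
# session-file output (device-export schema)

def _to_utc(ts: pd.DatetimeIndex, tz_offset_min: int) -> pd.DatetimeIndex:
    return ts - pd.Timedelta(minutes=tz_offset_min)


def write_session_files(bundle: PatientBundle, directory, n_files: int = 1,
                        overlap: int = 0, fmt: str = "json") -> list[str]:
    """Write each hemisphere's series as device-style session files.

    JSON schema: ``{patient_id, hemisphere, band_center_hz, band_halfwidth_hz,
    samples: [[ISO-8601 UTC timestamp, amplitude_uvp], ...]}``; missing
    samples are omitted (the device logs nothing during a loss).  With
    ``n_files > 1`` the series is split into chunks, optionally with
    ``overlap`` duplicated edge samples, emulating repeated clinic exports.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for hemi, s in bundle.series.items():
        finite = np.isfinite(s.values)
        utc = _to_utc(s.timestamps, s.tz_offset_min)
        stamps = utc[finite]
        vals = s.values[finite]
        bounds = np.linspace(0, len(vals), n_files + 1).astype(int)
        for i in range(n_files):
            lo = max(bounds[i] - (overlap if i > 0 else 0), 0)
            hi = min(bounds[i + 1] + (overlap if i < n_files - 1 else 0), len(vals))
            path = directory / f"{bundle.patient_id}_{hemi}_session{i:02d}.{fmt}"
            if fmt == "json":
                payload = {
                    "patient_id": bundle.patient_id,
                    "hemisphere": hemi,
                    "band_center_hz": BAND_CENTER_HZ,
                    "band_halfwidth_hz": BAND_HALFWIDTH_HZ,
                    "samples": [
                        [stamps[j].strftime("%Y-%m-%dT%H:%M:%SZ"), float(vals[j])]
                        for j in range(lo, hi)
                    ],
                }
                try:
                    path.write_text(json.dumps(payload))
                except OSError as exc:
                    raise OSError(f"failed writing session file {path}: {exc}") from exc
            elif fmt == "csv":
                df = pd.DataFrame({
                    "timestamp": [stamps[j].strftime("%Y-%m-%dT%H:%M:%SZ")
                                  for j in range(lo, hi)],
                    "hemisphere": hemi,
                    "amplitude": vals[lo:hi],
                })
                # patient id is carried in the filename for the CSV variant
                df.to_csv(path, index=False)
            else:
                raise ValueError(f"unknown session format {fmt!r}")
            written.append(str(path))
    return written


def write_clinical_files(bundles: list[PatientBundle], directory) -> tuple[str, str]:
    """Write cohort clinical metadata and state-interval CSVs."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_rows, interval_rows = [], []
    for b in bundles:
        t = b.trajectory
        meta_rows.append({
            "patient_id": t.patient_id,
            "responder": t.responder,
            "ybocs_initial": t.ybocs_initial,
            "ybocs_final": t.ybocs_final,
            "dbs_activation_date": t.dbs_activation_date.date().isoformat(),
            "tz_offset_min": b.series["L"].tz_offset_min if "L" in b.series else 0,
        })
        for iv in t.intervals:
            interval_rows.append({
                "patient_id": t.patient_id, "state": iv.state,
                "start_day": iv.start_day, "end_day": iv.end_day,
            })
    meta_path = directory / "clinical_meta.csv"
    intervals_path = directory / "state_intervals.csv"
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False)
    pd.DataFrame(interval_rows).to_csv(intervals_path, index=False)
    return str(meta_path), str(intervals_path)


def make_test_sine(freq_hz: float, duration_s: float, fs: float = 250.0,
                   amplitude: float = 1.0) -> np.ndarray:
    """Tiny raw time-domain helper (for PSD checks only)."""
    t = np.arange(int(duration_s * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t)
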