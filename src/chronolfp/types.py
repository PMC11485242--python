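"""Core in-memory containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: nominal device logging interval
SAMPLE_MINUTES = 10
#: samples logged per calendar day
BINS_PER_DAY = 24 * 60 // SAMPLE_MINUTES  # 144
#: sensing band centre used throughout (theta/alpha border, "9 Hz")
BAND_CENTER_HZ = 8.79
BAND_HALFWIDTH_HZ = 2.5

#: clinical state labels
PRE_DBS = "severe_symptoms_preDBS"
RESPONSE = "clinical_response"
PERSISTENT = "persistent_symptoms"
DISINHIBITED = "disinhibited"
UNLABELED = "unlabeled"
STATES = (PRE_DBS, RESPONSE, PERSISTENT, DISINHIBITED, UNLABELED)

#: dichotomy used by the pooled statistics and the classifier
BURDENED = "burdened"      # pre-DBS days plus post-DBS non-responder days
UNBURDENED = "unburdened"  # post-DBS responder (clinical response) days


@dataclass
class AmplitudeSeries:
    """A 10-min-sampled band-amplitude stream for one patient hemisphere.

    ``timestamps`` are local-time instants (UTC offset already applied,
    stored tz-naive) on a strictly increasing grid whose spacing is an
    integer multiple of 10 minutes.  ``values`` are amplitudes in µVp with
    NaN marking missing samples.
    """

    patient_id: str
    hemisphere: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    tz_offset_min: int = 0
    band_center_hz: float = BAND_CENTER_HZ

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if len(self.timestamps) > 1:
            deltas = np.diff(self.timestamps.asi8)
            if np.any(deltas <= 0):
                raise ValueError("timestamps must be strictly increasing")
            step = SAMPLE_MINUTES * 60 * 10**9
            if np.any(deltas % step != 0):
                raise ValueError("timestamp spacing must be a multiple of 10 min")

    def __len__(self) -> int:
        return len(self.values)

    def to_regular_grid(self) -> "AmplitudeSeries":
        """Return a copy on the full 10-min grid, gaps filled with NaN."""
        if len(self) == 0:
            return self
        grid = pd.date_range(self.timestamps[0], self.timestamps[-1],
                             freq=f"{SAMPLE_MINUTES}min")
        values = pd.Series(self.values, index=self.timestamps).reindex(grid)
        return AmplitudeSeries(self.patient_id, self.hemisphere, grid,
                               values.to_numpy(), self.tz_offset_min,
                               self.band_center_hz)


@dataclass
class DailyMatrix:
    """Days × 144 matrix of amplitudes aligned to local clock time.

    ``days`` are calendar-day indices relative to DBS activation
    (negative = pre-DBS; activation day itself is day 0).  Column ``b``
    covers local clock time ``[10·b, 10·(b+1))`` minutes.
    """

    days: np.ndarray
    values: np.ndarray
    zscored: bool = False
    patient_id: str = ""
    hemisphere: str = ""

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != BINS_PER_DAY:
            raise ValueError(f"values must have {BINS_PER_DAY} columns")
        if len(self.days) != self.values.shape[0]:
            raise ValueError("days and value rows must match")

    @property
    def n_days(self) -> int:
        return len(self.days)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.days)


@dataclass
class StateInterval:
    """Inclusive day interval (relative to DBS activation) with one clinical state."""

    state: str
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.end_day < self.start_day:
            raise ValueError("end_day precedes start_day")
        if self.state == PRE_DBS and self.end_day >= 0:
            raise ValueError("pre-DBS intervals must lie at days < 0")


@dataclass
class ClinicalTrajectory:
    """Per-patient clinical course: scores, activation date, state intervals."""

    patient_id: str
    responder: bool
    ybocs_initial: int
    ybocs_final: int
    dbs_activation_date: pd.Timestamp
    intervals: list[StateInterval] = field(default_factory=list)
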