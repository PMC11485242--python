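"""Sample entropy of single-day z-scored amplitude profiles.

Sample entropy = −ln(A/B), where B counts unique pairs of distinct
length-m windows whose Manhattan distance is strictly below the tolerance
r, and A counts the same for length-(m+1) windows.  Low values indicate a
regular, predictable day; analysis defaults are m = 2, r = 3.6 (z-units)
and subsampling τ = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist

from .types import DailyMatrix


@dataclass
class EntropyParams:
    """m: template length; r: Manhattan tolerance (z-units); tau: subsampling."""

    m: int = 2
    r: float = 3.6
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")


def _pair_count(x: np.ndarray, length: int, r: float) -> int:
    windows = sliding_window_view(x, length)
    if len(windows) < 2:
        return 0
    d = pdist(windows, metric="cityblock")
    return int(np.count_nonzero(d < r))


def sample_entropy(x: np.ndarray, params: EntropyParams | None = None) -> float:
    """−ln(A/B) over unique pairs of distinct windows (strict d < r).

    Returns ``inf`` with a warning when no (m+1)-window pair matches
    (A = 0, entropy undefined/unbounded).  Missing values are the caller's
    responsibility: complete vectors only.
    """
    params = params or EntropyParams()
    x = np.asarray(x, dtype=float).reshape(-1)[::params.tau]
    if len(x) <= params.m + 1:
        raise ValueError(f"series too short for m={params.m}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains missing values; supply complete days")
    b = _pair_count(x, params.m, params.r)
    a = _pair_count(x, params.m + 1, params.r)
    if a == 0 or b == 0:
        warnings.warn("no matching window pairs; sample entropy undefined")
        return float("inf")
    return float(-np.log(a / b))


def daily_sample_entropy(matrix: DailyMatrix, params: EntropyParams | None = None,
                         min_bins: int = 72) -> pd.DataFrame:
    """Per-day sample entropy of a z-scored daily matrix.

    Days with fewer than ``min_bins`` non-missing bins are missing; within
    usable days, missing bins are dropped and the remainder concatenated
    before windowing (windows may span a dropped bin).  Non-finite entropy
    values (no matching pairs) are reported as missing.
    """
    if not matrix.zscored:
        raise ValueError("daily sample entropy expects a z-scored matrix")
    params = params or EntropyParams()
    rows = []
    for day, row in zip(matrix.days, matrix.values):
        vals = row[np.isfinite(row)]
        if len(vals) < min_bins:
            rows.append((int(day), np.nan))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            value = sample_entropy(vals, params)
        rows.append((int(day), value if np.isfinite(value) else np.nan))
    return pd.DataFrame(rows, columns=["day", "value"])
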