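"""Beat-to-IBI pipeline: interval extraction, artifact correction, 4 Hz resampling.

The stages mirror standard heart-rate-variability preprocessing: detected
R-peak times are differenced into interbeat intervals (IBI, ms), aberrant
intervals are either corrected by local interpolation (short runs) or declared
missing (runs worth three or more beats), and the cleaned series is cubic-spline
interpolated onto a uniform 4 Hz grid.  Missing stretches of at least 10 s are
excluded from the resampled signal rather than bridged, because spline
imputation over long gaps is unreliable; shorter gaps are bridged and kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import UnusableRecordError

__all__ = [
    "BeatSeries",
    "IBISeries",
    "UniformIBISeries",
    "beats_to_ibi",
    "flag_and_correct",
    "interpolate_4hz",
    "DEFAULT_PHYSIO_BOUNDS_MS",
    "DEFAULT_JUMP_FRACTION",
    "MISSING_MASK_MIN_S",
]

#: Physiologically plausible IBI range (ms); outside counts as artifact.
DEFAULT_PHYSIO_BOUNDS_MS = (300.0, 1500.0)
#: Maximum tolerated relative change versus the previous accepted interval.
DEFAULT_JUMP_FRACTION = 0.25
#: Missing stretches at least this long (s) are masked, not spline-bridged.
MISSING_MASK_MIN_S = 10.0
#: Beats-needing-correction threshold at which a run becomes missing data.
MISSING_RUN_BEATS = 3


@dataclass(frozen=True)
class BeatSeries:
    """Ordered heartbeat (R-peak) event times in seconds from task start."""

    times: np.ndarray
    annotations: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("beat times must be one-dimensional")
        if t.size and t[0] < 0:
            raise ValueError("beat times must be non-negative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("beat times must be strictly increasing")
        if self.annotations is not None and len(self.annotations) != t.size:
            raise ValueError("annotations must align with beat times")

    @property
    def n_beats(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return float(self.times[-1]) if self.times.size else 0.0


@dataclass(frozen=True)
class IBISeries:
    """Interbeat intervals; ``times`` is each interval's terminating beat (s)."""

    times: np.ndarray
    ibi: np.ndarray
    missing_segments: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.ibi, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ibi", v)
        object.__setattr__(
            self, "missing_segments", _normalize_segments(self.missing_segments)
        )
        if t.shape != v.shape:
            raise ValueError("times and ibi must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("interval times must be strictly increasing")
        if v.size and not np.all(v > 0):
            raise ValueError("interbeat intervals must be positive")

    @property
    def n_intervals(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class UniformIBISeries:
    """Evenly sampled IBI signal (ms) with a per-sample validity mask.

    Sample ``k`` sits at ``start_time + k / rate``; the grid covers the task
    interval half-open, so ``len(values) == ceil(duration * rate)``.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    rate: float = 4.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.valid_mask, dtype=bool)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "valid_mask", m)
        if v.shape != m.shape or v.ndim != 1:
            raise ValueError("values and valid_mask must be equal-length 1-D arrays")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return self.values.size / self.rate


def _normalize_segments(
    segments: Sequence[tuple[float, float]],
) -> tuple[tuple[float, float], ...]:
    """Sort half-open segments and merge overlaps; reject empty intervals."""
    segs = sorted((float(a), float(b)) for a, b in segments)
    for a, b in segs:
        if not b > a:
            raise ValueError(f"missing segment ({a}, {b}) has non-positive length")
    merged: list[tuple[float, float]] = []
    for a, b in segs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return tuple(merged)


def beats_to_ibi(beats: BeatSeries) -> IBISeries:
    """Difference beat times into interbeat intervals in milliseconds."""
    if beats.n_beats < 2:
        raise UnusableRecordError(
            f"need at least 2 beats to form an interval, got {beats.n_beats}"
        )
    ibi_ms = np.diff(beats.times) * 1000.0
    return IBISeries(times=beats.times[1:], ibi=ibi_ms)


def _implied_beat_count(ibi_ms: float, reference_ms: float) -> int:
    """Number of beats an aberrant interval is 'worth'.

    A long interval spanning k reference beats implies k-1 undetected beats;
    an interval of ordinary length counts as a single beat needing correction.
    """
    return max(1, int(round(ibi_ms / reference_ms)) - 1)


def flag_and_correct(
    ibi: IBISeries,
    physio_bounds: tuple[float, float] = DEFAULT_PHYSIO_BOUNDS_MS,
    jump_fraction: float = DEFAULT_JUMP_FRACTION,
) -> IBISeries:
    """Automated artifact screening of an IBI series.

    An interval needs correction when it falls outside ``physio_bounds`` or
    differs from the preceding accepted interval by more than ``jump_fraction``
    (relative).  Consecutive flagged intervals form a run whose severity is the
    implied number of beats needing correction; runs worth fewer than
    ``MISSING_RUN_BEATS`` beats are repaired by linear interpolation between
    surrounding accepted intervals, while runs worth 3 or more beats are
    removed and recorded as missing segments spanning the affected time range.
    """
    lo, hi = physio_bounds
    if not lo < hi:
        raise ValueError("physio_bounds must satisfy min < max")
    if jump_fraction <= 0:
        raise ValueError("jump_fraction must be positive")

    n = ibi.n_intervals
    if n == 0:
        return ibi

    values = ibi.ibi
    in_bounds = (values >= lo) & (values <= hi)
    reference = float(np.median(values[in_bounds])) if in_bounds.any() else float(hi)

    flagged = np.zeros(n, dtype=bool)
    last_accepted: float | None = None
    for k in range(n):
        bad = not in_bounds[k]
        if not bad and last_accepted is not None:
            bad = abs(values[k] - last_accepted) > jump_fraction * last_accepted
        flagged[k] = bad
        if not bad:
            last_accepted = values[k]

    if not flagged.any():
        return ibi

    keep = np.ones(n, dtype=bool)
    corrected = values.copy()
    new_segments: list[tuple[float, float]] = list(ibi.missing_segments)

    # Walk flagged runs; decide repair vs missing per run severity.
    k = 0
    while k < n:
        if not flagged[k]:
            k += 1
            continue
        j = k
        while j + 1 < n and flagged[j + 1]:
            j += 1
        severity = sum(_implied_beat_count(values[i], reference) for i in range(k, j + 1))
        if severity >= MISSING_RUN_BEATS:
            start = ibi.times[k] - values[k] / 1000.0
            end = ibi.times[j]
            new_segments.append((start, end))
            keep[k : j + 1] = False
        else:
            left = k - 1
            right = j + 1
            left_ok = left >= 0 and not flagged[left]
            right_ok = right < n and not flagged[right]
            for i in range(k, j + 1):
                if left_ok and right_ok:
                    t0, t1 = ibi.times[left], ibi.times[right]
                    w = (ibi.times[i] - t0) / (t1 - t0)
                    corrected[i] = (1 - w) * values[left] + w * values[right]
                elif left_ok:
                    corrected[i] = values[left]
                elif right_ok:
                    corrected[i] = values[right]
                else:  # no accepted neighbour anywhere: drop the run instead
                    keep[k : j + 1] = False
                    start = ibi.times[k] - values[k] / 1000.0
                    new_segments.append((start, ibi.times[j]))
                    break
        k = j + 1

    return IBISeries(
        times=ibi.times[keep],
        ibi=corrected[keep],
        missing_segments=tuple(new_segments),
    )


def interpolate_4hz(
    ibi: IBISeries,
    task_duration: float,
    rate: float = 4.0,
    mask_min_gap_s: float = MISSING_MASK_MIN_S,
    edge_tolerance_s: float = 2.0,
) -> UniformIBISeries:
    """Cubic-spline interpolation of an IBI series onto a uniform grid.

    Samples inside recorded missing segments of duration >= ``mask_min_gap_s``
    (boundary inclusive) are masked invalid; shorter segments are bridged by
    the spline and remain valid.  Samples further than ``edge_tolerance_s``
    outside the observed beat span are masked as unsupported extrapolation.
    """
    if task_duration <= 0:
        raise ValueError("task_duration must be positive")
    if ibi.n_intervals < 4:
        raise UnusableRecordError(
            f"cubic spline needs at least 4 intervals, got {ibi.n_intervals}"
        )
    n_samples = int(np.ceil(task_duration * rate))
    grid = np.arange(n_samples) / rate

    spline = CubicSpline(ibi.times, ibi.ibi)
    values = spline(grid)
    valid = np.ones(n_samples, dtype=bool)

    valid &= grid >= ibi.times[0] - edge_tolerance_s
    valid &= grid <= ibi.times[-1] + edge_tolerance_s
    for start, end in ibi.missing_segments:
        if end - start >= mask_min_gap_s:
            valid &= ~((grid >= start) & (grid < end))

    values = np.where(valid, values, np.nan)
    return UniformIBISeries(values=values, valid_mask=valid, rate=rate, start_time=0.0)
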