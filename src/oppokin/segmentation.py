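"""Onward-movement segmentation from the speed profile.

A trial contains an approach (onward) movement and a return movement; only
the onward part is analysed.  Onset and end are found with a relative speed
threshold: starting at the global speed peak, walk backward until speed first
drops below 5% of the peak (the next sample forward is the onset), and walk
forward until speed first drops below 5% (the last supra-threshold sample is
the end).  Segmented profiles are linearly resampled to 100 points for
profile averaging and display.

Implausible segments (too short, or covering almost none of the trial's
displacement range) trigger an automatic fallback that re-detects the
movement as the longest contiguous supra-threshold run, replacing the manual
rescue that lab practice would apply to the few spurious trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import KinematicSeries

__all__ = [
    "SegmentationConfig",
    "MovementSegment",
    "NoMovementError",
    "find_peak",
    "find_onset",
    "find_end",
    "segment_onward",
    "resample_100",
]


class NoMovementError(ValueError):
    """Raised when the speed profile contains no detectable movement."""


@dataclass(frozen=True)
class SegmentationConfig:
    threshold_frac: float = 0.05  # onset/end threshold as a fraction of peak speed
    min_duration_s: float = 0.1  # fallback gate: minimum plausible movement time
    min_displacement_frac: float = 0.1  # fallback gate: minimum share of rd range


@dataclass
class MovementSegment:
    onset: int
    end: int
    peak: int
    peak_speed: float
    profile_rd: np.ndarray = field(repr=False)
    profile_rv: np.ndarray = field(repr=False)
    fallback: bool = False


def find_peak(rv: np.ndarray) -> int:
    """Index of the global speed maximum (earliest sample on ties)."""
    rv = np.asarray(rv)
    if rv.size == 0:
        raise NoMovementError("empty speed profile")
    return int(np.argmax(rv))


def find_onset(rv: np.ndarray, peak: int, threshold_frac: float = 0.05) -> int:
    """Walk backward from the peak; onset is the sample after the first
    sub-threshold sample.  If speed never drops below threshold before the
    peak, the onset is sample 0."""
    rv = np.asarray(rv, dtype=float)
    if rv.size == 0:
        raise NoMovementError("empty speed profile")
    thr = threshold_frac * rv[peak]
    below = np.nonzero(rv[:peak] < thr)[0]
    return int(below[-1]) + 1 if below.size else 0


def find_end(rv: np.ndarray, peak: int, threshold_frac: float = 0.05) -> int:
    """Walk forward from the peak; end is the last supra-threshold sample
    before speed first drops below threshold.  If it never drops, the end is
    the final sample."""
    rv = np.asarray(rv, dtype=float)
    if rv.size == 0:
        raise NoMovementError("empty speed profile")
    thr = threshold_frac * rv[peak]
    below = np.nonzero(rv[peak + 1 :] < thr)[0]
    return int(peak + below[0]) if below.size else int(rv.size - 1)


def _supra_runs(rv: np.ndarray, thr: float) -> list[tuple[int, int]]:
    """Contiguous [start, stop] runs with rv >= thr (inclusive indices)."""
    above = rv >= thr
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(rv) - 1)
    return list(zip(starts, stops))


def resample_100(profile: np.ndarray, onset: int, end: int, n: int = 100) -> np.ndarray:
    """Linearly interpolate ``profile[onset..end]`` onto ``n`` equally spaced
    points including both endpoints."""
    if end - onset < 2:
        raise ValueError(f"degenerate segment [{onset}, {end}]")
    profile = np.asarray(profile, dtype=float)
    grid = np.linspace(onset, end, n)
    return np.interp(grid, np.arange(profile.size), profile)


def segment_onward(
    series: KinematicSeries, config: SegmentationConfig = SegmentationConfig()
) -> MovementSegment:
    """Detect the onward movement of one effector's speed profile.

    Primary rule: global peak plus backward/forward 5%-of-peak threshold
    crossings.  If the resulting segment is implausibly short in time or in
    displacement, re-detect from the longest contiguous supra-threshold run
    and flag the trial (``fallback=True``).
    """
    rv = np.asarray(series.rv, dtype=float)
    rd = np.asarray(series.rd, dtype=float)
    if rv.size == 0 or np.all(rv == 0.0):
        raise NoMovementError("no movement detected: speed profile is identically zero")

    peak = find_peak(rv)
    onset = find_onset(rv, peak, config.threshold_frac)
    end = find_end(rv, peak, config.threshold_frac)
    fallback = False

    rd_range = float(np.ptp(rd))
    duration = (end - onset) / series.fs
    displacement = abs(rd[end] - rd[onset])
    implausible = duration < config.min_duration_s or (
        rd_range > 0 and displacement < config.min_displacement_frac * rd_range
    )
    if implausible:
        thr = config.threshold_frac * rv[peak]
        runs = _supra_runs(rv, thr)
        if runs:
            start, stop = max(runs, key=lambda r: r[1] - r[0])
            peak = start + int(np.argmax(rv[start : stop + 1]))
            onset, end = start, stop
            fallback = True

    if end - onset < 2:
        raise NoMovementError(
            f"movement segment [{onset}, {end}] too short to analyse"
        )
    return MovementSegment(
        onset=onset,
        end=end,
        peak=peak,
        peak_speed=float(rv[peak]),
        profile_rd=resample_100(rd, onset, end),
        profile_rv=resample_100(rv, onset, end),
        fallback=fallback,
    )
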