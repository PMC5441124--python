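"""Beat-interval pretreatment: singularity removal and beat-to-interval
conversion.

Short-term PRV series extracted from pulse or blood-pressure waveforms
contain occasional implausible intervals (missed or spurious beat
detections, ectopy).  Two rules delete them:

* the first interval is deleted if it lies more than 1.5 standard
  deviations from the series mean (a bad leading detection);
* any later interval is deleted if it jumps more than 30% above or
  below the previous *retained* interval.

The standard deviation is the population form (divide by N); the rules
use strict inequalities.  Referencing the previous retained datum in
the second rule keeps a single ectopic beat from cascading into a run
of deletions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .core import IntervalSeries, as_intervals

__all__ = [
    "FIRST_DATUM_STD_FACTOR",
    "JUMP_UPPER",
    "JUMP_LOWER",
    "BeatLocations",
    "beats_to_prv",
    "remove_singularities",
    "detect_beats_naive",
]

#: First-datum rule: delete PP(1) iff |PP(1) - mean| > this factor * std.
FIRST_DATUM_STD_FACTOR = 1.5
#: Jump rule: delete PP(i) iff PP(i) > JUMP_UPPER * previous retained
#: or PP(i) < JUMP_LOWER * previous retained.
JUMP_UPPER = 1.3
JUMP_LOWER = 0.7


@dataclass(frozen=True)
class BeatLocations:
    """Sample indices of detected beats in a waveform sampled at ``fs`` Hz."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.size >= 2 and not np.all(np.diff(idx) > 0):
            raise ValueError("beat locations must be strictly increasing")
        if not (self.fs > 0):
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)


def beats_to_prv(beats: BeatLocations) -> IntervalSeries:
    """First-order difference of beat locations, in milliseconds.

    ``interval[i] = (indices[i+1] - indices[i]) / fs * 1000``.
    """
    if len(beats) < 2:
        raise ValueError("need at least two beat locations to form intervals")
    intervals_ms = np.diff(beats.indices) / beats.fs * 1000.0
    return IntervalSeries(intervals_ms, units="ms")


def remove_singularities(series):
    """Delete singular intervals; return (cleaned series, deleted positions).

    Deleted positions are reported 1-based, matching the PP(1)..PP(N)
    convention of the input series.  The first-datum rule uses the mean
    and (population) standard deviation of the *whole input* series and
    is applied once, not re-applied to the new first datum.  The jump
    rule scans positions 2..N against the most recent retained datum.
    """
    values = as_intervals(series).values
    units = as_intervals(series).units
    if values.size == 0:
        raise ValueError("cannot pretreat an empty series")
    if values.size < 2:
        return IntervalSeries(values.copy(), units=units), []

    removed: list[int] = []
    mean = float(np.mean(values))
    std = float(np.std(values))  # population convention
    keep_first = abs(values[0] - mean) <= FIRST_DATUM_STD_FACTOR * std

    kept: list[float] = []
    if keep_first:
        kept.append(float(values[0]))
    else:
        removed.append(1)

    for i in range(1, values.size):
        x = float(values[i])
        if kept:
            ref = kept[-1]
            if x > JUMP_UPPER * ref or x < JUMP_LOWER * ref:
                removed.append(i + 1)
                continue
        kept.append(x)

    return IntervalSeries(np.asarray(kept), units=units), removed


def detect_beats_naive(waveform, fs: float):
    """Crude local-maximum beat detector for synthetic pulse waveforms.

    A convenience detector only: local maxima above an adaptive
    threshold (rolling median plus a multiple of the global MAD of the
    detrended signal), with a 0.3 s refractory period.  It is a naive
    stand-in suitable for clean synthetic waveforms, not a validated
    pulse-wave calibrator, and real recordings should be segmented with
    a proper fiducial-point detector before analysis.
    """
    x = np.asarray(waveform, dtype=float)
    if not (fs > 0):
        raise ValueError(f"sampling frequency must be positive, got {fs}")
    if x.size < fs:
        raise ValueError("waveform must be at least one second long")
    if np.ptp(x) == 0:
        warnings.warn("flat waveform: no beats detected", stacklevel=2)
        return BeatLocations(np.empty(0, dtype=np.int64), fs=fs)

    baseline = median_filter(x, size=int(2 * fs) | 1, mode="nearest")
    resid = x - baseline
    mad = float(np.median(np.abs(resid - np.median(resid))))
    threshold = baseline + 3.0 * mad
    refractory = max(int(round(0.3 * fs)), 1)
    peaks, _ = find_peaks(x, distance=refractory)
    peaks = peaks[x[peaks] > threshold[peaks]]
    if peaks.size == 0:
        warnings.warn("no beats above adaptive threshold", stacklevel=2)
    return BeatLocations(peaks.astype(np.int64), fs=fs)
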