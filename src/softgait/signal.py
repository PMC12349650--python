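"""Calibration, unit conversion and landing-impact peak detection.

The measurement chain for one 10 m walk:

1. **Calibrate** — while the participant stands still the vertical axis is
   initialized against gravity: an additive offset is applied to the whole
   trace so the standing-window mean equals exactly 1 g. This removes small
   attachment-angle biases.
2. **Detect peaks** — a landing impact is a strict local maximum exceeding
   1.2 g; a refractory interval of 0.3 s between accepted peaks suppresses
   double detections from high-frequency noise. When two candidates fall
   closer than the refractory interval, the larger one is kept
   (amplitude-greedy; ties go to the earlier sample).
3. **Average peak** — the mean retained peak value, after excluding the first
   two and last two steps (gait initiation/termination are not steady-state).

Conversion between g and SI units uses 1 g = 9.81 m/s^2.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .config import G_MS2, MIN_INTERVAL_S, THRESHOLD_G
from .errors import ParameterError, StatisticsError, ValidationError
from .io import AccelTrace

__all__ = [
    "CalibrationResult",
    "PeakSet",
    "ImpactSummary",
    "calibrate",
    "g_to_ms2",
    "ms2_to_g",
    "detect_peaks",
    "average_peak",
]

#: Standing windows with a larger standard deviation than this are rejected.
MAX_STANDING_SD_G = 0.1


@dataclasses.dataclass(frozen=True)
class CalibrationResult:
    """Outcome of standing-still initialization."""

    offset_g: float
    standing_window: tuple[float, float]
    standing_mean_g: float


@dataclasses.dataclass(frozen=True)
class PeakSet:
    """Accepted landing-impact peaks of one trace."""

    indices: np.ndarray
    values_g: np.ndarray
    sample_rate_hz: float
    threshold_g: float = THRESHOLD_G
    min_interval_s: float = MIN_INTERVAL_S

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        val = np.asarray(self.values_g, dtype=float)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "values_g", val)
        if idx.shape != val.shape:
            raise ValidationError("indices and values_g must have equal length")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValidationError("peak indices must be strictly increasing")
        if np.any(val <= self.threshold_g):
            raise ValidationError("all peak values must exceed the threshold")
        min_gap = math.ceil(self.min_interval_s * self.sample_rate_hz)
        if idx.size and np.any(np.diff(idx) < min_gap):
            raise ValidationError(f"peak spacing below refractory gap of {min_gap} samples")

    def __len__(self) -> int:
        return self.indices.size

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.sample_rate_hz


@dataclasses.dataclass(frozen=True)
class ImpactSummary:
    """Average landing-impact peak with the initiation/termination steps excluded."""

    average_peak_g: float
    n_peaks_total: int
    n_peaks_used: int
    excluded_g: np.ndarray  # first two and last two peak values

    @property
    def average_peak_ms2(self) -> float:
        return g_to_ms2(self.average_peak_g)


def g_to_ms2(x_g):
    """Convert acceleration from g to m/s^2 (1 g = 9.81 m/s^2)."""
    return np.multiply(x_g, G_MS2)


def ms2_to_g(x_ms2):
    """Convert acceleration from m/s^2 to g."""
    return np.divide(x_ms2, G_MS2)


def calibrate(trace: AccelTrace,
              standing_window: tuple[float, float]) -> tuple[AccelTrace, CalibrationResult]:
    """Initialize the vertical axis against standing gravity.

    Computes the mean over ``standing_window`` (seconds, relative to trace
    start) and shifts the whole trace so that mean equals 1 g exactly.

    Raises
    ------
    ParameterError
        If the window lies outside the trace or is shorter than 1 s.
    ValidationError
        If the windowed signal is not still (sd > 0.1 g) — e.g. the window
        contains steps.
    """
    start_s, end_s = standing_window
    if end_s - start_s < 1.0:
        raise ParameterError(f"standing window must span >= 1 s, got {end_s - start_s:.3f} s")
    fs = trace.sample_rate_hz
    i0 = int(round((start_s - trace.t0_s) * fs))
    i1 = int(round((end_s - trace.t0_s) * fs))
    if i0 < 0 or i1 > len(trace):
        raise ParameterError(f"standing window [{start_s}, {end_s}] s outside trace")
    window = trace.samples_g[i0:i1]
    sd = float(np.std(window))
    if sd > MAX_STANDING_SD_G:
        raise ValidationError(
            f"standing window not still: sd {sd:.3f} g exceeds {MAX_STANDING_SD_G} g")
    mean = float(np.mean(window))
    offset = 1.0 - mean
    corrected = AccelTrace(trace.samples_g + offset, fs, trace.t0_s)
    return corrected, CalibrationResult(offset_g=offset,
                                        standing_window=(start_s, end_s),
                                        standing_mean_g=mean)


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a flat plateau counts once, at its
    first sample. Endpoints are never maxima."""
    n = x.size
    out = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            # scan the (possibly length-1) plateau starting at i
            j = i
            while j + 1 < n and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=int)


def detect_peaks(trace: AccelTrace,
                 threshold_g: float = THRESHOLD_G,
                 min_interval_s: float = MIN_INTERVAL_S) -> PeakSet:
    """Detect landing-impact peaks in a calibrated trace.

    A candidate is a strict local maximum exceeding ``threshold_g``.
    Candidates are then thinned amplitude-greedily: in order of decreasing
    value (ties: earlier sample first), a candidate is accepted unless it
    lies within ``min_interval_s`` of an already-accepted peak. The accepted
    set therefore has all pairwise gaps >= ceil(min_interval_s * fs) samples.
    """
    fs = trace.sample_rate_hz
    min_gap = math.ceil(min_interval_s * fs)
    if len(trace) <= min_gap:
        raise ParameterError(
            f"trace of {len(trace)} samples shorter than the refractory interval "
            f"({min_gap} samples)")
    x = trace.samples_g
    candidates = _local_maxima(x)
    candidates = candidates[x[candidates] > threshold_g]
    # amplitude-greedy thinning; np.lexsort makes the earlier index win ties
    order = np.lexsort((candidates, -x[candidates]))
    accepted: list[int] = []
    for k in order:
        idx = candidates[k]
        if all(abs(idx - a) >= min_gap for a in accepted):
            accepted.append(idx)
    accepted.sort()
    accepted_arr = np.asarray(accepted, dtype=int)
    return PeakSet(indices=accepted_arr, values_g=x[accepted_arr],
                   sample_rate_hz=fs, threshold_g=threshold_g,
                   min_interval_s=min_interval_s)


def average_peak(peaks: PeakSet) -> ImpactSummary:
    """Mean peak value in g after dropping the first two and last two peaks.

    Raises :class:`StatisticsError` when fewer than five peaks were detected,
    since nothing would remain after the exclusion.
    """
    n = len(peaks)
    if n < 5:
        raise StatisticsError(
            f"insufficient steps: {n} peaks detected but at least 5 are needed "
            f"after excluding the first and last two")
    retained = peaks.values_g[2:n - 2]
    excluded = np.concatenate([peaks.values_g[:2], peaks.values_g[n - 2:]])
    return ImpactSummary(average_peak_g=float(np.mean(retained)),
                         n_peaks_total=n,
                         n_peaks_used=n - 4,
                         excluded_g=excluded)
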