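"""Spatiotemporal gait metrics, raw and speed-normalized.

Because preferred walking speed differs between trials, each metric (except
speed itself) is divided by the trial's walking speed before pre/post
comparison:

* step length (body-height ratio) = (step length cm / height cm) / speed
* step count per minute           = (steps / time_s * 60) / speed
* upward acceleration             = average peak (m/s^2) / speed

The normalized quantities keep the field's customary unit labels even though
they are dimensionally mixed — "m/s^2" on a normalized upward acceleration
denotes the speed-divided value. No rounding happens here; presentation
layers round to 2 decimals.
"""

from __future__ import annotations

import dataclasses

from .errors import ParameterError
from .io import GaitSession
from .signal import ImpactSummary, g_to_ms2

__all__ = ["GaitMetrics", "walking_speed", "step_length_cm", "compute_metrics"]


@dataclasses.dataclass(frozen=True)
class GaitMetrics:
    """Raw and speed-normalized metrics of one 10 m trial."""

    speed_m_s: float
    step_length_cm: float
    step_length_ratio_raw: float      # step length / body height
    steps_per_min_raw: float
    upward_accel_ms2_raw: float       # average landing-impact peak, SI
    step_length_ratio_norm: float     # each raw value / speed
    steps_per_min_norm: float
    upward_accel_norm: float
    n_peaks_detected: int | None = None  # reported alongside, never substituted

    def __post_init__(self) -> None:
        for name in ("speed_m_s", "step_length_cm", "step_length_ratio_raw",
                     "steps_per_min_raw", "upward_accel_ms2_raw"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")


def walking_speed(distance_m: float, time_s: float) -> float:
    """Stopwatch walking speed: distance / time, in m/s."""
    if distance_m <= 0 or time_s <= 0:
        raise ParameterError(f"distance and time must be positive, got "
                             f"{distance_m} m, {time_s} s")
    return distance_m / time_s


def step_length_cm(distance_m: float, step_count: int) -> float:
    """Step length: walked distance (10 m + overshoot) over counted steps, in cm."""
    if step_count < 1:
        raise ParameterError(f"step_count must be >= 1, got {step_count}")
    if distance_m <= 0:
        raise ParameterError(f"distance_m must be positive, got {distance_m}")
    return 100.0 * distance_m / step_count


def compute_metrics(session: GaitSession, impact: ImpactSummary) -> GaitMetrics:
    """Assemble all raw and speed-normalized metrics for one session.

    Step length uses the instructor-recorded metadata step count, not the
    number of detected peaks; the detected count is carried along for QC.
    Upward acceleration is converted to m/s^2 before normalization.
    """
    speed = walking_speed(session.distance_m, session.time_s)
    sl_cm = step_length_cm(session.distance_m, session.step_count)
    sl_ratio = sl_cm / session.height_cm
    spm = session.step_count / session.time_s * 60.0
    accel_ms2 = g_to_ms2(impact.average_peak_g)
    return GaitMetrics(
        speed_m_s=speed,
        step_length_cm=sl_cm,
        step_length_ratio_raw=sl_ratio,
        steps_per_min_raw=spm,
        upward_accel_ms2_raw=accel_ms2,
        step_length_ratio_norm=sl_ratio / speed,
        steps_per_min_norm=spm / speed,
        upward_accel_norm=accel_ms2 / speed,
        n_peaks_detected=impact.n_peaks_total,
    )
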