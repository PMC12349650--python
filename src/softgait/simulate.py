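"""Synthetic gait data with known ground truth.

Two levels of simulation make the whole pipeline testable without any real
recording:

* :func:`generate_trace` builds a single waist-worn vertical-acceleration
  trace: a still standing lead-in at baseline (1 g plus an optional sensor
  bias), then one smooth raised-cosine impulse per step whose amplitude is
  drawn around ``impact_mean_g`` — emulating the landing-impact peaks of
  1.2–2 g seen over a 1 g baseline in real lumbar recordings — plus i.i.d.
  Gaussian noise. The exact event times and noiseless peak values are
  returned as :class:`StepTruth`.
* :func:`generate_cohort` draws a paired pre/post cohort of metric rows with
  a configurable intervention effect: post step length shortened, cadence
  raised (their product leaves walking speed ~unchanged in the median), and
  the normalized landing impact coupled linearly to the normalized
  step-length ratio, which induces the positive correlation between the two
  post/pre change ratios that the pipeline's Spearman stage should recover.

Step counts are integers (a walk quantizes distance into whole steps), so
cohort step lengths carry realistic rounding noise on top of the sampled
distributions. Amplitude draws are clipped at 0.3 g above baseline so every
simulated step clears the 1.2 g detection threshold.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError
from .io import AccelTrace, GaitSession, validate_cohort

__all__ = [
    "WaveformParams",
    "StepTruth",
    "CohortParams",
    "generate_trace",
    "generate_session",
    "generate_cohort",
]

#: Minimum inter-step interval the detector can resolve (refractory), s.
REFRACTORY_S = 0.3
#: Floor on per-step impulse amplitude above baseline, g.
MIN_AMPLITUDE_G = 0.3


@dataclasses.dataclass(frozen=True)
class WaveformParams:
    """Parameters of a single simulated 10 m walk trace.

    ``impact_width_s`` is the half-width of the raised-cosine impulse;
    impulses must not overlap, so twice the width has to stay below the
    inter-step interval implied by the cadence.
    """

    sample_rate_hz: float = 60.0
    standing_duration_s: float = 2.0
    n_steps: int = 15
    cadence_spm: float = 120.0
    impact_mean_g: float = 0.45
    impact_sd_g: float = 0.10
    impact_width_s: float = 0.10
    noise_sd_g: float = 0.02
    baseline_offset_g: float = 0.0
    sensitivity_error_pct: float = 0.0   # per-trace multiplicative gain, +-pct uniform
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ParameterError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if self.standing_duration_s < 1.0:
            raise ParameterError("standing_duration_s must be >= 1 s (calibration window)")
        if self.n_steps < 5:
            raise ParameterError(f"n_steps must be >= 5, got {self.n_steps}")
        if self.step_interval_s <= REFRACTORY_S:
            raise ParameterError(
                f"cadence {self.cadence_spm} spm implies inter-step interval "
                f"{self.step_interval_s:.3f} s <= refractory {REFRACTORY_S} s")
        if self.impact_mean_g <= 0.2:
            raise ParameterError(
                f"impact_mean_g must exceed 0.2 g so peaks clear the 1.2 g "
                f"threshold, got {self.impact_mean_g}")
        if self.impact_sd_g < 0 or self.noise_sd_g < 0:
            raise ParameterError("standard deviations must be >= 0")
        if not 0 < 2 * self.impact_width_s < self.step_interval_s:
            raise ParameterError(
                f"impact_width_s {self.impact_width_s} must be positive and "
                f"below half the inter-step interval {self.step_interval_s:.3f} s")
        if self.sensitivity_error_pct < 0:
            raise ParameterError("sensitivity_error_pct must be >= 0")

    @property
    def step_interval_s(self) -> float:
        return 60.0 / self.cadence_spm


@dataclasses.dataclass(frozen=True)
class StepTruth:
    """Exact simulated heel-strike events, for validating the detector."""

    event_times_s: np.ndarray
    peak_values_g: np.ndarray      # noiseless trace value at each event
    true_step_count: int

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times_s, dtype=float)
        v = np.asarray(self.peak_values_g, dtype=float)
        object.__setattr__(self, "event_times_s", t)
        object.__setattr__(self, "peak_values_g", v)
        if np.any(np.diff(t) <= REFRACTORY_S):
            raise ParameterError("true events closer than the refractory interval")
        if v.size != self.true_step_count or t.size != self.true_step_count:
            raise ParameterError("truth arrays must match true_step_count")


def generate_trace(params: WaveformParams) -> tuple[AccelTrace, StepTruth]:
    """Simulate one vertical-acceleration trace plus its ground truth.

    Event times are snapped to the sample grid so the noiseless trace
    attains exactly ``baseline + amplitude`` at each event sample. The same
    params (same seed) always yield bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate_hz
    interval = params.step_interval_s

    event_times = params.standing_duration_s + interval * (1 + np.arange(params.n_steps))
    event_idx = np.round(event_times * fs).astype(int)
    event_times = event_idx / fs  # snapped

    total_s = event_times[-1] + params.impact_width_s + 0.5
    n = int(np.ceil(total_s * fs)) + 1
    t = np.arange(n) / fs

    baseline = 1.0 + params.baseline_offset_g
    x = np.full(n, baseline)
    amps = rng.normal(params.impact_mean_g, params.impact_sd_g, params.n_steps)
    amps = np.clip(amps, MIN_AMPLITUDE_G, None)
    for te, amp in zip(event_times, amps):
        lo = int(np.ceil((te - params.impact_width_s) * fs))
        hi = int(np.floor((te + params.impact_width_s) * fs))
        sl = slice(max(lo, 0), min(hi, n - 1) + 1)
        x[sl] += amp * 0.5 * (1.0 + np.cos(np.pi * (t[sl] - te) / params.impact_width_s))

    gain = 1.0
    if params.sensitivity_error_pct:
        gain = 1.0 + rng.uniform(-1, 1) * params.sensitivity_error_pct / 100.0
    x *= gain
    truth_values = x[event_idx].copy()
    if params.noise_sd_g:
        x = x + rng.normal(0.0, params.noise_sd_g, n)

    trace = AccelTrace(x, fs)
    truth = StepTruth(event_times_s=event_times, peak_values_g=truth_values,
                      true_step_count=params.n_steps)
    return trace, truth


def generate_session(params: WaveformParams, height_cm: float, distance_m: float,
                     speed_m_s: float, label: str = "pre",
                     participant_id: str = "P000") -> tuple[GaitSession, StepTruth]:
    """Wrap a simulated trace with self-consistent 10 m trial metadata.

    Elapsed time is distance/speed and the step count equals ``n_steps``.
    The trace must span at least the standing lead-in plus the timed walk.
    """
    if distance_m < 10.0:
        raise ParameterError(f"distance_m must be >= 10, got {distance_m}")
    if speed_m_s <= 0:
        raise ParameterError(f"speed_m_s must be positive, got {speed_m_s}")
    trace, truth = generate_trace(params)
    time_s = distance_m / speed_m_s
    if trace.duration_s < params.standing_duration_s + time_s:
        raise ConsistencyError(
            f"trace spans {trace.duration_s:.2f} s but standing "
            f"({params.standing_duration_s:.2f} s) plus walk ({time_s:.2f} s) "
            f"needs more; raise n_steps or cadence to match the walk")
    session = GaitSession(trace=trace, distance_m=distance_m, time_s=time_s,
                          step_count=params.n_steps, height_cm=height_cm,
                          label=label, participant_id=participant_id)
    return session, truth


@dataclasses.dataclass(frozen=True)
class CohortParams:
    """Paired pre/post cohort with a configurable intervention effect.

    Pre-lesson distributions follow a community cohort of older walkers
    (height ~154 +- 7 cm, preferred speed ~1.37 m/s, normalized step-length
    ratio ~0.33). The lesson effect is two per-participant multipliers:
    step length shrinks by ``step_length_multiplier`` and cadence grows by
    ``cadence_multiplier``; walking speed is their product times the pre
    speed, so with the defaults (0.95 x 1.053 ~ 1.0) speed is unchanged in
    the median. Normalized upward acceleration is
    ``accel_intercept + coupling_slope * step_length_ratio_norm + noise``,
    with noise correlated within a participant's pre/post pair.
    """

    n_participants: int = 223
    height_mean_cm: float = 154.4
    height_sd_cm: float = 7.0
    speed_mean_m_s: float = 1.37
    speed_sd_m_s: float = 0.26
    sl_ratio_norm_mean: float = 0.33
    sl_ratio_norm_sd: float = 0.05
    accel_intercept: float = 0.4       # normalized upward accel at zero ratio
    coupling_slope: float = 30.0       # d(accel_norm) / d(step-length ratio norm)
    accel_noise_sd: float = 0.4
    within_pair_correlation: float = 0.7
    step_length_multiplier: float = 0.95
    cadence_multiplier: float = 1.053
    multiplier_sd: float = 0.03        # lognormal sigma of per-participant multipliers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 5:
            raise ParameterError(
                f"n_participants must be >= 5 (paired statistics undefined "
                f"below that), got {self.n_participants}")
        if self.step_length_multiplier <= 0 or self.cadence_multiplier <= 0:
            raise ParameterError("effect multipliers must be positive")
        if self.coupling_slope < 0:
            raise ParameterError("coupling_slope must be >= 0")
        if not 0.0 <= self.within_pair_correlation < 1.0:
            raise ParameterError("within_pair_correlation must lie in [0, 1)")
        for name in ("height_sd_cm", "speed_sd_m_s", "sl_ratio_norm_sd",
                     "accel_noise_sd", "multiplier_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a paired pre/post cohort as a long-format metric table.

    Returns one row per (participant, label) with the session-level fields
    (distance, time, steps, height) and the raw plus speed-normalized
    metrics, exactly the schema the cohort statistics consume.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_participants

    height = np.clip(rng.normal(params.height_mean_cm, params.height_sd_cm, n), 120, 200)
    speed_pre = np.clip(rng.normal(params.speed_mean_m_s, params.speed_sd_m_s, n), 0.6, 2.5)
    sl_norm_target = np.clip(
        rng.normal(params.sl_ratio_norm_mean, params.sl_ratio_norm_sd, n), 0.15, 0.55)

    m_sl = params.step_length_multiplier * np.exp(rng.normal(0, params.multiplier_sd, n))
    m_cad = params.cadence_multiplier * np.exp(rng.normal(0, params.multiplier_sd, n))
    speed_post = speed_pre * m_sl * m_cad

    # impact noise, correlated within the pre/post pair
    rho = params.within_pair_correlation
    shared = rng.normal(0, 1, n)
    eps = {}
    for label in ("pre", "post"):
        own = rng.normal(0, 1, n)
        eps[label] = params.accel_noise_sd * (
            np.sqrt(rho) * shared + np.sqrt(1 - rho) * own)

    sl_target_cm = {
        "pre": sl_norm_target * height * speed_pre,
        "post": sl_norm_target * height * speed_pre * m_sl,
    }
    speeds = {"pre": speed_pre, "post": speed_post}

    rows = []
    for label in ("pre", "post"):
        distance = 10.0 + rng.uniform(0.1, 0.8, n)
        steps = np.maximum(np.round(100.0 * distance / sl_target_cm[label]), 8).astype(int)
        sl_cm = 100.0 * distance / steps
        speed = speeds[label]
        time_s = distance / speed
        sl_ratio_norm = (sl_cm / height) / speed
        spm_norm = (steps / time_s * 60.0) / speed
        accel_norm = (params.accel_intercept
                      + params.coupling_slope * sl_ratio_norm + eps[label])
        accel_norm = np.maximum(accel_norm, 1.0)
        rows.append(pd.DataFrame({
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "label": label,
            "height_cm": height,
            "distance_m": distance,
            "time_s": time_s,
            "step_count": steps,
            "speed_m_s": speed,
            "step_length_cm": sl_cm,
            "step_length_ratio_norm": sl_ratio_norm,
            "steps_per_min_norm": spm_norm,
            "upward_accel_norm": accel_norm,
            "upward_accel_ms2_raw": accel_norm * speed,
        }))
    table = pd.concat(rows, ignore_index=True)
    return validate_cohort(table)
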