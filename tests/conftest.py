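import numpy as np
import pandas as pd
import pytest

from softgait import AccelTrace, CohortParams, WaveformParams, generate_cohort, generate_trace


@pytest.fixture
def clean_params():
    """Noiseless, fixed-amplitude waveform: analytically known peaks."""
    return WaveformParams(n_steps=10, cadence_spm=100.0, impact_mean_g=0.6,
                          impact_sd_g=0.0, noise_sd_g=0.0, seed=0)


@pytest.fixture
def noisy_params():
    return WaveformParams(n_steps=12, cadence_spm=100.0, noise_sd_g=0.02, seed=3)


@pytest.fixture
def calibrated_trace(noisy_params):
    trace, truth = generate_trace(noisy_params)
    return trace, truth


@pytest.fixture
def small_cohort():
    return generate_cohort(CohortParams(n_participants=60, seed=11))


@pytest.fixture
def flat_trace():
    return AccelTrace(np.full(300, 1.0), 60.0)


def make_random_trace(rng, n=240, fs=60.0):
    """Rough trace for oracle comparisons: 1 g baseline, lumpy noise, a few
    injected super-threshold bumps."""
    x = 1.0 + rng.normal(0.0, 0.12, n)
    for _ in range(rng.integers(0, 6)):
        i = int(rng.integers(2, n - 2))
        x[i] += rng.uniform(0.2, 1.0)
    return AccelTrace(x, fs)


def oracle_detect(trace, threshold_g=1.2, min_interval_s=0.3):
    """Independent O(n^2) reference detector: enumerate strict local maxima
    (plateaus count once, at their first sample), drop those at or below the
    threshold, then keep candidates in order of descending amplitude
    (earlier index wins ties) subject to the refractory spacing."""
    import math
    x = trace.samples_g
    n = len(x)
    cands = []
    for i in range(1, n - 1):
        if x[i] <= x[i - 1]:
            continue
        j = i
        while j + 1 < n and x[j + 1] == x[j]:
            j += 1
        if j + 1 < n and x[j + 1] < x[i]:
            cands.append(i)
    cands = [i for i in cands if x[i] > threshold_g]
    gap = math.ceil(min_interval_s * trace.sample_rate_hz)
    chosen: list[int] = []
    for i in sorted(cands, key=lambda i: (-x[i], i)):
        if all(abs(i - c) >= gap for c in chosen):
            chosen.append(i)
    return sorted(chosen)


def make_metric_frame(rng, n, label="pre"):
    """Minimal cohort-schema frame with random but valid metric columns."""
    return pd.DataFrame({
        "participant_id": [f"P{i:03d}" for i in range(n)],
        "label": label,
        "speed_m_s": rng.uniform(1.0, 1.7, n),
        "step_length_ratio_norm": rng.uniform(0.25, 0.45, n),
        "steps_per_min_norm": rng.uniform(70, 110, n),
        "upward_accel_norm": rng.uniform(9, 12, n),
    })
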