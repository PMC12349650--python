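"""Pipeline constants and configuration.

Every fixed constant of the measurement protocol lives here: the landing-impact
peak threshold, the refractory interval between accepted peaks, the sensor
sampling rate, the fixed reference speed used on the participant result sheet,
the g -> m/s^2 conversion factor and the significance level of the statistical
plan.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

#: Standard gravity used for the g <-> m/s^2 conversion.
G_MS2: float = 9.81

#: Peak acceptance threshold for landing-impact detection (g).
THRESHOLD_G: float = 1.2

#: Refractory interval between accepted peaks (s); suppresses double detections.
MIN_INTERVAL_S: float = 0.3

#: Sensor sampling frequency (Hz).
SAMPLE_RATE_HZ: float = 60.0

#: Fixed reference walking speed for the result sheet, 5 km/h in m/s.
FIXED_SPEED_M_S: float = 1.39

#: Two-sided significance level of the statistical plan.
ALPHA: float = 0.05


@dataclasses.dataclass
class PipelineConfig:
    """Run-time configuration for the full pipeline.

    Defaults reproduce the measurement protocol; any field can be overridden
    from a JSON config file or CLI flags.
    """

    threshold_g: float = THRESHOLD_G
    min_interval_s: float = MIN_INTERVAL_S
    sample_rate_hz: float = SAMPLE_RATE_HZ
    fixed_speed_m_s: float = FIXED_SPEED_M_S
    g_ms2: float = G_MS2
    alpha: float = ALPHA
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("threshold_g", "min_interval_s", "sample_rate_hz",
                     "fixed_speed_m_s", "g_ms2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
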