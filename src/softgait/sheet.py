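"""Participant-facing before/after result sheet.

To make two trials walked at different speeds comparable on a single sheet,
the measured average impact (g) is rescaled to a fixed reference speed of
1.39 m/s (5 km/h):

    normalized (g) = measured (g) / walking speed (m/s) * 1.39 m/s

Because a standing body experiences 1 g, the normalized value doubles as a
body-weight multiple: 1.6 g reads as "a load of about 1.6 times your body
weight". Note that multiplying by a fixed speed proportionally rescales any
measurement error as well.

The sheet reports the absolute change in g and the relative change
(before - after) / before; both are exposed, and the wording flags an
increase explicitly rather than phrasing it as an improvement.
"""

from __future__ import annotations

import dataclasses
import json

from .config import FIXED_SPEED_M_S
from .errors import ParameterError
from .metrics import GaitMetrics
from .signal import ms2_to_g

__all__ = ["ResultSheet", "normalize_to_fixed_speed", "render_sheet"]


@dataclasses.dataclass(frozen=True)
class ResultSheet:
    """Fixed-speed-normalized before/after impact feedback."""

    before_norm_g: float
    after_norm_g: float
    fixed_speed_m_s: float
    delta_g: float                    # after - before
    relative_change: float            # (before - after) / before
    rendered_text: str

    @property
    def body_weight_multiple_before(self) -> float:
        """The normalized g value read as a multiple of body weight."""
        return self.before_norm_g

    @property
    def body_weight_multiple_after(self) -> float:
        return self.after_norm_g

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["body_weight_multiple_before"] = self.body_weight_multiple_before
        payload["body_weight_multiple_after"] = self.body_weight_multiple_after
        return json.dumps(payload, indent=2)


def normalize_to_fixed_speed(measured_g: float, speed_m_s: float,
                             fixed_speed_m_s: float = FIXED_SPEED_M_S) -> float:
    """Rescale a measured impact (g) to the fixed reference walking speed."""
    if measured_g <= 0 or speed_m_s <= 0 or fixed_speed_m_s <= 0:
        raise ParameterError(
            f"measured_g, speed and fixed speed must be positive, got "
            f"{measured_g} g at {speed_m_s} m/s (fixed {fixed_speed_m_s})")
    return measured_g / speed_m_s * fixed_speed_m_s


def render_sheet(before: GaitMetrics, after: GaitMetrics,
                 fixed_speed_m_s: float = FIXED_SPEED_M_S) -> ResultSheet:
    """Build the before/after sheet from two sessions' metrics."""
    before_g = normalize_to_fixed_speed(
        ms2_to_g(before.upward_accel_ms2_raw), before.speed_m_s, fixed_speed_m_s)
    after_g = normalize_to_fixed_speed(
        ms2_to_g(after.upward_accel_ms2_raw), after.speed_m_s, fixed_speed_m_s)
    delta = after_g - before_g
    relative = (before_g - after_g) / before_g

    lines = [
        "Landing impact at a fixed walking speed of "
        f"{fixed_speed_m_s:.2f} m/s (5 km/h):",
        f"  Before: {before_g:.2f} g — a load of about {before_g:.1f} times your body weight",
        f"  After:  {after_g:.2f} g — a load of about {after_g:.1f} times your body weight",
        f"  Change: {delta:+.2f} g",
    ]
    if delta < 0:
        lines.append(
            f"  Your landing impact decreased by {100 * relative:.1f}% relative to before.")
    elif delta > 0:
        lines.append("  Your landing impact increased compared with before the lesson.")
    else:
        lines.append("  Your landing impact did not change.")
    return ResultSheet(
        before_norm_g=before_g,
        after_norm_g=after_g,
        fixed_speed_m_s=fixed_speed_m_s,
        delta_g=delta,
        relative_change=relative,
        rendered_text="\n".join(lines),
    )
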