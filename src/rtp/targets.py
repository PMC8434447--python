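"""Deterministic generation of target waveforms and event schedules.

The cyclic-tracking target is a sinusoid: amplitude and frequency are the
configurable quantities, and a sinusoid is the minimal smooth cyclic
waveform, which also makes half-cycle segmentation analytic.  Motor-skill
-game events are sequential and non-overlapping — one object on screen at
a time — each spawning at a uniformly random admissible abscissa on the
top edge and traversing to the paddle line in exactly the configured
event duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .session import MSG, GameEvent, TrialConfig, PADDLE_AXIS_POS, ValidationError

__all__ = [
    "CTWaveform",
    "DIAGONAL_OFFSET",
    "ct_target_position",
    "schedule_msg_events",
    "event_object_position",
]

#: Lateral offset of a diagonal trajectory, normalized units; the sign is
#: drawn per event (clipping at the screen edge may shrink the offset).
DIAGONAL_OFFSET = 0.25

#: Ordinate at which objects spawn (top edge).
SPAWN_POS = 0.0

#: Spawn/arrival abscissae keep this margin from the screen edges, so
#: objects are fully visible and the arrival band stays clear of a
#: paddle idling at its home position on the edge.
SPAWN_MARGIN = 0.1


@dataclass(frozen=True)
class CTWaveform:
    """Sinusoidal cyclic-tracking target.

    position(t) = center + amplitude * sin(2*pi*frequency_hz*t + phase)
    on the configured axis, so |position - center| <= amplitude always.
    The default phase of 0 starts the target at its center.
    """

    amplitude: float
    frequency_hz: float
    axis: str = "horizontal"
    phase: float = 0.0
    center: float = 0.5

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")
        if self.frequency_hz <= 0:
            raise ValidationError("frequency_hz must be > 0")

    @classmethod
    def from_config(cls, config: TrialConfig) -> "CTWaveform":
        return cls(
            amplitude=config.target_amplitude,
            frequency_hz=config.target_frequency_hz,
            axis=config.axis,
        )

    def position(self, t_ms):
        """Vectorized target coordinate at time(s) ``t_ms`` (milliseconds)."""
        t = np.asarray(t_ms, dtype=float) / 1000.0
        return self.center + self.amplitude * np.sin(
            2.0 * math.pi * self.frequency_hz * t + self.phase
        )

    def extrema_times_ms(self, duration_ms: float) -> np.ndarray:
        """Times of all waveform extrema in [0, duration_ms].

        Extrema occur where the sine's argument is pi/2 + k*pi, i.e.
        every half period starting a quarter period after a zero of the
        phase-shifted argument.
        """
        half_period_ms = 1000.0 / (2.0 * self.frequency_hz)
        # first k with t >= 0
        t0 = (math.pi / 2.0 - self.phase) / (2.0 * math.pi * self.frequency_hz) * 1000.0
        k0 = math.ceil(-t0 / half_period_ms - 1e-12)
        ts = t0 + half_period_ms * np.arange(k0, k0 + int(duration_ms / half_period_ms) + 2)
        return ts[(ts >= -1e-9) & (ts <= duration_ms + 1e-9)]


def ct_target_position(waveform: CTWaveform, t_ms) -> float:
    """Target coordinate of ``waveform`` at ``t_ms`` (>= 0) on its axis."""
    if np.any(np.asarray(t_ms) < 0):
        raise ValueError("t_ms must be >= 0")
    pos = waveform.position(t_ms)
    return float(pos) if np.isscalar(t_ms) else pos


def schedule_msg_events(config: TrialConfig) -> list[GameEvent]:
    """Generate the back-to-back event schedule for an MSG trial.

    Exactly ``floor(duration_s / event_duration_s)`` non-overlapping
    events are produced.  Per event, the RNG (seeded by
    ``config.rng_seed``) draws, in a fixed order: the spawn abscissa,
    uniform on the admissible range ``[max(object_radius, SPAWN_MARGIN),
    1 - max(object_radius, SPAWN_MARGIN)]``; a uniform variate
    deciding distractor status against ``distractor_fraction``; and, for
    diagonal trials, the sign of the lateral offset.  The same seed and
    config therefore reproduce the schedule bitwise.
    """
    if config.module_kind != MSG:
        raise ValidationError("schedule_msg_events requires an MSG config")
    if config.event_duration_s > config.duration_s and config.duration_s > 0:
        raise ValidationError(
            f"event_duration_s ({config.event_duration_s}) exceeds trial duration "
            f"({config.duration_s})"
        )
    n_events = int(math.floor(config.duration_s / config.event_duration_s + 1e-9))
    rng = np.random.default_rng(config.rng_seed)
    margin = max(config.object_radius, SPAWN_MARGIN)
    lo, hi = margin, 1.0 - margin
    dur_ms = int(round(config.event_duration_s * 1000))
    events: list[GameEvent] = []
    for i in range(n_events):
        spawn_x = float(rng.uniform(lo, hi))
        kind = "distractor" if rng.random() < config.distractor_fraction else "target"
        if config.trajectory_complexity == "diagonal":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            end_x = float(np.clip(spawn_x + sign * DIAGONAL_OFFSET, lo, hi))
            heading = "diagonal-right" if sign > 0 else "diagonal-left"
        else:
            end_x = spawn_x
            heading = "downward"
        events.append(
            GameEvent(
                event_id=i,
                kind=kind,
                t_appear_ms=i * dur_ms,
                t_disappear_ms=(i + 1) * dur_ms,
                spawn_x=spawn_x,
                heading=heading,
                end_x=end_x,
            )
        )
    return events


def event_object_position(event: GameEvent, config: TrialConfig, t_ms) -> tuple[float, float]:
    """Object (x, y) during ``event`` at time ``t_ms``.

    Linear interpolation from the spawn point on the top edge to the
    arrival point on the paddle axis line; straight headings keep
    ``end_x == spawn_x``, diagonal ones shear laterally.
    """
    if not event.t_appear_ms <= t_ms <= event.t_disappear_ms:
        raise ValueError(
            f"t_ms {t_ms} outside event {event.event_id} window "
            f"[{event.t_appear_ms}, {event.t_disappear_ms}]"
        )
    u = (t_ms - event.t_appear_ms) / event.duration_ms
    x = event.spawn_x + u * (event.end_x - event.spawn_x)
    y = SPAWN_POS + u * (PADDLE_AXIS_POS - SPAWN_POS)
    return float(x), float(y)
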