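"""Synthetic player: generates session logs with controllable impairment.

The player model is deliberately minimal — a pure tracking delay, a gain
on required displacement, additive Gaussian position noise, and a
per-event miss probability — because each parameter maps one-to-one onto
a performance measure (lag -> residual error, gain -> movement
amplitude, noise -> amplitude variation / movement error, miss
probability -> success rate).  That makes every metric testable by
parameter recovery without patient data.

All randomness comes from one ``numpy`` Generator seeded from
``PlayerModel.seed``; no global RNG state is touched, so
(config, player) reproduce a session bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import CT, MSG, SessionLog, TrialConfig, ValidationError
from .targets import CTWaveform, event_object_position, schedule_msg_events

__all__ = ["PlayerModel", "simulate_ct", "simulate_msg", "simulate"]


@dataclass
class PlayerModel:
    """Parameters of the synthetic player.

    Parameters
    ----------
    reaction_time_mean_ms, reaction_time_sd_ms : float
        Appearance-to-movement latency for goal-directed responses,
        drawn Normal(mean, sd) per event, clipped at 0.
    tracking_lag_ms : float
        Pure delay of the pursuit response in CT trials.
    gain : float
        Dimensionless multiplier on the required displacement (1 =
        accurate amplitude, <1 = hypometric).
    noise_sd : float
        SD of additive Gaussian position noise, normalized units.  Also
        used as the endpoint-scatter SD of goal-directed responses.
    miss_prob : float
        Probability that a target event elicits no response.
    max_speed_units_per_s : float
        Speed cap of the minimum-time ramp toward the interception
        point, normalized units per second.  The default (5 u/s, full
        screen in 200 ms) is generous: 5 % of any on-screen distance is
        covered within one 100 Hz sample period, so the detected onset
        lags the programmed reaction time by at most one sample.
    seed : int
        RNG seed for this session.
    """

    reaction_time_mean_ms: float = 300.0
    reaction_time_sd_ms: float = 0.0
    tracking_lag_ms: float = 0.0
    gain: float = 1.0
    noise_sd: float = 0.0
    miss_prob: float = 0.0
    max_speed_units_per_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reaction_time_mean_ms", "reaction_time_sd_ms", "tracking_lag_ms",
                     "gain", "noise_sd", "max_speed_units_per_s"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValidationError("miss_prob must lie in [0, 1]")


def _sample_times_ms(config: TrialConfig) -> np.ndarray:
    return np.arange(config.n_samples, dtype=np.int64) * config.dt_ms


def simulate_ct(config: TrialConfig, player: PlayerModel) -> SessionLog:
    """Simulate a cyclic-tracking trial.

    paddle(t) = center + gain * (target(t - lag) - center) + noise,
    clipped to the unit screen.  Perfect settings (lag 0, gain 1, noise
    0) reproduce the target exactly, so every residual error is zero.
    """
    if config.module_kind != CT:
        raise ValidationError("simulate_ct requires a CT config")
    rng = np.random.default_rng(player.seed)
    t = _sample_times_ms(config)
    wf = CTWaveform.from_config(config)
    target = wf.position(t)
    lagged = wf.position(t.astype(float) - player.tracking_lag_ms)
    paddle = wf.center + player.gain * (lagged - wf.center)
    if player.noise_sd > 0:
        paddle = paddle + rng.normal(0.0, player.noise_sd, size=paddle.shape)
    paddle = np.clip(paddle, 0.0, 1.0)
    if config.axis == "horizontal":
        tx, ty = target, np.full_like(target, 0.5)
    else:
        tx, ty = np.full_like(target, 0.5), target
    samples = pd.DataFrame(
        {
            "t_ms": t,
            "paddle_pos": paddle,
            "target_x": tx,
            "target_y": ty,
            "event_id": pd.array([pd.NA] * len(t), dtype="Int64"),
        }
    )
    return SessionLog(config=config, samples=samples, events=[], participant_id="sim")


def simulate_msg(config: TrialConfig, player: PlayerModel) -> SessionLog:
    """Simulate a motor-skill-game trial.

    Events are scheduled from the config.  The paddle rests at a home
    position on the screen edge (0.0) — outside the arrival band, which
    the spawn margin keeps clear of the edges, so an unresponsive paddle
    never catches anything — and re-homes at each event boundary (an
    idealized between-trials reset that keeps events independent).  For
    each *target* event the player responds with probability
    ``1 - miss_prob``: the paddle holds home until a drawn reaction
    time, then ramps at the capped speed toward
    ``home + gain * (endpoint - home)`` where the endpoint is the
    arrival abscissa plus Gaussian scatter, and holds.  Missed targets
    and distractors leave the paddle at home.  Additive position noise
    is applied to every sample last.

    Per target event the RNG draws, in fixed order, (miss variate,
    reaction time, endpoint scatter) regardless of outcome, so schedules
    under different ``miss_prob`` values share the same draws — success
    rate is then monotone in ``miss_prob`` for a fixed seed.
    """
    if config.module_kind != MSG:
        raise ValidationError("simulate_msg requires an MSG config")
    events = schedule_msg_events(config)
    rng = np.random.default_rng(player.seed)
    t = _sample_times_ms(config)
    paddle = np.empty(len(t), dtype=float)
    tx = np.full(len(t), np.nan)
    ty = np.full(len(t), np.nan)
    eid = np.full(len(t), -1, dtype=np.int64)

    home = 0.0
    v = player.max_speed_units_per_s / 1000.0  # units per ms
    for ev in events:
        sel = (t >= ev.t_appear_ms) & (t < ev.t_disappear_ms)
        idx = np.flatnonzero(sel)
        if ev.kind == "target":
            u_miss = rng.random()
            react = max(0.0, rng.normal(player.reaction_time_mean_ms, player.reaction_time_sd_ms))
            scatter = rng.normal(0.0, player.noise_sd)
            responds = u_miss >= player.miss_prob
        else:
            responds = False
        if responds:
            goal = home + player.gain * ((ev.end_x + scatter) - home)
            goal = float(np.clip(goal, 0.0, 1.0))
            t_start = ev.t_appear_ms + react
            travel = np.clip((t[idx].astype(float) - t_start) * v, 0.0, None)
            paddle[idx] = home + np.sign(goal - home) * np.minimum(travel, abs(goal - home))
        else:
            paddle[idx] = home
        for i in idx:
            ox, oy = event_object_position(ev, config, int(t[i]))
            tx[i], ty[i] = ox, oy
        eid[idx] = ev.event_id
    # samples past the last event (duration not a multiple of event length)
    paddle[eid < 0] = home
    if player.noise_sd > 0:
        paddle = paddle + rng.normal(0.0, player.noise_sd, size=paddle.shape)
    paddle = np.clip(paddle, 0.0, 1.0)

    samples = pd.DataFrame(
        {
            "t_ms": t,
            "paddle_pos": paddle,
            "target_x": tx,
            "target_y": ty,
            "event_id": pd.array([pd.NA if e < 0 else int(e) for e in eid], dtype="Int64"),
        }
    )
    return SessionLog(config=config, samples=samples, events=events, participant_id="sim")


def simulate(config: TrialConfig, player: PlayerModel) -> SessionLog:
    """Dispatch to :func:`simulate_ct` or :func:`simulate_msg`."""
    return simulate_ct(config, player) if config.module_kind == CT else simulate_msg(config, player)
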