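"""Motor-skill-game performance measures.

An MSG trial is segmented into one *game movement response* per event:
the paddle trajectory over the event's appearance-to-disappearance
window.  From each response the module derives

* **movement onset time (MOT)** — latency from object appearance until
  the paddle has covered at least 5 % of the required movement distance,
  sustained for 30 ms (a relative-displacement threshold with debounce,
  robust across sample rates and impaired, jittery kinematics);
* **success** — for a target, whether the paddle overlaps the object at
  its arrival sample (|paddle - end_x| <= paddle_halfwidth +
  object_radius); for a distractor, whether the paddle *avoids* it;
* **movement error (ME)** — mean absolute deviation of the paddle from
  the required interception abscissa over the samples from onset to
  event end;
* **movement time (MT)** — from onset to arrival stabilization, the
  start of the final within-catch-window run that lasts to event end;
* **movement variation** — COV of per-response peak displacement within
  each heading group.

The trial summary aggregates these over events: the success rate (SR)
counts caught targets over *target* events only (distractors never enter
the denominator), and means are taken over responses with a detected
onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .session import MSG, GameEvent, SessionLog, TrialConfig, ValidationError

__all__ = [
    "GameResponse",
    "MSGSummary",
    "segment_responses",
    "movement_onset",
    "judge_success",
    "movement_error",
    "movement_time",
    "msg_summary",
    "ONSET_DISTANCE_FRACTION",
    "ONSET_SUSTAIN_MS",
    "ONSET_MIN_DISTANCE",
]

#: Fraction of the required movement distance that must be covered for
#: movement onset.  Configurable via the ``movement_onset`` arguments.
ONSET_DISTANCE_FRACTION = 0.05

#: Debounce: the displacement must persist at least this long.
ONSET_SUSTAIN_MS = 30.0

#: Absolute floor on the onset threshold, normalized units.  Guards
#: short-distance events, where 5 % of the required distance would sit
#: below the position-noise floor and every sample would "cross" it:
#: 0.04 is about 1.5x the displacement noise SD at a position noise of
#: 0.02 (the roughest motion the detector is specified to handle), yet
#: still below the distance a brisk goal-directed movement covers in a
#: single 100 Hz sample, so latency stays within one sample period.
ONSET_MIN_DISTANCE = 0.04


@dataclass
class GameResponse:
    """One segmented game movement response.

    ``t_ms`` and ``trajectory`` are aligned arrays covering
    ``[t_appear_ms, t_disappear_ms)`` — exactly
    ``event_duration_s * sample_rate_hz`` samples for a conforming log;
    the last sample is the object's arrival sample.  Metric fields are
    ``None``/False until filled by :func:`msg_summary` (or the
    individual metric functions).
    """

    event_id: int
    direction: str
    t_ms: np.ndarray
    trajectory: np.ndarray
    onset_ms: Optional[float] = None
    movement_time_ms: Optional[float] = None
    caught: bool = False
    movement_error: float = float("nan")

    @property
    def t_appear_ms(self) -> int:
        return int(self.t_ms[0])


def segment_responses(log: SessionLog) -> list[GameResponse]:
    """Slice the sample stream into one response per event.

    Samples with ``t_appear_ms <= t < t_disappear_ms`` belong to the
    event; with back-to-back events this yields exactly
    ``event_duration_s * sample_rate_hz`` samples per response.  An
    event whose window holds no samples raises a validation error naming
    the event.
    """
    if log.config.module_kind != MSG:
        raise ValidationError("segment_responses requires an MSG log")
    t = log.samples["t_ms"].to_numpy()
    paddle = log.samples["paddle_pos"].to_numpy(dtype=float)
    expected = int(round(log.config.event_duration_s * log.config.sample_rate_hz))
    out: list[GameResponse] = []
    for ev in log.events:
        sel = (t >= ev.t_appear_ms) & (t < ev.t_disappear_ms)
        if sel.sum() != expected:
            raise ValidationError(
                f"event {ev.event_id}: window [{ev.t_appear_ms}, {ev.t_disappear_ms}) "
                f"holds {int(sel.sum())} samples, expected {expected}"
            )
        out.append(
            GameResponse(
                event_id=ev.event_id,
                direction=ev.heading,
                t_ms=t[sel].copy(),
                trajectory=paddle[sel].copy(),
            )
        )
    return out


def _event_by_id(log: SessionLog, event_id: int) -> GameEvent:
    for ev in log.events:
        if ev.event_id == event_id:
            return ev
    raise ValidationError(f"event {event_id} not in log")


def movement_onset(
    response: GameResponse,
    event: GameEvent,
    config: TrialConfig,
    *,
    distance_fraction: float = ONSET_DISTANCE_FRACTION,
    sustain_ms: float = ONSET_SUSTAIN_MS,
) -> Optional[float]:
    """Movement onset time in ms from object appearance, or None.

    Onset is the first sample at which the paddle's displacement from
    its position at appearance reaches ``distance_fraction`` of the
    required movement distance ``|end_x - paddle(appearance)|`` (with an
    absolute floor of ``ONSET_MIN_DISTANCE``) and stays there for
    ``sustain_ms`` (or to the end of the event).  A paddle that never
    moves that far yields None — the no-movement contract, not an error.
    """
    traj = np.asarray(response.trajectory, dtype=float)
    if traj.size < 2:
        raise ValidationError("movement_onset needs at least 2 samples")
    p0 = traj[0]
    required = abs(event.end_x - p0)
    threshold = max(distance_fraction * required, ONSET_MIN_DISTANCE)
    disp = np.abs(traj - p0)
    above = disp >= threshold
    n_sustain = max(1, int(round(sustain_ms * config.sample_rate_hz / 1000.0)))
    for i in np.flatnonzero(above):
        window = above[i : i + n_sustain]
        if window.all():
            return float(response.t_ms[i] - response.t_ms[0])
    return None


def _catch_window(config: TrialConfig) -> float:
    return config.paddle_halfwidth + config.object_radius


def judge_success(response: GameResponse, event: GameEvent, config: TrialConfig) -> bool:
    """Decide the outcome of one event at the object's arrival sample.

    Targets succeed when caught — paddle within ``paddle_halfwidth +
    object_radius`` of the arrival abscissa ``end_x`` at the last sample
    of the event window; distractors succeed when *not* overlapping
    there.  Transit overlap is irrelevant: the games catch objects at
    the paddle line only.
    """
    overlap = abs(response.trajectory[-1] - event.end_x) <= _catch_window(config)
    return overlap if event.kind == "target" else not overlap


def movement_error(
    response: GameResponse, event: GameEvent, config: TrialConfig
) -> float:
    """Mean |paddle - end_x| over samples from onset to event end.

    Requires a detected onset; with ``response.onset_ms`` unset it is
    computed here.  A response without onset has no defined movement
    error and reports NaN (flagged missing).
    """
    onset = response.onset_ms
    if onset is None:
        onset = movement_onset(response, event, config)
    if onset is None:
        return float("nan")
    rel = response.t_ms - response.t_ms[0]
    tail = response.trajectory[rel >= onset]
    return float(np.mean(np.abs(tail - event.end_x)))


def movement_time(
    response: GameResponse, event: GameEvent, config: TrialConfig
) -> Optional[float]:
    """Onset-to-stabilization time in ms, or None.

    Stabilization is the last time the paddle enters the catch window
    around ``end_x`` and remains inside it through the arrival sample.
    None when there is no onset or the paddle is outside the window at
    arrival.
    """
    onset = response.onset_ms
    if onset is None:
        onset = movement_onset(response, event, config)
    if onset is None:
        return None
    inside = np.abs(response.trajectory - event.end_x) <= _catch_window(config)
    if not inside[-1]:
        return None
    outside = np.flatnonzero(~inside)
    stab_idx = 0 if outside.size == 0 else int(outside[-1]) + 1
    rel = response.t_ms - response.t_ms[0]
    return float(max(0.0, rel[stab_idx] - onset))


@dataclass
class MSGSummary:
    """Trial-level summary of one motor-skill-game session.

    ``success_rate_pct`` is over target events only.  Means are over
    target responses with a detected onset (NaN when none).
    ``amplitude_cov_pct`` maps each heading to the COV of per-response
    peak displacement (headings with fewer than 2 responses are
    omitted).
    """

    success_rate_pct: float
    mean_onset_ms: float
    mean_movement_time_ms: float
    mean_movement_error: float
    amplitude_cov_pct: dict = field(default_factory=dict)
    n_events: int = 0
    n_targets: int = 0
    n_distractors: int = 0


def msg_summary(log: SessionLog) -> MSGSummary:
    """Segment, score and aggregate one MSG trial.

    Raises a validation error when the trial contains no target events
    (the success rate would be undefined).
    """
    responses = segment_responses(log)
    events = {ev.event_id: ev for ev in log.events}
    config = log.config
    n_targets = sum(1 for ev in log.events if ev.kind == "target")
    if n_targets == 0:
        raise ValidationError("MSG summary requires at least one target event")

    caught = 0
    onsets: list[float] = []
    mts: list[float] = []
    mes: list[float] = []
    peaks_by_dir: dict[str, list[float]] = {}
    for resp in responses:
        ev = events[resp.event_id]
        resp.onset_ms = movement_onset(resp, ev, config)
        success = judge_success(resp, ev, config)
        if ev.kind == "target":
            resp.caught = success
            caught += int(success)
            resp.movement_error = movement_error(resp, ev, config)
            resp.movement_time_ms = movement_time(resp, ev, config)
            if resp.onset_ms is not None:
                onsets.append(resp.onset_ms)
                if not np.isnan(resp.movement_error):
                    mes.append(resp.movement_error)
                if resp.movement_time_ms is not None:
                    mts.append(resp.movement_time_ms)
            peak = float(np.max(np.abs(resp.trajectory - resp.trajectory[0])))
            peaks_by_dir.setdefault(resp.direction, []).append(peak)

    covs: dict[str, float] = {}
    for direction, peaks in sorted(peaks_by_dir.items()):
        arr = np.asarray(peaks)
        if arr.size >= 2 and arr.mean() > 0:
            covs[direction] = float(100.0 * arr.std(ddof=1) / arr.mean())
    nan = float("nan")
    return MSGSummary(
        success_rate_pct=100.0 * caught / n_targets,
        mean_onset_ms=float(np.mean(onsets)) if onsets else nan,
        mean_movement_time_ms=float(np.mean(mts)) if mts else nan,
        mean_movement_error=float(np.mean(mes)) if mes else nan,
        amplitude_cov_pct=covs,
        n_events=len(log.events),
        n_targets=n_targets,
        n_distractors=len(log.events) - n_targets,
    )
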