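"""Session-log domain model and lossless on-disk format.

A trial ("session") is one standardized assessment run: a trial
configuration, a 100 Hz stream of synchronized paddle/object positions,
and an event stream recording each game object's appearance and
disappearance.  All geometry lives in normalized screen units on the
unit square [0, 1] x [0, 1], origin top-left, x rightward, y downward;
mapping to pixels is a presentation concern and never enters the model.

On disk a session is a pair of sibling files sharing a stem:
``<name>.json`` holds the header (config, participant, events) and
``<name>.csv`` the sample table with columns
``t_ms, paddle_pos, target_x, target_y, event_id``.  Reading a written
session reproduces the original object exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CT",
    "MSG",
    "HEADINGS",
    "PADDLE_AXIS_POS",
    "SAMPLE_COLUMNS",
    "TrialConfig",
    "GameEvent",
    "SessionLog",
    "ParticipantRecord",
    "ValidationError",
    "ParseError",
    "write_session",
    "read_session",
    "read_participants",
    "write_participants",
]

CT = "CT"
MSG = "MSG"

#: Admissible object headings.  Falling-object games use the downward /
#: diagonal labels; horizontal games the leftward/rightward ones.
HEADINGS = (
    "leftward",
    "rightward",
    "downward",
    "upward",
    "diagonal-left",
    "diagonal-right",
)

#: Fixed coordinate of the one-dimensional paddle's axis line: y = 0.95
#: for falling-object (vertical) games, x = 0.95 for horizontal ones.
PADDLE_AXIS_POS = 0.95

SAMPLE_COLUMNS = ("t_ms", "paddle_pos", "target_x", "target_y", "event_id")


class ValidationError(ValueError):
    """An in-memory object violates a session-model invariant."""


class ParseError(ValueError):
    """A session file on disk does not conform to the documented dialect."""


@dataclass
class TrialConfig:
    """Configuration of one assessment trial.

    Cyclic-tracking (CT) trials use ``target_frequency_hz``; motor-skill
    -game (MSG) trials use ``event_duration_s``, ``distractor_fraction``,
    ``trajectory_complexity`` and ``object_speed``.  Fields that belong
    to the other module must be left unset.

    Parameters
    ----------
    module_kind : {"CT", "MSG"}
    duration_s : float
        Trial length in seconds; ``duration_s * sample_rate_hz`` must be
        a whole number of samples.
    sample_rate_hz : int
        Logger rate, default 100 Hz.  Must divide 1000 so sample spacing
        is an integer number of milliseconds.
    axis : {"horizontal", "vertical"}
        Axis of target motion (CT) or of paddle motion (MSG; objects
        then travel along the perpendicular axis toward the paddle line).
    target_amplitude : float
        Half peak-to-peak excursion of the CT target, in [0, 0.5].
    target_frequency_hz : float, optional
        CT target oscillation frequency, > 0.
    event_duration_s : float, optional
        MSG appearance-to-disappearance duration of each game event.
    paddle_halfwidth, object_radius : float
        Catch geometry, normalized units.
    distractor_fraction : float
        Probability that an MSG event is a distractor to be avoided.
    trajectory_complexity : {"straight", "diagonal"}
    object_speed : float
        Nominal object speed in normalized units / s (informational; the
        traversal time is fixed by ``event_duration_s``).
    rng_seed : int
        Seed for the event-schedule RNG.
    """

    module_kind: str
    duration_s: float
    sample_rate_hz: int = 100
    axis: str = "vertical"
    target_amplitude: float = 0.3
    target_frequency_hz: Optional[float] = None
    event_duration_s: Optional[float] = None
    paddle_halfwidth: float = 0.05
    object_radius: float = 0.03
    distractor_fraction: float = 0.0
    trajectory_complexity: str = "straight"
    object_speed: float = 0.475
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    @property
    def dt_ms(self) -> int:
        return 1000 // int(self.sample_rate_hz)

    def validate(self) -> None:
        if self.module_kind not in (CT, MSG):
            raise ValidationError(f"module_kind must be CT or MSG, got {self.module_kind!r}")
        if self.duration_s < 0:
            raise ValidationError("duration_s must be >= 0")
        if self.sample_rate_hz <= 0 or 1000 % int(self.sample_rate_hz) != 0:
            raise ValidationError(
                "sample_rate_hz must be a positive divisor of 1000 "
                f"(integer-ms timestamps), got {self.sample_rate_hz}"
            )
        n = self.duration_s * self.sample_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"duration_s x sample_rate_hz = {n} is not a whole number of samples"
            )
        if self.axis not in ("horizontal", "vertical"):
            raise ValidationError(f"axis must be horizontal or vertical, got {self.axis!r}")
        if not 0.0 <= self.target_amplitude <= 0.5:
            raise ValidationError("target_amplitude must lie in [0, 0.5]")
        if self.module_kind == CT:
            if self.target_frequency_hz is None or self.target_frequency_hz <= 0:
                raise ValidationError("CT trials require target_frequency_hz > 0")
            if self.event_duration_s is not None:
                raise ValidationError("event_duration_s must be unset for CT trials")
        else:
            if self.event_duration_s is None or self.event_duration_s <= 0:
                raise ValidationError("MSG trials require event_duration_s > 0")
            if self.target_frequency_hz is not None:
                raise ValidationError("target_frequency_hz must be unset for MSG trials")
        if not 0.0 <= self.distractor_fraction <= 1.0:
            raise ValidationError("distractor_fraction must lie in [0, 1]")
        if self.trajectory_complexity not in ("straight", "diagonal"):
            raise ValidationError(
                f"trajectory_complexity must be straight or diagonal, got {self.trajectory_complexity!r}"
            )
        if self.paddle_halfwidth < 0 or self.object_radius < 0:
            raise ValidationError("paddle_halfwidth and object_radius must be >= 0")
        if self.object_radius > 0.5:
            raise ValidationError("object_radius must keep the object inside the unit screen")
        if self.object_speed < 0:
            raise ValidationError("object_speed must be >= 0")


@dataclass
class GameEvent:
    """One game object's life from appearance to disappearance."""

    event_id: int
    kind: str  # "target" | "distractor"
    t_appear_ms: int
    t_disappear_ms: int
    spawn_x: float
    heading: str
    end_x: float

    def __post_init__(self) -> None:
        if self.kind not in ("target", "distractor"):
            raise ValidationError(f"event kind must be target or distractor, got {self.kind!r}")
        if self.heading not in HEADINGS:
            raise ValidationError(f"unknown heading {self.heading!r}")
        if self.t_disappear_ms <= self.t_appear_ms:
            raise ValidationError(
                f"event {self.event_id}: t_disappear_ms must exceed t_appear_ms"
            )
        for name, val in (("spawn_x", self.spawn_x), ("end_x", self.end_x)):
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"event {self.event_id}: {name}={val} outside [0, 1]")

    @property
    def duration_ms(self) -> int:
        return self.t_disappear_ms - self.t_appear_ms


@dataclass
class ParticipantRecord:
    """Demographic / clinical metadata for one participant.

    GMFCS and MACS levels are restricted to I-III (the platform's
    inclusion criteria for ambulant children with cerebral palsy).
    """

    id: str
    age_years: float
    gender: str
    gmfcs_level: str
    macs_level: str

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F"):
            raise ValidationError(f"gender must be M or F, got {self.gender!r}")
        for name, lvl in (("gmfcs_level", self.gmfcs_level), ("macs_level", self.macs_level)):
            if lvl not in ("I", "II", "III"):
                raise ValidationError(f"{name} must be I, II or III, got {lvl!r}")


def _empty_samples() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_ms": pd.Series(dtype="int64"),
            "paddle_pos": pd.Series(dtype="float64"),
            "target_x": pd.Series(dtype="float64"),
            "target_y": pd.Series(dtype="float64"),
            "event_id": pd.Series(dtype="Int64"),
        }
    )


@dataclass
class SessionLog:
    """One recorded assessment trial.

    ``samples`` is a DataFrame with columns ``t_ms`` (int64, strictly
    increasing, spaced ``1000 / sample_rate_hz`` ms), ``paddle_pos``
    (float), ``target_x`` / ``target_y`` (float, NaN between events) and
    ``event_id`` (nullable Int64 referencing ``events``).
    """

    config: TrialConfig
    samples: pd.DataFrame = field(default_factory=_empty_samples)
    events: list[GameEvent] = field(default_factory=list)
    participant_id: str = ""

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionLog):
            return NotImplemented
        return (
            self.config == other.config
            and self.participant_id == other.participant_id
            and self.events == other.events
            and self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
        )

    def validate(self) -> None:
        self.config.validate()
        df = self.samples
        missing = set(SAMPLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"samples missing columns {sorted(missing)}")
        if len(df) != self.config.n_samples:
            raise ValidationError(
                f"sample count {len(df)} != duration_s x sample_rate_hz = {self.config.n_samples}"
            )
        t = df["t_ms"].to_numpy()
        if len(t) > 0:
            dt = np.diff(t)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise ValidationError(f"t_ms not strictly increasing at row {row}")
            if np.any(dt != self.config.dt_ms):
                row = int(np.argmax(dt != self.config.dt_ms)) + 1
                raise ValidationError(
                    f"t_ms spacing != {self.config.dt_ms} ms at row {row}"
                )
        by_id = {e.event_id: e for e in self.events}
        if len(by_id) != len(self.events):
            raise ValidationError("duplicate event_id in events")
        ids = df["event_id"]
        for row, (eid, t_ms) in enumerate(zip(ids, df["t_ms"])):
            if pd.isna(eid):
                continue
            ev = by_id.get(int(eid))
            if ev is None:
                raise ValidationError(f"row {row}: event_id {eid} not in events")
            if not ev.t_appear_ms <= t_ms <= ev.t_disappear_ms:
                raise ValidationError(
                    f"row {row}: t_ms {t_ms} outside event {eid} window "
                    f"[{ev.t_appear_ms}, {ev.t_disappear_ms}]"
                )

    @property
    def duration_ms(self) -> int:
        return int(round(self.config.duration_s * 1000))


# ---------------------------------------------------------------------------
# On-disk dialect: UTF-8, comma-separated, "." decimal, mandatory CSV header;
# missing target coordinates / event ids are empty fields.
# ---------------------------------------------------------------------------

def _paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (".json", ".csv"):
        base = base.with_suffix("")
    return base.with_suffix(".json"), base.with_suffix(".csv")


def write_session(log: SessionLog, path: str | Path) -> None:
    """Write ``log`` to ``<path>.json`` + ``<path>.csv``.

    The log is validated first; an invariant violation raises
    :class:`ValidationError` naming the offending field.  Floats are
    written with full ``repr`` precision so the round trip is lossless.
    """
    log.validate()
    json_path, csv_path = _paths(path)
    header = {
        "format": "rtp-session",
        "version": 1,
        "participant_id": log.participant_id,
        "config": asdict(log.config),
        "events": [asdict(e) for e in log.events],
    }
    json_path.write_text(json.dumps(header, indent=2) + "\n", encoding="utf-8")
    with open(csv_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(SAMPLE_COLUMNS) + "\n")
        for t, p, tx, ty, eid in log.samples[list(SAMPLE_COLUMNS)].itertuples(index=False):
            fh.write(
                f"{int(t)},{p!r},"
                f"{'' if (tx is None or (isinstance(tx, float) and math.isnan(tx))) else repr(tx)},"
                f"{'' if (ty is None or (isinstance(ty, float) and math.isnan(ty))) else repr(ty)},"
                f"{'' if pd.isna(eid) else int(eid)}\n"
            )


def read_session(path: str | Path) -> SessionLog:
    """Read and validate a session written by :func:`write_session`.

    Raises :class:`ParseError` (with a row number where applicable) on a
    malformed header, unknown columns, or a timestamp regression.
    """
    json_path, csv_path = _paths(path)
    try:
        header = json.loads(json_path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"cannot read session header {json_path}: {exc}") from exc
    if header.get("format") != "rtp-session":
        raise ParseError(f"{json_path}: not an rtp-session header")
    try:
        config = TrialConfig(**header["config"])
        events = [GameEvent(**e) for e in header["events"]]
        participant_id = header["participant_id"]
    except (KeyError, TypeError, ValidationError) as exc:
        raise ParseError(f"{json_path}: malformed header: {exc}") from exc

    try:
        df = pd.read_csv(
            csv_path,
            float_precision="round_trip",
            dtype={
                "t_ms": "int64",
                "paddle_pos": "float64",
                "target_x": "float64",
                "target_y": "float64",
                "event_id": "Int64",
            },
        )
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot read sample table {csv_path}: {exc}") from exc
    if list(df.columns) != list(SAMPLE_COLUMNS):
        raise ParseError(
            f"{csv_path}: unexpected columns {list(df.columns)}; expected {list(SAMPLE_COLUMNS)}"
        )
    t = df["t_ms"].to_numpy()
    if len(t) > 1:
        bad = np.diff(t) <= 0
        if bad.any():
            # 1-based file line of the regressing row: +1 diff offset,
            # +1 header line, +1 one-based numbering
            raise ParseError(f"{csv_path}: timestamp regression at row {int(np.argmax(bad)) + 3}")

    log = SessionLog(config=config, samples=df, events=events, participant_id=participant_id)
    try:
        log.validate()
    except ValidationError as exc:
        raise ParseError(f"{csv_path}: {exc}") from exc
    return log


# -- participants file (Table-1 layout) -------------------------------------

_PARTICIPANT_COLUMNS = ("id", "age_years", "gender", "gmfcs", "macs")


def write_participants(records: list[ParticipantRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"id": r.id, "age_years": r.age_years, "gender": r.gender,
             "gmfcs": r.gmfcs_level, "macs": r.macs_level}
            for r in records
        ],
        columns=list(_PARTICIPANT_COLUMNS),
    )
    df.to_csv(path, index=False)


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != list(_PARTICIPANT_COLUMNS):
        raise ParseError(f"{path}: expected columns {list(_PARTICIPANT_COLUMNS)}")
    return [
        ParticipantRecord(
            id=row.id,
            age_years=float(row.age_years),
            gender=row.gender,
            gmfcs_level=row.gmfcs,
            macs_level=row.macs,
        )
        for row in df.itertuples(index=False)
    ]
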