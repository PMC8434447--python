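"""Worked-example fixtures: the published six-child pilot tables.

These small tables (demographics, PDMS-2 subtest scores, and the three
object-manipulation assessment tasks) ship as in-memory DataFrames so
the outcome arithmetic can be exercised against printed numbers.  Known
data errata are annotated, never silently corrected:

* PDMS-2 visuomotor, participant P1, post score is printed "1120"; the
  corrected value 120 is carried in the ``post`` column with the printed
  value kept in ``post_printed``.
* Fine-rotation task: the printed success-rate percent-change cells for
  P1, P2, P4, P5 and P6, and the response-time cell for P4, are
  inconsistent with their own pre/post cells.
* Cone task: the P1 response-time percent change recomputes to -15 but
  is printed -16.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .session import ParticipantRecord

__all__ = [
    "participants",
    "pdms2_scores",
    "cue_task_scores",
    "CUE_TASKS",
    "ERRATA",
    "write_fixtures",
]

CUE_TASKS = ("soccer_ball", "cone", "fine_rotation")

#: Annotated data errata (participant, table, cell, printed, corrected/
#: recomputed).  Kept as data so reports can surface them.
ERRATA = [
    {"table": "pdms2", "participant": "P1", "cell": "vmi_post",
     "printed": 1120, "value": 120, "note": "typographical; 120 is consistent with the printed 9% change"},
    {"table": "cone", "participant": "P1", "cell": "rt_pct",
     "printed": -16, "value": -15, "note": "one rounding step off its own pre/post cells"},
    {"table": "fine_rotation", "participant": "P1", "cell": "sr_pct",
     "printed": 33, "value": 35, "note": "inconsistent with its own pre/post cells"},
    {"table": "fine_rotation", "participant": "P2", "cell": "sr_pct",
     "printed": 34, "value": 36, "note": "inconsistent with its own pre/post cells"},
    {"table": "fine_rotation", "participant": "P4", "cell": "sr_pct",
     "printed": 80, "value": 0, "note": "pre = post = 45 implies 0"},
    {"table": "fine_rotation", "participant": "P5", "cell": "sr_pct",
     "printed": 13, "value": 0, "note": "pre = post = 75 implies 0"},
    {"table": "fine_rotation", "participant": "P6", "cell": "sr_pct",
     "printed": 9, "value": 8, "note": "inconsistent with its own pre/post cells"},
    {"table": "fine_rotation", "participant": "P4", "cell": "rt_pct",
     "printed": 18, "value": 15, "note": "inconsistent with its own pre/post cells"},
]


def participants() -> list[ParticipantRecord]:
    """Demographics of the six-child pilot (ids P1-P6)."""
    rows = [
        ("P1", 12, "M", "II", "III"),
        ("P2", 10, "M", "I", "II"),
        ("P3", 8, "M", "I", "II"),
        ("P4", 7, "F", "II", "III"),
        ("P5", 8, "F", "II", "III"),
        ("P6", 5, "M", "II", "III"),
    ]
    return [
        ParticipantRecord(id=i, age_years=a, gender=g, gmfcs_level=gm, macs_level=ma)
        for i, a, g, gm, ma in rows
    ]


def participants_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"id": r.id, "age_years": r.age_years, "gender": r.gender,
             "gmfcs": r.gmfcs_level, "macs": r.macs_level}
            for r in participants()
        ]
    )


def pdms2_scores() -> pd.DataFrame:
    """PDMS-2 grasp and visuomotor pre/post scores with printed changes.

    Columns: participant, measure ("grasp" | "vmi"), pre, post,
    post_printed, pct_printed.  ``post`` carries the corrected P1
    visuomotor score (see ERRATA); the printed group averages are 12
    (grasp) and 9 (vmi).
    """
    rows = [
        ("P1", "grasp", 46, 52, 52, 13),
        ("P2", "grasp", 47, 52, 52, 11),
        ("P3", "grasp", 44, 50, 50, 14),
        ("P4", "grasp", 46, 51, 51, 11),
        ("P5", "grasp", 44, 49, 49, 11),
        ("P6", "grasp", 44, 50, 50, 14),
        ("P1", "vmi", 110, 120, 1120, 9),
        ("P2", "vmi", 120, 130, 130, 8),
        ("P3", "vmi", 116, 125, 125, 8),
        ("P4", "vmi", 120, 131, 131, 9),
        ("P5", "vmi", 126, 134, 134, 6),
        ("P6", "vmi", 113, 127, 127, 12),
    ]
    return pd.DataFrame(
        rows, columns=["participant", "measure", "pre", "post", "post_printed", "pct_printed"]
    )


_CUE_ROWS = {
    # participant, sr_pre, sr_post, sr_pct_printed, rt_pre, rt_post, rt_pct_printed
    "soccer_ball": [
        ("P1", 45, 87, 93, 572, 535, -6),
        ("P2", 70, 78, 11, 436, 359, -18),
        ("P3", 54, 66, 22, 453, 470, 4),
        ("P4", 93, 93, 0, 570, 527, -8),
        ("P5", 30, 84, 180, 732, 527, -28),
        ("P6", 55, 100, 82, 687, 532, -23),
    ],
    "cone": [
        ("P1", 42, 66, 57, 415, 353, -16),
        ("P2", 53, 88, 66, 370, 334, -10),
        ("P3", 45, 60, 33, 497, 451, -9),
        ("P4", 71, 95, 34, 510, 475, -7),
        ("P5", 57, 100, 75, 565, 521, -8),
        ("P6", 90, 90, 0, 578, 411, -29),
    ],
    # fine rotation prints response-time changes as positive reductions
    "fine_rotation": [
        ("P1", 52, 70, 33, 520, 500, 4),
        ("P2", 70, 95, 34, 665, 440, 34),
        ("P3", 62, 69, 11, 830, 680, 18),
        ("P4", 45, 45, 80, 540, 460, 18),
        ("P5", 75, 75, 13, 650, 526, 19),
        ("P6", 74, 80, 9, 625, 552, 12),
    ],
}

#: Printed group-average rows (percent) per task: (sr_avg, rt_avg).
CUE_PRINTED_AVERAGES = {
    "soccer_ball": (65, -13),
    "cone": (44, -13),
    "fine_rotation": (30, 18),
}


def cue_task_scores(task: str) -> pd.DataFrame:
    """Pre/post assessment scores for one object-manipulation task.

    ``task`` is one of ``soccer_ball`` (shoulder-elbow rolling),
    ``cone`` (pronation-supination) or ``fine_rotation`` (two-finger
    dowel rotation).  Success rate is in %, response time in ms; values
    are already averaged over the task's two movement directions.  The
    fine-rotation table prints response-time changes as positive
    *reductions*; the other two print signed changes.
    """
    if task not in CUE_TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {CUE_TASKS}")
    return pd.DataFrame(
        _CUE_ROWS[task],
        columns=["participant", "sr_pre", "sr_post", "sr_pct_printed",
                 "rt_pre", "rt_post", "rt_pct_printed"],
    )


def write_fixtures(out_dir: str | Path) -> list[Path]:
    """Materialize all fixture tables as CSV files in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    p = out / "participants.csv"
    participants_frame().to_csv(p, index=False)
    written.append(p)
    p = out / "pdms2.csv"
    pdms2_scores().to_csv(p, index=False)
    written.append(p)
    for task in CUE_TASKS:
        p = out / f"cue_{task}.csv"
        cue_task_scores(task).to_csv(p, index=False)
        written.append(p)
    p = out / "errata.csv"
    pd.DataFrame(ERRATA).to_csv(p, index=False)
    written.append(p)
    return written
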