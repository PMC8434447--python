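"""Pre/post outcome tables and test-retest reliability.

Percent changes are reported as integers, rounded half away from zero —
the convention that reproduces every self-consistent printed cell of the
worked-example tables.  Reliability uses the two-way random-effects,
absolute-agreement, single-measure intraclass correlation ICC(2,1),
computed from the classical ANOVA mean squares, with

    SEM = SD * sqrt(1 - ICC)        (SD pooled over both sessions)
    MDC = 1.96 * sqrt(2) * SEM      (95 % level)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeTable",
    "ReliabilityResult",
    "percent_change",
    "percent_reduction",
    "group_average",
    "build_outcome_table",
    "icc_test_retest",
    "UndefinedChangeError",
]

Number = Union[int, float]
#: Per-participant measure value: a scalar, or a mapping direction -> value
#: that is averaged over directions before the pre/post arithmetic.
MeasureValue = Union[Number, Mapping[str, Number]]


class UndefinedChangeError(ValueError):
    """Percent change from a zero baseline is undefined."""


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def percent_change(pre: Number, post: Number) -> int:
    """Signed percent change 100*(post - pre)/pre, rounded half away from zero."""
    if pre == 0:
        raise UndefinedChangeError("percent change undefined for pre = 0")
    return _round_half_away(100.0 * (post - pre) / pre)


def percent_reduction(pre: Number, post: Number) -> int:
    """Percent reduction 100*(pre - post)/pre, rounded half away from zero.

    Equal to ``-percent_change(pre, post)`` before rounding; reported
    with positive sign for improvements on measures where smaller is
    better (e.g. response times).
    """
    if pre == 0:
        raise UndefinedChangeError("percent reduction undefined for pre = 0")
    return _round_half_away(100.0 * (pre - post) / pre)


def group_average(values: Iterable[Number]) -> int:
    """Rounded arithmetic mean of integer percent values."""
    vals = list(values)
    if not vals:
        raise ValueError("group_average of an empty list")
    return _round_half_away(sum(vals) / len(vals))


@dataclass
class OutcomeTable:
    """Per-participant pre/post/percent-change rows plus a group average.

    ``rows`` has columns ``participant, pre, post, percent_change``;
    ``average_percent_change`` is the rounded mean of the change column.
    """

    measure: str
    rows: pd.DataFrame
    average_percent_change: int

    def to_frame(self) -> pd.DataFrame:
        """Rows plus an ``Average`` footer row, as printed."""
        footer = pd.DataFrame(
            [{"participant": "Average", "pre": np.nan, "post": np.nan,
              "percent_change": self.average_percent_change}]
        )
        return pd.concat([self.rows, footer], ignore_index=True)


def _collapse(value: MeasureValue) -> float:
    if isinstance(value, Mapping):
        if not value:
            raise ValueError("empty direction mapping")
        return float(np.mean(list(value.values())))
    return float(value)


def build_outcome_table(
    pre_summaries: Mapping[str, MeasureValue],
    post_summaries: Mapping[str, MeasureValue],
    measure: str = "",
    *,
    reduction: bool = False,
) -> OutcomeTable:
    """Assemble a pre/post outcome table across participants.

    Values given per movement direction are first averaged over the
    directions, then the per-participant percent change (or, with
    ``reduction=True``, percent reduction) and the group average are
    computed.  Participant ids must match between the two sets.
    """
    missing = set(pre_summaries) ^ set(post_summaries)
    if missing:
        raise ValueError(f"unmatched participant id(s): {sorted(missing)}")
    if not pre_summaries:
        raise ValueError("no participants")
    change = percent_reduction if reduction else percent_change
    rows = []
    for pid in pre_summaries:
        pre = _collapse(pre_summaries[pid])
        post = _collapse(post_summaries[pid])
        rows.append(
            {"participant": pid, "pre": pre, "post": post,
             "percent_change": change(pre, post)}
        )
    df = pd.DataFrame(rows, columns=["participant", "pre", "post", "percent_change"])
    return OutcomeTable(
        measure=measure,
        rows=df,
        average_percent_change=group_average(df["percent_change"]),
    )


@dataclass
class ReliabilityResult:
    """Test-retest reliability of a measure over two sessions.

    ``degenerate`` flags a table with zero total variance, where the ICC
    is undefined (icc/sem/mdc are then NaN).
    """

    icc: float
    sem: float
    mdc: float
    mdc_pct_of_mean: float
    degenerate: bool = False


def icc_test_retest(session1_scores, session2_scores) -> ReliabilityResult:
    """ICC(2,1), SEM and MDC for paired test-retest scores.

    The ICC is the two-way random-effects, absolute-agreement,
    single-measure coefficient from the ANOVA decomposition of the
    n-subjects x 2-sessions table:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR/MSC/MSE the row (subject), column (session) and residual
    mean squares.  Requires n >= 3 subjects.
    """
    x = np.column_stack(
        [np.asarray(session1_scores, dtype=float), np.asarray(session2_scores, dtype=float)]
    )
    if x.shape[0] < 3:
        raise ValueError("icc_test_retest requires at least 3 paired scores")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    if sst <= 1e-300:
        nan = float("nan")
        return ReliabilityResult(icc=nan, sem=nan, mdc=nan, mdc_pct_of_mean=nan,
                                 degenerate=True)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    sd = float(x.std(ddof=1))
    sem = sd * math.sqrt(max(0.0, 1.0 - icc))
    mdc = 1.96 * math.sqrt(2.0) * sem
    mdc_pct = 100.0 * mdc / grand if grand != 0 else float("nan")
    return ReliabilityResult(icc=float(icc), sem=sem, mdc=mdc, mdc_pct_of_mean=mdc_pct)
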