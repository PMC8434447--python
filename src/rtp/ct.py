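"""Cyclic-tracking performance measures.

Residual error is the per-sample absolute difference between target and
paddle along the tracking axis — absolute rather than signed, so totals
cannot cancel.  Amplitude variation segments the trial into half cycles
of the *known target waveform* (boundaries at consecutive target
extrema, analytic for the sinusoid), measures the paddle's peak-to-
trough excursion in each, and reports mean, sample SD and the
coefficient of variation (COV = 100 * SD / mean).

Because tracking typically takes a cycle or two to settle, the first two
full target periods — measured from trial start — are excluded from
every summary statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .session import CT, SessionLog, ValidationError
from .targets import CTWaveform

__all__ = ["HalfCycle", "CTSummary", "residual_error_series", "segment_half_cycles", "ct_summary"]

#: Minimum number of analyzed half cycles for a reported COV.
MIN_HALF_CYCLES_FOR_COV = 4


@dataclass(frozen=True)
class HalfCycle:
    """One extremum-to-extremum interval of the target waveform.

    ``amplitude`` is the paddle's max - min excursion within the
    interval (2x the target amplitude for a perfect tracker).
    """

    index: int
    start_ms: float
    end_ms: float
    amplitude: float


@dataclass
class CTSummary:
    """Summary measures for one cyclic-tracking trial.

    ``total_residual_error`` is in normalized-unit-samples (a sum over
    samples), ``average_residual_error`` in normalized units.
    ``cov_percent`` is None when undefined (mean amplitude 0, or fewer
    than 4 analyzed half cycles).  ``n_cycles_analyzed`` counts analyzed
    *half* cycles.
    """

    total_residual_error: float
    average_residual_error: float
    mean_amplitude: float
    sd_amplitude: float
    cov_percent: Optional[float]
    n_cycles_analyzed: int


def _target_axis_column(log: SessionLog) -> str:
    return "target_x" if log.config.axis == "horizontal" else "target_y"


def residual_error_series(log: SessionLog) -> np.ndarray:
    """Per-sample |target - paddle| along the configured axis."""
    if log.config.module_kind != CT:
        raise ValidationError("residual_error_series requires a CT log")
    target = log.samples[_target_axis_column(log)].to_numpy(dtype=float)
    if np.isnan(target).any():
        row = int(np.argmax(np.isnan(target)))
        raise ValidationError(f"missing target sample at row {row}")
    paddle = log.samples["paddle_pos"].to_numpy(dtype=float)
    return np.abs(target - paddle)


def _half_cycle_bounds_ms(log: SessionLog) -> np.ndarray:
    wf = CTWaveform.from_config(log.config)
    return wf.extrema_times_ms(log.duration_ms)


def segment_half_cycles(log: SessionLog) -> list[HalfCycle]:
    """Segment a CT trial into complete target half cycles.

    Boundaries are the target waveform's consecutive extrema (every
    ``1/(2f)`` s from the first extremum); only intervals lying entirely
    inside the trial are returned.  Per interval, the amplitude is the
    paddle's max - min over samples with ``start <= t <= end``.  Trials
    shorter than three full target cycles are rejected: after excluding
    the first two cycles nothing would remain.
    """
    if log.config.module_kind != CT:
        raise ValidationError("segment_half_cycles requires a CT log")
    f = log.config.target_frequency_hz
    if log.config.duration_s * f < 3.0 - 1e-9:
        raise ValidationError(
            f"trial holds {log.config.duration_s * f:.2f} target cycles; "
            "at least 3 are required (the first two are excluded from analysis)"
        )
    bounds = _half_cycle_bounds_ms(log)
    t = log.samples["t_ms"].to_numpy()
    paddle = log.samples["paddle_pos"].to_numpy(dtype=float)
    out: list[HalfCycle] = []
    for i in range(len(bounds) - 1):
        start, end = bounds[i], bounds[i + 1]
        sel = (t >= start - 1e-9) & (t <= end + 1e-9)
        if not sel.any():
            continue
        seg = paddle[sel]
        out.append(HalfCycle(index=i, start_ms=float(start), end_ms=float(end),
                             amplitude=float(seg.max() - seg.min())))
    return out


def ct_summary(log: SessionLog) -> CTSummary:
    """Compute TRE/ARE and amplitude statistics for a CT trial.

    All statistics exclude the first two full target periods
    (``t < 2 / f``): residual errors are summed/averaged over the
    remaining samples, amplitude statistics over half cycles starting at
    or after the cutoff.  SD uses the sample (n-1) formula.
    """
    errors = residual_error_series(log)
    f = log.config.target_frequency_hz
    cutoff_ms = 2000.0 / f
    t = log.samples["t_ms"].to_numpy()
    analyzed = errors[t >= cutoff_ms - 1e-9]
    if analyzed.size == 0:
        raise ValidationError("no samples remain after the first-two-cycle exclusion")
    tre = float(analyzed.sum())
    are = float(analyzed.mean())

    half_cycles = [h for h in segment_half_cycles(log) if h.start_ms >= cutoff_ms - 1e-9]
    amps = np.array([h.amplitude for h in half_cycles], dtype=float)
    mean_amp = float(amps.mean()) if amps.size else float("nan")
    sd_amp = float(amps.std(ddof=1)) if amps.size >= 2 else float("nan")
    cov: Optional[float]
    if amps.size < MIN_HALF_CYCLES_FOR_COV or mean_amp <= 0 or math.isnan(sd_amp):
        cov = None
    else:
        cov = 100.0 * sd_amp / mean_amp
    return CTSummary(
        total_residual_error=tre,
        average_residual_error=are,
        mean_amplitude=mean_amp,
        sd_amplitude=sd_amp,
        cov_percent=cov,
        n_cycles_analyzed=len(half_cycles),
    )
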