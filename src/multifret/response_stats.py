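"""Plateau statistics and normalized % FRET shifts.

A stimulant protocol is summarized per ROI as:

* ``P_base`` — mean of the last ``window`` (default 10) defined ratio points
  strictly before the first stimulant addition;
* ``P_stim`` per stimulant — same rule, with the boundary at the next
  addition (the final stimulant uses the tail of the trace);
* ``C = (P_base - P_stim) / P_base`` — the fractional change from baseline,
  positive for a ratio decrease (Epac-family decreasing-FRET sensors),
  negative for a ratio increase (e.g. AKAP79-CUTie);
* ``% FRET shift = 100 * C_stim / C_max`` — each stimulant's change
  normalized to the change produced by the saturating maximizer, so the
  maximizer itself is exactly 100 % and the sign of ``C`` cancels whenever a
  stimulant moves the ratio in the same direction as the maximizer.

"Before adding" is strict (``time < event time``): the addition frame may
already contain response.  Plateau windows are counted over defined
(non-missing) points, so transiently lost frames do not silently shrink the
average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .acquisition_io import EventTimeline
from .ratiometrics import RatioTrace

logger = logging.getLogger(__name__)

__all__ = [
    "EventResponse",
    "ResponseSummary",
    "plateau_mean",
    "change_from_baseline",
    "percent_shift",
    "analyze_response",
    "summary_table",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 10


@dataclass(frozen=True)
class EventResponse:
    label: str
    time: float
    is_maximizer: bool
    p_stim: float
    c: float
    percent_shift: float


@dataclass(frozen=True)
class ResponseSummary:
    """Per-ROI response statistics for one stimulant timeline."""

    roi_name: str
    position_id: str
    p_base: float
    responses: tuple[EventResponse, ...]
    maximizer_label: str
    c_max: float
    window: int


def plateau_mean(
    trace: RatioTrace,
    boundary_time: float | None = None,
    window: int = DEFAULT_WINDOW,
) -> float:
    """Mean of the last ``window`` defined ratios strictly before
    ``boundary_time`` (``None`` = the end of the trace).

    With fewer than ``window`` defined points available, all of them are
    used and a warning notes the count.
    """
    if window < 1:
        raise ValueError(f"plateau window must be >= 1, got {window}")
    defined = trace.defined
    if boundary_time is None:
        selected = defined
    else:
        selected = defined & (trace.times < boundary_time)
    values = trace.ratios[selected]
    if values.size == 0:
        raise ValueError(
            f"no defined trace points before t={boundary_time} for ROI "
            f"{trace.roi_name!r} at position {trace.position_id!r}"
        )
    if values.size < window:
        logger.warning(
            "ROI %r at position %r: only %d defined point(s) before t=%s "
            "(window=%d); plateau uses all of them",
            trace.roi_name,
            trace.position_id,
            values.size,
            boundary_time,
            window,
        )
    return float(values[-window:].mean())


def change_from_baseline(p_base: float, p_stim: float) -> float:
    """Fractional change ``C = (P_base - P_stim) / P_base``.

    The sign is preserved: negative ``C`` means the ratio increased, as for
    increasing-FRET sensors.
    """
    if p_base == 0:
        raise ValueError("P_base is zero; change from baseline undefined")
    return (p_base - p_stim) / p_base


def percent_shift(c_stim: float, c_max: float) -> float:
    """Normalized response ``100 * C_stim / C_max`` (percent of the
    maximizer-induced change).  Computed as ``100 * (C_stim / C_max)`` so the
    maximizer's own shift is exactly 100.0."""
    if c_max == 0:
        raise ValueError("maximizer produced no change; normalization undefined")
    return 100.0 * (c_stim / c_max)


def analyze_response(
    trace: RatioTrace,
    events: EventTimeline,
    window: int = DEFAULT_WINDOW,
) -> ResponseSummary:
    """Full per-ROI response pipeline: plateaus, baseline changes and
    normalized % FRET shifts for every stimulant of the timeline."""
    defined_times = trace.times[trace.defined]
    if defined_times.size == 0:
        raise ValueError(
            f"trace for ROI {trace.roi_name!r} at position "
            f"{trace.position_id!r} has no defined points"
        )
    last_t = float(defined_times[-1])
    late = [e.label for e in events if e.time > last_t]
    if late:
        raise ValueError(
            f"event(s) {late} occur after the last trace point (t={last_t}); "
            f"event times must lie within the acquisition's time span"
        )

    try:
        p_base = plateau_mean(trace, events.events[0].time, window)
    except ValueError as err:
        raise ValueError(f"baseline plateau: {err}") from err

    plateaus = []
    for k, event in enumerate(events):
        boundary = events.events[k + 1].time if k + 1 < len(events) else None
        try:
            plateaus.append(plateau_mean(trace, boundary, window))
        except ValueError as err:
            raise ValueError(f"plateau for event {event.label!r}: {err}") from err

    changes = [change_from_baseline(p_base, p) for p in plateaus]
    c_max = changes[[e.is_maximizer for e in events].index(True)]
    responses = tuple(
        EventResponse(
            label=e.label,
            time=e.time,
            is_maximizer=e.is_maximizer,
            p_stim=p,
            c=c,
            percent_shift=percent_shift(c, c_max),
        )
        for e, p, c in zip(events, plateaus, changes)
    )
    return ResponseSummary(
        roi_name=trace.roi_name,
        position_id=trace.position_id,
        p_base=p_base,
        responses=responses,
        maximizer_label=events.maximizer.label,
        c_max=c_max,
        window=window,
    )


def summary_table(summaries: Sequence[ResponseSummary]) -> pd.DataFrame:
    """One row per (position, ROI, event): P_base, P_stim, C, % shift."""
    rows = []
    for s in summaries:
        for r in s.responses:
            rows.append(
                {
                    "position": s.position_id,
                    "roi": s.roi_name,
                    "event": r.label,
                    "event_time": r.time,
                    "P_base": s.p_base,
                    "P_stim": r.p_stim,
                    "C": r.c,
                    "percent_fret_shift": r.percent_shift,
                    "is_maximizer": r.is_maximizer,
                    "window": s.window,
                }
            )
    return pd.DataFrame(rows)
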