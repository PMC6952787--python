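"""Acquisition, event-timeline and table/workbook I/O.

A multi-position FRET experiment cycles a motorized stage through a set of
preselected cells, acquiring one frame per position per cycle at a nominal
interval.  This module holds the in-memory model of such an acquisition
(:class:`Frame`, :class:`Acquisition`), the stimulant timeline
(:class:`EventTimeline`), and the disk formats:

* image stacks in three declared dialects (``stack``: one multipage TIFF per
  position; ``ome``: a single OME-TIFF with one series per position;
  ``frames``: a directory per position with one TIFF per frame — the layout
  the live watcher polls);
* an event CSV with header ``label,time_seconds,is_maximizer``;
* per-position trace CSV tables and an xlsx summary workbook, optionally
  injected into a user-supplied template.

Frame timestamps are taken from a ``timestamps.json`` sidecar next to the
stacks when present, and synthesized as ``frame_index * interval`` otherwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .channel_split import ChannelLayout, split_frame

if TYPE_CHECKING:  # pragma: no cover
    from .ratiometrics import RatioTrace
    from .response_stats import ResponseSummary

logger = logging.getLogger(__name__)

__all__ = [
    "Frame",
    "Acquisition",
    "StimulusEvent",
    "EventTimeline",
    "load_acquisition",
    "load_events",
    "write_events",
    "write_traces",
    "trace_table",
    "read_trace_table",
    "write_workbook",
    "DIALECTS",
]

DIALECTS = ("stack", "ome", "frames")
TIMESTAMP_SIDECAR = "timestamps.json"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Frame:
    """One camera exposure at one stage position.

    ``pixels`` are raw camera counts (unsigned integer grid); ``timestamp``
    is seconds since acquisition start; ``frame_index`` is the 0-based
    acquisition cycle; ``channel`` is set only in pre-split mode.
    """

    pixels: np.ndarray
    timestamp: float
    position_id: str
    frame_index: int
    channel: str | None = None


@dataclass
class Acquisition:
    """An ordered multi-position, multi-cycle collection of frames.

    In ``full-frame`` mode each position holds one :class:`Frame` per cycle
    (``frames``); in ``pre-split`` mode each position holds one frame per
    channel per cycle (``channel_frames``).
    """

    positions: list[str]
    interval: float
    channel_mode: str = "full-frame"
    frames: dict[str, list[Frame]] = field(default_factory=dict)
    channel_frames: dict[str, dict[str, list[Frame]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError(f"position_ids are not unique: {self.positions}")
        if self.channel_mode not in ("full-frame", "pre-split"):
            raise ValueError(f"unknown channel_mode {self.channel_mode!r}")
        self._validate_lengths()
        self._validate_geometry()

    def _validate_lengths(self) -> None:
        counts = {p: self.n_frames(p) for p in self.positions}
        if len(set(counts.values())) > 1:
            common = min(counts.values())
            ragged = sorted(p for p, c in counts.items() if c != common)
            raise ValueError(
                f"positions have unequal frame counts {counts}; "
                f"offending position(s): {ragged} "
                f"(pass truncate_to_common=True to trim to {common})"
            )

    def _validate_geometry(self) -> None:
        shapes = set()
        dtypes = set()
        for f in self.iter_frames():
            shapes.add(f.pixels.shape)
            dtypes.add(f.pixels.dtype)
        if len(shapes) > 1:
            raise ValueError(f"frame dimensions are not constant: {sorted(shapes)}")
        if len(dtypes) > 1:
            raise ValueError(f"mixed pixel bit depths: {sorted(map(str, dtypes))}")
        for pos in self.positions:
            ts = self.timestamps(pos)
            if np.any(np.diff(ts) <= 0):
                bad = [int(i) for i in np.nonzero(np.diff(ts) <= 0)[0] + 1]
                raise ValueError(
                    f"non-monotonic timestamps at position {pos!r}, "
                    f"frame indices {bad}"
                )

    def iter_frames(self) -> Iterable[Frame]:
        for pos in self.positions:
            if self.channel_mode == "full-frame":
                yield from self.frames.get(pos, [])
            else:
                for stack in self.channel_frames.get(pos, {}).values():
                    yield from stack

    def n_frames(self, position: str | None = None) -> int:
        """Number of acquisition cycles (per position)."""
        if position is None:
            position = self.positions[0]
        if self.channel_mode == "full-frame":
            return len(self.frames.get(position, []))
        stacks = self.channel_frames.get(position, {})
        return min((len(s) for s in stacks.values()), default=0)

    def timestamps(self, position: str) -> np.ndarray:
        if self.channel_mode == "full-frame":
            return np.array([f.timestamp for f in self.frames[position]], dtype=float)
        first = next(iter(self.channel_frames[position].values()))
        return np.array([f.timestamp for f in first], dtype=float)

    def cycle(self, index: int) -> dict[str, Frame | dict[str, Frame]]:
        """Frames of one acquisition cycle, keyed by position."""
        if self.channel_mode == "full-frame":
            return {p: self.frames[p][index] for p in self.positions}
        return {
            p: {ch: stack[index] for ch, stack in self.channel_frames[p].items()}
            for p in self.positions
        }

    def channel_images(
        self, position: str, index: int, layout: ChannelLayout
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Per-channel sub-images of one frame, after splitting/registration.

        In pre-split mode the stored per-channel images are returned as-is
        (the splitter geometry does not apply).
        """
        if self.channel_mode == "full-frame":
            f = self.frames[position][index]
            return f.timestamp, split_frame(f.pixels, layout)
        stacks = self.channel_frames[position]
        images = {ch: stacks[ch][index].pixels for ch in stacks}
        t = next(iter(stacks.values()))[index].timestamp
        return t, images


@dataclass(frozen=True)
class StimulusEvent:
    label: str
    time: float
    is_maximizer: bool = False


@dataclass(frozen=True)
class EventTimeline:
    """Ordered stimulant additions; exactly one is the signal maximizer.

    The maximizer (typically IBMX, or IBMX + forskolin, added last) saturates
    the sensor and defines the 100 % reference for shift normalization.
    """

    events: tuple[StimulusEvent, ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("event timeline is empty; no response can be computed")
        times = [e.time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"event times must strictly increase, got {times}")
        n_max = sum(e.is_maximizer for e in self.events)
        if n_max != 1:
            raise ValueError(
                f"exactly one event must be flagged as maximizer, found {n_max}"
            )

    @property
    def maximizer(self) -> StimulusEvent:
        return next(e for e in self.events if e.is_maximizer)

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# acquisition loading


def _read_sidecar_timestamps(root: Path) -> dict[str, list[float]] | None:
    sidecar = root / TIMESTAMP_SIDECAR
    if not sidecar.is_file():
        return None
    data = json.loads(sidecar.read_text())
    return {str(k): [float(t) for t in v] for k, v in data.items()}


def _position_timestamps(
    sidecar: dict[str, list[float]] | None,
    position: str,
    n: int,
    interval: float,
) -> list[float]:
    if sidecar is not None and position in sidecar:
        ts = sidecar[position][:n]
        if len(ts) < n:
            raise ValueError(
                f"timestamp sidecar for position {position!r} has {len(ts)} "
                f"entries for {n} frames"
            )
        return ts
    return [i * interval for i in range(n)]


def load_acquisition(
    path: str | Path,
    *,
    dialect: str,
    interval: float = 1.0,
    channel_mode: str = "full-frame",
    positions: Sequence[str] | None = None,
    truncate_to_common: bool = False,
) -> Acquisition:
    """Load a multi-position time-lapse acquisition from disk.

    Parameters
    ----------
    path
        Acquisition root: a directory for the ``stack`` and ``frames``
        dialects, a single ``.ome.tif`` file for ``ome``.
    dialect
        One of ``stack`` / ``ome`` / ``frames``; never guessed.
    interval
        Nominal seconds per acquisition cycle, used to synthesize timestamps
        when no sidecar metadata is present.
    positions
        Declared position order; defaults to lexicographic order of what is
        found on disk.
    truncate_to_common
        Trim ragged position tails to the common frame count instead of
        raising.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == "ome":
        stacks = _load_ome(path)
        root = path.parent
    elif dialect == "stack":
        stacks = _load_stacks(path, channel_mode)
        root = path
    else:
        stacks = _load_frame_dirs(path)
        root = path

    found = sorted(stacks)
    if positions is not None:
        missing = [p for p in positions if p not in stacks]
        if missing:
            raise FileNotFoundError(
                f"position(s) {missing} not found under {path} (found {found})"
            )
        order = list(positions)
    else:
        order = found
    if not order:
        raise FileNotFoundError(f"no positions found under {path}")

    if channel_mode == "pre-split":
        counts = {
            p: min(len(s) for s in stacks[p].values()) for p in order  # type: ignore[union-attr]
        }
    else:
        counts = {p: len(stacks[p]) for p in order}
    common = min(counts.values())
    if len(set(counts.values())) > 1 and not truncate_to_common:
        ragged = sorted(p for p, c in counts.items() if c != max(counts.values()))
        raise ValueError(
            f"positions have unequal frame counts {counts}; "
            f"offending position(s): {ragged} "
            f"(pass truncate_to_common=True to trim to {common})"
        )

    sidecar = _read_sidecar_timestamps(root)
    if channel_mode == "pre-split":
        channel_frames: dict[str, dict[str, list[Frame]]] = {}
        for pos in order:
            ts = _position_timestamps(sidecar, pos, common, interval)
            channel_frames[pos] = {
                ch: [
                    Frame(arr, ts[k], pos, k, channel=ch)
                    for k, arr in enumerate(stack[:common])
                ]
                for ch, stack in stacks[pos].items()  # type: ignore[union-attr]
            }
        return Acquisition(
            positions=order,
            interval=interval,
            channel_mode="pre-split",
            channel_frames=channel_frames,
        )

    frames: dict[str, list[Frame]] = {}
    for pos in order:
        ts = _position_timestamps(sidecar, pos, common, interval)
        frames[pos] = [
            Frame(arr, ts[k], pos, k) for k, arr in enumerate(stacks[pos][:common])
        ]
    return Acquisition(
        positions=order, interval=interval, channel_mode="full-frame", frames=frames
    )


def _load_stacks(path: Path, channel_mode: str):
    """``stack`` dialect: one multipage TIFF per position.

    Full-frame: ``<root>/<position>.tif``.  Pre-split: ``<root>/<position>/``
    containing one ``<channel>.tif`` stack per channel.
    """
    if not path.is_dir():
        raise FileNotFoundError(f"acquisition directory not found: {path}")
    if channel_mode == "pre-split":
        out: dict[str, dict[str, list[np.ndarray]]] = {}
        for pos_dir in sorted(p for p in path.iterdir() if p.is_dir()):
            channels = {}
            for f in sorted(pos_dir.glob("*.tif*")):
                channels[f.name.split(".")[0]] = _as_pages(tifffile.imread(f))
            if channels:
                out[pos_dir.name] = channels
        return out
    out2: dict[str, list[np.ndarray]] = {}
    for f in sorted(path.glob("*.tif*")):
        out2[f.name.split(".")[0]] = _as_pages(tifffile.imread(f))
    return out2


def _as_pages(arr: np.ndarray) -> list[np.ndarray]:
    arr = np.asarray(arr)
    if arr.ndim == 2:
        return [arr]
    if arr.ndim == 3:
        return [arr[k] for k in range(arr.shape[0])]
    raise ValueError(f"unsupported stack shape {arr.shape}")


def _load_frame_dirs(path: Path) -> dict[str, list[np.ndarray]]:
    """``frames`` dialect: ``<root>/<position>/t####.tif``, one per cycle."""
    if not path.is_dir():
        raise FileNotFoundError(f"acquisition directory not found: {path}")
    out: dict[str, list[np.ndarray]] = {}
    for pos_dir in sorted(p for p in path.iterdir() if p.is_dir()):
        files = sorted(pos_dir.glob("*.tif*"))
        if files:
            out[pos_dir.name] = [tifffile.imread(f) for f in files]
    return out


def _load_ome(path: Path) -> dict[str, list[np.ndarray]]:
    """``ome`` dialect: single OME-TIFF, one series per position."""
    if not path.is_file():
        raise FileNotFoundError(f"OME-TIFF file not found: {path}")
    out: dict[str, list[np.ndarray]] = {}
    with tifffile.TiffFile(path) as tif:
        for i, series in enumerate(tif.series):
            name = series.name if series.name and series.name != "" else f"P{i:02d}"
            out[str(name)] = _as_pages(series.asarray())
    return out


# ---------------------------------------------------------------------------
# event timeline I/O

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f", ""}


def _parse_flag(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if np.isnan(value):
            return False
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise ValueError(f"cannot interpret is_maximizer value {value!r}")


def load_events(path: str | Path) -> EventTimeline:
    """Read a stimulant timeline CSV (``label,time_seconds,is_maximizer``).

    If no row is flagged as maximizer the last event is flagged, with a
    logged warning (the protocol convention: the saturating stimulant is
    added last).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"event file not found: {path}")
    table = pd.read_csv(path)
    required = {"label", "time_seconds"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"event file {path} must have columns label,time_seconds"
            f"[,is_maximizer]; found {list(table.columns)}"
        )
    if len(table) == 0:
        raise ValueError(f"event file {path} contains zero events")
    flags = (
        [_parse_flag(v) for v in table["is_maximizer"]]
        if "is_maximizer" in table.columns
        else [False] * len(table)
    )
    if sum(flags) == 0:
        logger.warning(
            "no event flagged as maximizer in %s; defaulting to the last "
            "event (%r)",
            path,
            str(table["label"].iloc[-1]),
        )
        flags[-1] = True
    events = tuple(
        StimulusEvent(str(lbl), float(t), bool(fl))
        for lbl, t, fl in zip(table["label"], table["time_seconds"], flags)
    )
    return EventTimeline(events)


def write_events(timeline: EventTimeline, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "label": [e.label for e in timeline],
            "time_seconds": [e.time for e in timeline],
            "is_maximizer": [e.is_maximizer for e in timeline],
        }
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# trace tables


def trace_table(traces: Sequence["RatioTrace"]) -> pd.DataFrame:
    """Tabulate the traces of one position: time plus five columns per ROI
    (donor mean, donor background, acceptor mean, acceptor background,
    ratio), keeping every intermediate mean for auditability."""
    if not traces:
        raise ValueError("no traces to tabulate")
    positions = {t.position_id for t in traces}
    if len(positions) > 1:
        raise ValueError(f"traces span multiple positions: {sorted(positions)}")
    times = traces[0].times
    for t in traces[1:]:
        if len(t.times) != len(times) or not np.array_equal(
            t.times, times, equal_nan=True
        ):
            raise ValueError("traces of one position must share a common timeline")
    data: dict[str, np.ndarray] = {"time": times}
    for t in traces:
        data[f"{t.roi_name}_donor_mean"] = t.donor_means
        data[f"{t.roi_name}_donor_bg"] = t.donor_bg_means
        data[f"{t.roi_name}_acceptor_mean"] = t.acceptor_means
        data[f"{t.roi_name}_acceptor_bg"] = t.acceptor_bg_means
        data[f"{t.roi_name}_ratio"] = t.ratios
    return pd.DataFrame(data)


def write_traces(
    traces: Sequence["RatioTrace"], path: str | Path, *, prefix: str = "traces_"
) -> list[Path]:
    """Write one CSV table per position under directory ``path``.

    Values are written with shortest round-trip float formatting, so reading
    the table back reproduces the stored doubles exactly.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("empty trace collection; nothing written")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    by_pos: dict[str, list] = {}
    for t in traces:
        by_pos.setdefault(t.position_id, []).append(t)
    for pos in sorted(by_pos):
        table = trace_table(by_pos[pos])
        out = path / f"{prefix}{pos}.csv"
        tmp = out.with_suffix(".csv.tmp")
        # 17 significant digits round-trip any float64 exactly
        table.to_csv(tmp, index=False, float_format=lambda v: format(v, ".17g"))
        tmp.replace(out)  # atomic on POSIX: readers never see partial tables
        written.append(out)
    return written


def read_trace_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# workbook export


def _summary_rows(summaries: Sequence["ResponseSummary"]) -> list[list]:
    rows = []
    for s in summaries:
        for r in s.responses:
            rows.append(
                [
                    s.position_id,
                    s.roi_name,
                    r.label,
                    s.p_base,
                    r.p_stim,
                    r.c,
                    r.percent_shift,
                    bool(r.is_maximizer),
                    s.window,
                ]
            )
    return rows


SUMMARY_HEADER = [
    "position",
    "roi",
    "event",
    "P_base",
    "P_stim",
    "C",
    "percent_fret_shift",
    "is_maximizer",
    "window",
]


def write_workbook(
    summaries: Sequence["ResponseSummary"],
    traces: Sequence["RatioTrace"],
    out_path: str | Path,
    *,
    template: str | Path | None = None,
    raw_sheet: str = "RawData",
    summary_sheet: str = "Summary",
) -> Path:
    """Export traces and response summaries to an xlsx workbook.

    Without a template: one raw-trace sheet per position plus one summary
    sheet.  With a template: the raw data (all positions, stacked, with a
    position column) is injected into the reserved ``raw_sheet``, the
    summary is (re)written to ``summary_sheet``, and every other sheet —
    user formulas, charts — is left untouched.
    """
    import openpyxl

    out_path = Path(out_path)
    traces = list(traces)
    summaries = list(summaries)
    by_pos: dict[str, list] = {}
    for t in traces:
        by_pos.setdefault(t.position_id, []).append(t)

    if template is not None:
        template = Path(template)
        if not template.is_file():
            raise FileNotFoundError(f"workbook template not found: {template}")
        wb = openpyxl.load_workbook(template)
        if raw_sheet not in wb.sheetnames:
            raise ValueError(
                f"template {template} is missing the reserved raw-data sheet "
                f"{raw_sheet!r} (sheets present: {wb.sheetnames})"
            )
        ws = wb[raw_sheet]
        ws.delete_rows(1, ws.max_row)
        header_written = False
        for pos in sorted(by_pos):
            table = trace_table(by_pos[pos])
            if not header_written:
                ws.append(["position"] + list(table.columns))
                header_written = True
            for row in table.itertuples(index=False):
                ws.append([pos] + [_cell(v) for v in row])
    else:
        wb = openpyxl.Workbook()
        wb.remove(wb.active)
        for pos in sorted(by_pos):
            ws = wb.create_sheet(f"raw_{pos}"[:31])
            table = trace_table(by_pos[pos])
            ws.append(list(table.columns))
            for row in table.itertuples(index=False):
                ws.append([_cell(v) for v in row])

    if summary_sheet in wb.sheetnames:
        wb.remove(wb[summary_sheet])
    ws = wb.create_sheet(summary_sheet)
    ws.append(SUMMARY_HEADER)
    for row in _summary_rows(summaries):
        ws.append([_cell(v) for v in row])

    wb.save(out_path)
    return out_path


def _cell(v):
    """Coerce numpy scalars to plain Python for openpyxl."""
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and np.isnan(v):
        return None
    return v
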