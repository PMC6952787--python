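"""Per-ROI intensities and background-corrected FRET ratios.

The core quantities of ratiometric FRET imaging:

* the mean intensity of a region of interest,
  ``F_bar = (1/n) * sum(x_i)`` over the ``n`` masked pixels;
* the background-corrected ratio of the two channels,
  ``FRET = (F_donor - F_donor_bg) / (F_acceptor - F_acceptor_bg)``
  (or the reciprocal arrangement for sensors reported as acceptor/donor,
  e.g. a YFP/CFP ratio).

Background is measured from a dedicated background ROI per channel on every
frame, not from a fixed scalar, so slow lamp drift and constant camera
offsets are absorbed by the subtraction.

Traces can be built in batch (:func:`compute_traces`) or streamed one
acquisition cycle at a time (:func:`update_traces`); both run the identical
per-frame code path, so streaming and batch results are bitwise equal.
Frames with a non-positive corrected denominator yield a missing value (NaN)
plus a logged warning rather than aborting a long live acquisition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .acquisition_io import Acquisition, Frame
from .channel_split import ChannelLayout

logger = logging.getLogger(__name__)

__all__ = [
    "ROI",
    "ROISet",
    "RatioTrace",
    "roi_mean",
    "fret_ratio",
    "init_traces",
    "update_traces",
    "compute_traces",
    "load_rois",
    "save_rois",
    "ORIENTATIONS",
]

ORIENTATIONS = ("donor/acceptor", "acceptor/donor")

#: key in a background-ROI mapping meaning "one mask applied to each channel"
SHARED = "shared"


# ---------------------------------------------------------------------------
# ROI model


@dataclass(frozen=True)
class ROI:
    """A named pixel mask in sub-image (post-split, post-registration)
    coordinates, stored as run-length rows ``(row, col_start, length)``."""

    name: str
    runs: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError(f"ROI {self.name!r} is empty")
        for row, col, length in self.runs:
            if row < 0 or col < 0 or length <= 0:
                raise ValueError(
                    f"ROI {self.name!r} has invalid run {(row, col, length)}"
                )

    @classmethod
    def from_rect(cls, name: str, row0: int, col0: int, height: int, width: int) -> "ROI":
        """Rectangle ``[row0, row0+height) x [col0, col0+width)`` (half-open)."""
        if height <= 0 or width <= 0:
            raise ValueError(f"ROI {name!r}: rectangle must have positive size")
        return cls(name, tuple((row0 + r, col0, width) for r in range(height)))

    @classmethod
    def from_mask(cls, name: str, mask: np.ndarray) -> "ROI":
        mask = np.asarray(mask, dtype=bool)
        runs: list[tuple[int, int, int]] = []
        for r in range(mask.shape[0]):
            row = mask[r]
            # run boundaries from the padded difference of the boolean row
            d = np.diff(np.concatenate(([0], row.view(np.int8), [0])))
            starts = np.nonzero(d == 1)[0]
            ends = np.nonzero(d == -1)[0]
            runs.extend((r, int(s), int(e - s)) for s, e in zip(starts, ends))
        return cls(name, tuple(runs))

    @property
    def n_pixels(self) -> int:
        return sum(length for _, _, length in self.runs)

    def bounds(self) -> tuple[int, int]:
        """Exclusive (max_row+1, max_col+1) the mask requires."""
        return (
            max(r for r, _, _ in self.runs) + 1,
            max(c + n for _, c, n in self.runs),
        )

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        hmax, wmax = self.bounds()
        if hmax > shape[0] or wmax > shape[1]:
            raise ValueError(
                f"ROI {self.name!r} (extent {hmax}x{wmax}) exceeds sub-image "
                f"bounds {shape[0]}x{shape[1]}"
            )
        mask = np.zeros(shape, dtype=bool)
        for row, col, length in self.runs:
            mask[row, col : col + length] = True
        return mask

    def to_dict(self) -> dict:
        return {"type": "rle", "runs": [list(r) for r in self.runs]}

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "ROI":
        kind = d.get("type", "rect")
        if kind == "rect":
            return cls.from_rect(
                name, int(d["row0"]), int(d["col0"]), int(d["height"]), int(d["width"])
            )
        if kind == "rle":
            return cls(name, tuple((int(r), int(c), int(n)) for r, c, n in d["runs"]))
        raise ValueError(f"ROI {name!r}: unknown type {kind!r}")


@dataclass
class ROISet:
    """Signal and background ROIs of one stage position.

    ``background_rois`` is keyed by channel name, or by ``"shared"`` for a
    single mask applied to every channel.
    """

    position_id: str
    signal_rois: dict[str, ROI]
    background_rois: dict[str, ROI]
    _overlap_checked: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.signal_rois:
            raise ValueError(f"position {self.position_id!r} has no signal ROIs")
        if not self.background_rois:
            raise ValueError(f"position {self.position_id!r} has no background ROI")

    def background_for(self, channel: str) -> ROI:
        if channel in self.background_rois:
            return self.background_rois[channel]
        if SHARED in self.background_rois:
            return self.background_rois[SHARED]
        raise KeyError(
            f"position {self.position_id!r}: no background ROI for channel "
            f"{channel!r} and no shared background"
        )

    def check_overlap(self, shape: tuple[int, int]) -> None:
        """Warn (once) if any background mask overlaps a signal mask."""
        if self._overlap_checked:
            return
        self._overlap_checked = True
        signal = np.zeros(shape, dtype=bool)
        for roi in self.signal_rois.values():
            signal |= roi.to_mask(shape)
        for key, roi in self.background_rois.items():
            if np.any(signal & roi.to_mask(shape)):
                logger.warning(
                    "position %r: background ROI %r overlaps a signal ROI; "
                    "background subtraction will be biased",
                    self.position_id,
                    key,
                )


def load_rois(path: str | Path) -> dict[str, ROISet]:
    """Read the JSON ROI file: per position, named signal ROIs and one
    background ROI per channel (or a shared one)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"ROI file not found: {path}")
    data = json.loads(path.read_text())
    out: dict[str, ROISet] = {}
    for pos, block in data["positions"].items():
        signal = {n: ROI.from_dict(n, d) for n, d in block["signal"].items()}
        background = {k: ROI.from_dict(k, d) for k, d in block["background"].items()}
        out[str(pos)] = ROISet(str(pos), signal, background)
    return out


def save_rois(rois: Mapping[str, ROISet], path: str | Path) -> Path:
    path = Path(path)
    data = {
        "positions": {
            pos: {
                "signal": {n: r.to_dict() for n, r in rs.signal_rois.items()},
                "background": {k: r.to_dict() for k, r in rs.background_rois.items()},
            }
            for pos, rs in rois.items()
        }
    }
    path.write_text(json.dumps(data, indent=1))
    return path


# ---------------------------------------------------------------------------
# primitives


def roi_mean(image: np.ndarray, mask: np.ndarray | ROI) -> float:
    """Mean intensity over the masked pixels: ``(1/n) * sum(x_i)``.

    Camera counts are summed in float64 regardless of the input bit depth.
    """
    image = np.asarray(image)
    if isinstance(mask, ROI):
        mask = mask.to_mask(image.shape)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape:
            raise ValueError(
                f"mask shape {mask.shape} exceeds or mismatches image bounds "
                f"{image.shape}"
            )
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty ROI mask")
    return float(image[mask].astype(np.float64).sum() / n)


def fret_ratio(
    donor_mean: float,
    donor_bg: float,
    acceptor_mean: float,
    acceptor_bg: float,
    orientation: str = "donor/acceptor",
    *,
    context: str = "",
) -> float:
    """Background-corrected channel ratio for one frame.

    ``donor/acceptor`` returns
    ``(donor_mean - donor_bg) / (acceptor_mean - acceptor_bg)``;
    ``acceptor/donor`` the reciprocal arrangement.  A non-positive corrected
    denominator yields NaN (a missing trace value) with a logged warning; a
    negative corrected numerator is computed as-is with a warning.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(
            f"unknown orientation {orientation!r}; expected one of {ORIENTATIONS}"
        )
    donor = donor_mean - donor_bg
    acceptor = acceptor_mean - acceptor_bg
    num, den = (donor, acceptor) if orientation == "donor/acceptor" else (acceptor, donor)
    if den <= 0:
        logger.warning(
            "non-positive corrected denominator (%.6g) %s; recording missing value",
            den,
            context or "in fret_ratio",
        )
        return float("nan")
    if num < 0:
        logger.warning(
            "negative corrected numerator (%.6g) %s", num, context or "in fret_ratio"
        )
    return num / den


# ---------------------------------------------------------------------------
# traces


@dataclass
class RatioTrace:
    """Per-ROI time series of background-corrected FRET ratios, carrying the
    four per-frame channel means it was computed from (auditability: the
    ratio is recomputable from the stored means)."""

    roi_name: str
    position_id: str
    orientation: str = "donor/acceptor"
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    donor_means: np.ndarray = field(default_factory=lambda: np.empty(0))
    donor_bg_means: np.ndarray = field(default_factory=lambda: np.empty(0))
    acceptor_means: np.ndarray = field(default_factory=lambda: np.empty(0))
    acceptor_bg_means: np.ndarray = field(default_factory=lambda: np.empty(0))
    ratios: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        lengths = {
            len(a)
            for a in (
                self.times,
                self.donor_means,
                self.donor_bg_means,
                self.acceptor_means,
                self.acceptor_bg_means,
                self.ratios,
            )
        }
        if len(lengths) != 1:
            raise ValueError("per-frame arrays of a trace must share one length")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of frames with a defined (non-missing) ratio."""
        return ~np.isnan(self.ratios)

    def append(
        self,
        time: float,
        donor_mean: float,
        donor_bg: float,
        acceptor_mean: float,
        acceptor_bg: float,
        ratio: float,
    ) -> None:
        self.times = np.append(self.times, time)
        self.donor_means = np.append(self.donor_means, donor_mean)
        self.donor_bg_means = np.append(self.donor_bg_means, donor_bg)
        self.acceptor_means = np.append(self.acceptor_means, acceptor_mean)
        self.acceptor_bg_means = np.append(self.acceptor_bg_means, acceptor_bg)
        self.ratios = np.append(self.ratios, ratio)

    def scaled(self, k: float) -> "RatioTrace":
        """A copy with every ratio multiplied by ``k`` (means untouched are
        meaningless, so they are scaled consistently on the numerator side)."""
        return replace(
            self,
            donor_means=self.donor_bg_means + (self.donor_means - self.donor_bg_means) * k,
            ratios=self.ratios * k,
        )


def _saturation_limit(dtype: np.dtype) -> int | None:
    if np.issubdtype(dtype, np.integer):
        return int(np.iinfo(dtype).max)
    return None


def _measure_frame(
    images: Mapping[str, np.ndarray],
    roiset: ROISet,
    layout: ChannelLayout,
    orientation: str,
    saturation_threshold: float,
) -> dict[str, tuple[float, float, float, float, float]]:
    """Measure all signal ROIs of one position on one frame's channel images."""
    donor_img = images[layout.donor]
    acceptor_img = images[layout.acceptor]
    shape = donor_img.shape
    roiset.check_overlap(shape)
    donor_bg = roi_mean(donor_img, roiset.background_for(layout.donor))
    acceptor_bg = roi_mean(acceptor_img, roiset.background_for(layout.acceptor))
    limit = _saturation_limit(np.asarray(donor_img).dtype)
    out = {}
    for name, roi in roiset.signal_rois.items():
        mask = roi.to_mask(shape)
        if limit is not None and saturation_threshold is not None:
            n_sat = int((donor_img[mask] == limit).sum()) + int(
                (acceptor_img[mask] == limit).sum()
            )
            frac = n_sat / (2 * roi.n_pixels)
            if frac > saturation_threshold:
                logger.warning(
                    "position %r ROI %r: %.1f%% of pixels at the bit-depth "
                    "maximum (%d); mean intensity is biased",
                    roiset.position_id,
                    name,
                    100 * frac,
                    limit,
                )
        d = roi_mean(donor_img, mask)
        a = roi_mean(acceptor_img, mask)
        ratio = fret_ratio(
            d,
            donor_bg,
            a,
            acceptor_bg,
            orientation,
            context=f"at position {roiset.position_id!r} ROI {name!r}",
        )
        out[name] = (d, donor_bg, a, acceptor_bg, ratio)
    return out


def init_traces(
    rois: Mapping[str, ROISet], orientation: str = "donor/acceptor"
) -> list[RatioTrace]:
    """Empty traces, one per (position, signal ROI), in position order."""
    traces = []
    for pos, roiset in rois.items():
        for name in roiset.signal_rois:
            traces.append(RatioTrace(roi_name=name, position_id=pos, orientation=orientation))
    return traces


def update_traces(
    traces: Sequence[RatioTrace],
    cycle_frames: Mapping[str, Frame | Mapping[str, Frame] | None],
    layout: ChannelLayout,
    rois: Mapping[str, ROISet],
    *,
    saturation_threshold: float = 0.01,
) -> list[RatioTrace]:
    """Extend every trace by the one acquisition cycle in ``cycle_frames``.

    ``cycle_frames`` maps every position to its new frame (a full camera
    :class:`~multifret.acquisition_io.Frame`, a per-channel frame mapping in
    pre-split mode, or ``None`` for a corrupt/lost frame, which is recorded
    as a missing value).  The cycle must cover all positions, and each new
    frame's ``frame_index`` must equal the current trace length: the stage
    visits every position once per cycle, in order.

    After any number of cycles the traces are element-wise identical to a
    from-scratch batch computation on the full acquisition.
    """
    traces = list(traces)
    positions = {t.position_id for t in traces}
    missing = positions - set(cycle_frames)
    if missing:
        raise ValueError(
            f"cycle must cover all positions; missing frame(s) for {sorted(missing)}"
        )
    by_pos: dict[str, list[RatioTrace]] = {}
    for t in traces:
        by_pos.setdefault(t.position_id, []).append(t)

    for pos, pos_traces in by_pos.items():
        expected = len(pos_traces[0])
        item = cycle_frames[pos]
        if item is None:
            # corrupt or lost frame: keep the timeline, record missing values
            t_guess = float(expected)
            if expected > 0:
                t_guess = float(pos_traces[0].times[-1]) + (
                    float(np.diff(pos_traces[0].times).mean()) if expected > 1 else 1.0
                )
            for t in pos_traces:
                t.append(t_guess, np.nan, np.nan, np.nan, np.nan, np.nan)
            continue
        if isinstance(item, Frame):
            idx, timestamp = item.frame_index, item.timestamp
            images = None
        else:
            first = next(iter(item.values()))
            idx, timestamp = first.frame_index, first.timestamp
            images = {ch: f.pixels for ch, f in item.items()}
        if idx != expected:
            raise ValueError(
                f"out-of-order frame for position {pos!r}: got frame_index "
                f"{idx}, expected {expected}"
            )
        if images is None:
            from .channel_split import split_frame

            images = split_frame(item.pixels, layout)
        measured = _measure_frame(
            images, rois[pos], layout, pos_traces[0].orientation, saturation_threshold
        )
        for t in pos_traces:
            d, dbg, a, abg, ratio = measured[t.roi_name]
            t.append(timestamp, d, dbg, a, abg, ratio)
    return traces


def compute_traces(
    acq: Acquisition,
    layout: ChannelLayout,
    rois: Mapping[str, ROISet],
    orientation: str = "donor/acceptor",
    *,
    saturation_threshold: float = 0.01,
) -> list[RatioTrace]:
    """Batch computation of all ratio traces of an acquisition.

    Implemented as repeated single-cycle updates, which is what makes the
    streaming-equals-batch contract structural rather than coincidental.
    """
    missing = [p for p in acq.positions if p not in rois]
    if missing:
        raise ValueError(f"no ROISet for position(s) {missing}")
    ordered = {p: rois[p] for p in acq.positions}
    traces = init_traces(ordered, orientation)
    for k in range(acq.n_frames()):
        update_traces(
            traces,
            acq.cycle(k),
            layout,
            ordered,
            saturation_threshold=saturation_threshold,
        )
    return traces
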