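"""Beam-splitter channel geometry.

An image splitter (e.g. a QuadView) projects spectrally separated copies of
the field of view onto fixed blocks of a single camera sensor.  This module
maps a full camera frame onto named spectral sub-images according to that
block geometry, optionally applying per-channel integer registration shifts,
and provides a brute-force normalized-cross-correlation offset estimator for
channels that are not perfectly co-registered.

Conventions (fixed so ROI masks are portable):

* quadrants are indexed row-major from the top-left, 0-based;
* pixel coordinates are ``(row, col)``, 0-based, half-open blocks;
* an offset ``(dy, dx)`` for a channel is the displacement of that channel's
  content relative to the reference channel; ``split_frame`` undoes it.

Registration is integer-pixel only: sub-pixel shifts would interpolate raw
counts before they are averaged, which the ratio computation must avoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelLayout", "split_frame", "estimate_offset", "layout_from_dict"]

#: quadrant name meaning "not collected"
UNUSED = "unused"


@dataclass(frozen=True)
class ChannelLayout:
    """Mapping from camera-frame quadrants to named spectral channels.

    Parameters
    ----------
    assignments
        Quadrant index (row-major, 0-based) -> channel name, or ``"unused"``.
    roles
        ``{"donor": <channel>, "acceptor": <channel>}`` — which channels feed
        the numerator and denominator of the FRET ratio.
    grid
        ``(rows, cols)`` of the splitter partition; ``(2, 2)`` for a QuadView.
    offsets
        Per-channel integer ``(dy, dx)`` registration shift; channels absent
        from the mapping are taken as ``(0, 0)``.
    """

    assignments: dict[int, str]
    roles: dict[str, str]
    grid: tuple[int, int] = (2, 2)
    offsets: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rows, cols = self.grid
        if rows < 1 or cols < 1:
            raise ValueError(f"layout grid must be positive, got {self.grid}")
        n_quadrants = rows * cols
        used: list[str] = []
        for q, name in self.assignments.items():
            if not (0 <= q < n_quadrants):
                raise ValueError(
                    f"quadrant index {q} outside grid of {n_quadrants} quadrants"
                )
            if name != UNUSED:
                used.append(name)
        if len(set(used)) != len(used):
            raise ValueError(f"duplicate channel names in assignments: {used}")
        for role in ("donor", "acceptor"):
            if role not in self.roles:
                raise ValueError(f"layout roles must define {role!r}")
            if self.roles[role] not in used:
                raise ValueError(
                    f"{role} role references channel {self.roles[role]!r} "
                    f"which is not assigned to any quadrant"
                )
        if self.roles["donor"] == self.roles["acceptor"]:
            raise ValueError("donor and acceptor must be distinct channels")
        for name, (dy, dx) in self.offsets.items():
            if int(dy) != dy or int(dx) != dx:
                raise ValueError(f"offset for {name!r} must be integer pixels")

    @property
    def channels(self) -> tuple[str, ...]:
        """Assigned channel names, in quadrant order."""
        return tuple(
            name for _, name in sorted(self.assignments.items()) if name != UNUSED
        )

    @property
    def donor(self) -> str:
        return self.roles["donor"]

    @property
    def acceptor(self) -> str:
        return self.roles["acceptor"]

    def offset(self, channel: str) -> tuple[int, int]:
        dy, dx = self.offsets.get(channel, (0, 0))
        return int(dy), int(dx)


def layout_from_dict(d: dict) -> ChannelLayout:
    """Build a :class:`ChannelLayout` from a config-file mapping."""
    return ChannelLayout(
        assignments={int(k): str(v) for k, v in d["assignments"].items()},
        roles={str(k): str(v) for k, v in d["roles"].items()},
        grid=tuple(d.get("grid", (2, 2))),  # type: ignore[arg-type]
        offsets={str(k): (int(v[0]), int(v[1])) for k, v in d.get("offsets", {}).items()},
    )


def split_frame(pixels: np.ndarray, layout: ChannelLayout) -> dict[str, np.ndarray]:
    """Split one camera frame into registered per-channel sub-images.

    Quadrant ``(r, c)`` covers the half-open block
    ``[r*H/rows, (r+1)*H/rows) x [c*W/cols, (c+1)*W/cols)``.  Each channel's
    registration offset is undone by an integer shift, and a margin of
    ``max|dy|`` rows / ``max|dx|`` cols is cropped symmetrically from every
    channel so all sub-images share a common size.

    Returns ``{channel name: sub-image}`` (views into ``pixels``).
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError(f"frame must be 2-D, got shape {pixels.shape}")
    h, w = pixels.shape
    rows, cols = layout.grid
    if h % rows != 0 or w % cols != 0:
        raise ValueError(
            f"frame shape {h}x{w} not divisible by layout grid {rows}x{cols}: "
            f"height must be a multiple of {rows} and width of {cols}"
        )
    qh, qw = h // rows, w // cols

    names = layout.channels
    my = max((abs(layout.offset(n)[0]) for n in names), default=0)
    mx = max((abs(layout.offset(n)[1]) for n in names), default=0)
    for n in names:
        dy, dx = layout.offset(n)
        if abs(dy) >= qh or abs(dx) >= qw:
            raise ValueError(
                f"offset {(dy, dx)} for channel {n!r} exceeds quadrant size {qh}x{qw}"
            )
    if 2 * my >= qh or 2 * mx >= qw:
        raise ValueError(
            f"registration margins ({my}, {mx}) leave no pixels in a "
            f"{qh}x{qw} quadrant"
        )

    out: dict[str, np.ndarray] = {}
    for q, name in layout.assignments.items():
        if name == UNUSED:
            continue
        r, c = divmod(q, cols)
        sub = pixels[r * qh : (r + 1) * qh, c * qw : (c + 1) * qw]
        dy, dx = layout.offset(name)
        out[name] = sub[my + dy : qh - my + dy, mx + dx : qw - mx + dx]
    return out


def estimate_offset(
    reference_sub: np.ndarray, target_sub: np.ndarray, max_shift: int = 16
) -> tuple[int, int]:
    """Estimate the integer displacement of ``target_sub`` relative to
    ``reference_sub`` by exhaustive normalized cross-correlation.

    Searches all shifts with ``|dy|, |dx| <= max_shift`` and returns the one
    maximizing the Pearson correlation of the overlapping region.  Ties are
    broken toward smaller ``|dy|+|dx|``, then smaller ``dy``, then smaller
    ``dx``.  If ``target = shift(reference, (dy, dx))`` the estimate is
    exactly ``(dy, dx)``.

    Raises ``ValueError`` for flat (zero-variance) images, which carry no
    registration information.
    """
    ref = np.asarray(reference_sub, dtype=np.float64)
    tgt = np.asarray(target_sub, dtype=np.float64)
    if ref.shape != tgt.shape:
        raise ValueError(f"sub-image shapes differ: {ref.shape} vs {tgt.shape}")
    if ref.ndim != 2:
        raise ValueError("sub-images must be 2-D")
    if np.ptp(ref) == 0 or np.ptp(tgt) == 0:
        raise ValueError("cannot register featureless image (zero variance)")
    h, w = ref.shape
    if max_shift < 0 or max_shift >= min(h, w):
        raise ValueError(f"max_shift={max_shift} out of range for {h}x{w} images")

    best_key: tuple | None = None
    best_shift = (0, 0)
    for dy in range(-max_shift, max_shift + 1):
        y0, y1 = max(0, dy), h + min(0, dy)
        for dx in range(-max_shift, max_shift + 1):
            x0, x1 = max(0, dx), w + min(0, dx)
            a = ref[y0 - dy : y1 - dy, x0 - dx : x1 - dx]
            b = tgt[y0:y1, x0:x1]
            if a.size < 2:
                continue
            a = a - a.mean()
            b = b - b.mean()
            denom = np.sqrt((a * a).sum() * (b * b).sum())
            if denom == 0.0:
                continue
            ncc = float((a * b).sum() / denom)
            # larger ncc wins; ties prefer small |dy|+|dx|, then small dy, dx
            key = (round(ncc, 12), -(abs(dy) + abs(dx)), -dy, -dx)
            if best_key is None or key > best_key:
                best_key = key
                best_shift = (dy, dx)
    if best_key is None:
        raise ValueError("no valid overlap found within max_shift window")
    return best_shift
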