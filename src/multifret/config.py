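"""Run configuration: one YAML file describing a complete analysis.

Paths inside the file are resolved relative to the file's own directory, so
a rendered dataset directory is self-contained.  The effective (resolved)
configuration is written into the output directory of every run for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .channel_split import ChannelLayout, layout_from_dict
from .response_stats import DEFAULT_WINDOW

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    acquisition_path: Path
    dialect: str
    rois_path: Path
    events_path: Path
    output_dir: Path
    layout: ChannelLayout
    interval: float = 1.0
    channel_mode: str = "full-frame"
    positions: list[str] | None = None
    truncate_to_common: bool = False
    orientation: str = "donor/acceptor"
    plateau_window: int = DEFAULT_WINDOW
    saturation_threshold: float = 0.01
    template_path: Path | None = None
    template_raw_sheet: str = "RawData"
    summary_sheet: str = "Summary"
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "acquisition": {
                "path": str(self.acquisition_path),
                "dialect": self.dialect,
                "channel_mode": self.channel_mode,
                "interval": self.interval,
                "positions": self.positions,
                "truncate_to_common": self.truncate_to_common,
            },
            "layout": {
                "grid": list(self.layout.grid),
                "assignments": {int(k): v for k, v in self.layout.assignments.items()},
                "roles": dict(self.layout.roles),
                "offsets": {k: list(v) for k, v in self.layout.offsets.items()},
            },
            "rois": str(self.rois_path),
            "events": str(self.events_path),
            "output": str(self.output_dir),
            "orientation": self.orientation,
            "plateau_window": self.plateau_window,
            "saturation_threshold": self.saturation_threshold,
            "template": None if self.template_path is None else str(self.template_path),
            "template_raw_sheet": self.template_raw_sheet,
            "summary_sheet": self.summary_sheet,
        }

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict()))
        return path


def load_config(path: str | Path) -> RunConfig:
    """Parse a run-configuration YAML file (see the rendered ``config.yaml``
    of any simulated dataset for the schema)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    base = path.parent

    def resolve(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    try:
        acq = raw["acquisition"]
        layout = layout_from_dict(raw["layout"])
        cfg = RunConfig(
            acquisition_path=resolve(acq["path"]),
            dialect=str(acq["dialect"]),
            interval=float(acq.get("interval", 1.0)),
            channel_mode=str(acq.get("channel_mode", "full-frame")),
            positions=(
                [str(p) for p in acq["positions"]]
                if acq.get("positions") is not None
                else None
            ),
            truncate_to_common=bool(acq.get("truncate_to_common", False)),
            rois_path=resolve(raw["rois"]),
            events_path=resolve(raw["events"]),
            output_dir=resolve(raw.get("output", "analysis")),
            layout=layout,
            orientation=str(raw.get("orientation", "donor/acceptor")),
            plateau_window=int(raw.get("plateau_window", DEFAULT_WINDOW)),
            saturation_threshold=float(raw.get("saturation_threshold", 0.01)),
            template_path=(
                resolve(raw["template"]) if raw.get("template") else None
            ),
            template_raw_sheet=str(raw.get("template_raw_sheet", "RawData")),
            summary_sheet=str(raw.get("summary_sheet", "Summary")),
        )
    except KeyError as err:
        raise ValueError(f"config {path} is missing required key {err}") from err
    if cfg.orientation not in ("donor/acceptor", "acceptor/donor"):
        raise ValueError(f"config orientation {cfg.orientation!r} is invalid")
    if cfg.plateau_window < 1:
        raise ValueError("config plateau_window must be >= 1")
    return cfg
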