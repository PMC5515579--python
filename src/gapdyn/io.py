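"""Table and image IO plus run manifests.

Units are spelled out in column headers; every CLI run emits exactly one
JSON manifest tying the outputs to the configuration hash and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .ms2 import APAxisCalibration, MovieStack
from .profiles import NuclearRecord


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int | None
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    package_version: str = __version__
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        self.timestamp = datetime.now(timezone.utc).isoformat()
        Path(path).write_text(json.dumps(asdict(self), indent=1))


# -- tables -----------------------------------------------------------------


def spots_to_frame(spots_by_frame: list) -> pd.DataFrame:
    rows = [
        {"frame": s.frame_index, "x_px": s.x, "y_px": s.y,
         "mean_intensity_counts": s.mean_intensity,
         "ap_position_percent_el": s.ap_position}
        for spots in spots_by_frame for s in spots
    ]
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px",
                                       "mean_intensity_counts",
                                       "ap_position_percent_el"])


def tracks_to_frame(tracks: list) -> pd.DataFrame:
    rows = []
    for tid, tr in enumerate(tracks):
        for s in tr.spots:
            rows.append({"track_id": tid, "frame": s.frame_index,
                         "x_px": s.x, "y_px": s.y,
                         "mean_intensity_counts": s.mean_intensity,
                         "ap_position_percent_el": s.ap_position,
                         "duration_s": tr.duration_s,
                         "region": tr.region or ""})
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px",
                                       "mean_intensity_counts",
                                       "ap_position_percent_el",
                                       "duration_s", "region"])


def region_stats_to_frame(stats: dict) -> pd.DataFrame:
    rows = [
        {"region_percent_el": r.region, "n_tracks": r.n_tracks,
         "mean_persistence_min": r.mean_min, "sd_persistence_min": r.sd_min}
        for r in stats.values()
    ]
    return pd.DataFrame(rows)


def nuclei_to_frame(nuclei: list) -> pd.DataFrame:
    return pd.DataFrame([
        {"embryo_id": n.embryo_id, "position_um_from_posterior": n.position_um,
         "percent_el": n.percent_el, "mean_intensity_counts": n.mean_intensity}
        for n in nuclei
    ])


def nuclei_from_csv(path: str | Path) -> list:
    df = pd.read_csv(path)
    return [NuclearRecord(embryo_id=str(r.embryo_id),
                          position_um=float(r.position_um_from_posterior),
                          percent_el=float(r.percent_el),
                          mean_intensity=float(r.mean_intensity_counts))
            for r in df.itertuples()]


# -- images -----------------------------------------------------------------


def write_movie(path: str | Path, stack: MovieStack) -> None:
    """Multi-page TIFF, one page per time point, with metadata tags."""
    tifffile.imwrite(
        path, stack.frames.astype(np.float32),
        metadata={"frame_interval_s": stack.frame_interval_s,
                  "pixel_size_nm": stack.pixel_size_nm,
                  "ap_el_at_x0": stack.ap_axis.el_at_x0,
                  "ap_el_per_px": stack.ap_axis.el_per_px},
    )


def read_movie(path: str | Path, frame_interval_s: float | None = None
               ) -> MovieStack:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[None]
    kwargs = {}
    if frame_interval_s is not None:
        kwargs["frame_interval_s"] = frame_interval_s
    elif "frame_interval_s" in meta:
        kwargs["frame_interval_s"] = float(meta["frame_interval_s"])
    if "pixel_size_nm" in meta:
        kwargs["pixel_size_nm"] = float(meta["pixel_size_nm"])
    if "ap_el_at_x0" in meta and "ap_el_per_px" in meta:
        kwargs["ap_axis"] = APAxisCalibration(
            el_at_x0=float(meta["ap_el_at_x0"]),
            el_per_px=float(meta["ap_el_per_px"]))
    return MovieStack(frames=np.asarray(frames, dtype=float), **kwargs)
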