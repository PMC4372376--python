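"""Plain-file handoff between pipeline stages: TIFF / CSV / YAML."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .quant import CellMeasure

__all__ = [
    "write_stack",
    "read_stack",
    "write_cells_csv",
    "read_cells_csv",
    "write_yaml",
    "read_yaml",
]


def write_stack(path, frames: np.ndarray, metadata: dict | None = None) -> None:
    """Write a (T, H, W) or (H, W) array as a float32 multi-page TIFF.

    Generating parameters are embedded as JSON in the description tag and
    echoed to a ``.yaml`` sidecar.
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 2:
        frames = frames[None]
    desc = json.dumps(metadata or {})
    tifffile.imwrite(path, frames, description=desc)
    if metadata:
        write_yaml(Path(path).with_suffix(".yaml"), metadata)


def read_stack(path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if frames.ndim == 2:
        frames = frames[None]
    return frames.astype(np.float64), meta


def write_cells_csv(path, per_frame_measures: list[list[CellMeasure]]) -> None:
    rows = []
    for frame_measures in per_frame_measures:
        for m in frame_measures:
            rows.append(
                {
                    "frame": m.frame,
                    "cell_id": m.cell_id,
                    "area_px": m.area_px,
                    "area_um2": m.area_um2,
                    "dry_mass_pg": m.dry_mass,
                    "mean_density_pg_px": m.mean_density,
                    "centroid_row": m.centroid[0],
                    "centroid_col": m.centroid[1],
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "frame",
            "cell_id",
            "area_px",
            "area_um2",
            "dry_mass_pg",
            "mean_density_pg_px",
            "centroid_row",
            "centroid_col",
        ],
    ).to_csv(path, index=False)


def read_cells_csv(path) -> list[list[CellMeasure]]:
    df = pd.read_csv(path)
    frames = sorted(df["frame"].unique())
    out = []
    for t in frames:
        sub = df[df["frame"] == t]
        out.append(
            [
                CellMeasure(
                    cell_id=int(r.cell_id),
                    frame=int(r.frame),
                    area_px=int(r.area_px),
                    area_um2=float(r.area_um2),
                    dry_mass=float(r.dry_mass_pg),
                    mean_density=float(r.mean_density_pg_px),
                    centroid=(float(r.centroid_row), float(r.centroid_col)),
                )
                for r in sub.itertuples()
            ]
        )
    return out


def write_yaml(path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
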