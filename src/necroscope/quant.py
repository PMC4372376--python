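"""Dry-mass quantification from flattened phase images.

Phase is converted to dry-mass density through a single calibration
constant (pg per radian per pixel), cells are segmented by a fixed phase
threshold, touching cells are separated by marker-seeded watershed, and
per-cell area / dry mass / mean density are measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

__all__ = [
    "Calibration",
    "SegmentationConfig",
    "LabelMask",
    "CellMeasure",
    "phase_to_mass_density",
    "segment_cells",
    "split_touching",
    "measure_cells",
    "DEFAULT_TAU",
    "DEFAULT_KAPPA",
]

#: Segmentation threshold in radians and the dry-mass density it corresponds
#: to; the default conversion constant is fixed by this pair.
DEFAULT_TAU = 0.21
DEFAULT_MASS_AT_TAU = 0.05  # pg per pixel at the threshold phase
DEFAULT_KAPPA = DEFAULT_MASS_AT_TAU / DEFAULT_TAU  # ~0.238095 pg/(rad px)


@dataclass(frozen=True)
class Calibration:
    """Phase-to-mass conversion: ``density[pg/px] = kappa * phase[rad]``."""

    kappa: float = DEFAULT_KAPPA
    pixel_size: float = 0.64  # micrometres per pixel

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")


@dataclass(frozen=True)
class SegmentationConfig:
    tau: float = DEFAULT_TAU
    min_area: int = 50
    connectivity: int = 8
    fill_holes: bool = True
    #: drop components overlapping this many border pixels (FFT-border
    #: reconstruction artifacts; analogous to "exclude on edges")
    exclude_border: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.min_area < 1:
            raise ValueError(f"min_area must be >= 1, got {self.min_area}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.exclude_border < 0:
            raise ValueError("exclude_border must be >= 0")

    @property
    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(2, 2 if self.connectivity == 8 else 1)


@dataclass
class LabelMask:
    """Connected-component labelling; 0 is background, labels are 1..count."""

    labels: np.ndarray
    count: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) != self.count or (
            len(present) and (present.min() != 1 or present.max() != self.count)
        ):
            raise ValueError("labels must be consecutive 1..count")


@dataclass(frozen=True)
class CellMeasure:
    """Per-cell, per-frame measurement record."""

    cell_id: int
    frame: int
    area_px: int
    area_um2: float
    dry_mass: float  # pg
    mean_density: float  # pg/pixel
    centroid: tuple[float, float]  # (row, col), mass-weighted


def phase_to_mass_density(phase_values: np.ndarray, calib: Calibration) -> np.ndarray:
    """Map phase (rad) to dry-mass density (pg/pixel), elementwise linear.

    Negative phase maps to negative density on purpose: background noise is
    kept unbiased and the segmentation threshold excludes it from cells.
    """
    return np.asarray(phase_values, dtype=float) * calib.kappa


def _relabel_canonical(labels: np.ndarray) -> LabelMask:
    """Renumber components by decreasing area; ties by top-left-most pixel."""
    flat = labels.ravel()
    ids = np.unique(flat)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return LabelMask(np.zeros_like(labels), 0)
    areas = ndimage.sum_labels(np.ones_like(flat), flat, ids)
    # first (row-major) pixel index of each component, for deterministic ties
    first = np.full(int(ids.max()) + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so that the smallest index wins the final assignment
    first[flat[nz[::-1]]] = nz[::-1]
    order = sorted(range(len(ids)), key=lambda k: (-areas[k], first[ids[k]]))
    lut = np.zeros(int(ids.max()) + 1, dtype=np.int32)
    for new, k in enumerate(order, start=1):
        lut[ids[k]] = new
    return LabelMask(lut[labels], len(ids))


def segment_cells(phase_values: np.ndarray, cfg: SegmentationConfig | None = None) -> LabelMask:
    """Threshold a flattened phase image and label the cell components.

    Foreground is ``phase >= tau``; holes are filled (footprint, not just
    super-threshold pixels), components smaller than ``min_area`` are
    dropped, and labels are renumbered deterministically.
    """
    cfg = cfg or SegmentationConfig()
    phase_values = np.asarray(phase_values)
    fg = phase_values >= cfg.tau
    if cfg.fill_holes:
        fg = ndimage.binary_fill_holes(fg, structure=None)
    labels, _ = ndimage.label(fg, structure=cfg.structure)
    if cfg.exclude_border > 0:
        b = cfg.exclude_border
        band = np.zeros_like(labels, dtype=bool)
        band[:b, :] = band[-b:, :] = band[:, :b] = band[:, -b:] = True
        edge_ids = np.unique(labels[band])
        edge_ids = edge_ids[edge_ids > 0]
        if len(edge_ids):
            labels[np.isin(labels, edge_ids)] = 0
    if cfg.min_area > 1:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        kill = ids[counts < cfg.min_area]
        if len(kill):
            labels[np.isin(labels, kill)] = 0
    return _relabel_canonical(labels)


def split_touching(
    mask: LabelMask,
    density: np.ndarray,
    markers: list[tuple[int, int]],
) -> LabelMask:
    """Separate merged cells with a marker-seeded watershed on -density.

    Only components holding two or more markers are split; everything else
    is carried over unchanged, so total foreground is preserved exactly.
    """
    density = np.asarray(density)
    if density.shape != mask.labels.shape:
        raise ValueError("density and mask shapes differ")
    if not markers:
        return LabelMask(mask.labels.copy(), mask.count)

    per_label: dict[int, list[tuple[int, int]]] = {}
    for m in markers:
        r, c = int(m[0]), int(m[1])
        lab = int(mask.labels[r, c])
        if lab == 0:
            raise ValueError(f"marker {(r, c)} falls on background")
        per_label.setdefault(lab, []).append((r, c))

    out = np.zeros_like(mask.labels, dtype=np.int32)
    next_id = 1
    for lab in range(1, mask.count + 1):
        comp = mask.labels == lab
        seeds = per_label.get(lab, [])
        if len(seeds) < 2:
            out[comp] = next_id
            next_id += 1
            continue
        marker_img = np.zeros_like(out)
        for k, (r, c) in enumerate(seeds, start=1):
            marker_img[r, c] = k
        ws = watershed(-density, markers=marker_img, mask=comp)
        for k in range(1, len(seeds) + 1):
            out[ws == k] = next_id + k - 1
        next_id += len(seeds)
    return _relabel_canonical(out)


def measure_cells(
    mask: LabelMask,
    density: np.ndarray,
    calib: Calibration,
    frame: int = 0,
) -> list[CellMeasure]:
    """One record per label: footprint area, integrated dry mass, centroid."""
    density = np.asarray(density, dtype=float)
    if density.shape != mask.labels.shape:
        raise ValueError(
            f"density shape {density.shape} != mask shape {mask.labels.shape}"
        )
    records: list[CellMeasure] = []
    if mask.count == 0:
        return records
    ids = np.arange(1, mask.count + 1)
    areas = ndimage.sum_labels(np.ones_like(density), mask.labels, ids)
    masses = ndimage.sum_labels(density, mask.labels, ids)
    rows, cols = np.indices(density.shape)
    mr = ndimage.sum_labels(density * rows, mask.labels, ids)
    mc = ndimage.sum_labels(density * cols, mask.labels, ids)
    for i, cid in enumerate(ids):
        area = int(areas[i])
        mass = float(masses[i])
        cr = float(mr[i] / mass) if mass != 0 else float("nan")
        cc = float(mc[i] / mass) if mass != 0 else float("nan")
        records.append(
            CellMeasure(
                cell_id=int(cid),
                frame=frame,
                area_px=area,
                area_um2=area * calib.pixel_size**2,
                dry_mass=mass,
                mean_density=mass / area,
                centroid=(cr, cc),
            )
        )
    return records
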