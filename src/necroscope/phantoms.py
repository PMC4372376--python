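"""Synthetic data: cell phase phantoms, off-axis holograms, FCM events.

Cells are sums of anisotropic raised-cosine bumps (smooth, compactly
supported), so the rendered phase is differentiable and unwrapping
artifacts unrelated to the algorithms under test are avoided. Every frame
of every cell is renormalised to its drawn dry mass, so mass conservation
holds by construction; fate morphodynamics (swelling + peripheral blebs,
shrinkage + late fragmentation into bodies, or no change) act on the
footprint only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .quant import Calibration

__all__ = [
    "Fate",
    "PhantomSpec",
    "CellPhantom",
    "HologramFrame",
    "Cohort",
    "make_cell_phantom",
    "simulate_timelapse_cohort",
    "render_hologram",
    "simulate_fcm_events",
    "simulate_unstained_control",
    "largest_remainder_counts",
    "DEFAULT_CLASS_PARAMS",
    "DEFAULT_CARRIER",
]

#: integral of a unit-peak raised-cosine bump divided by (r_y * r_x);
#: equals pi * (1/2 - 2/pi^2)
C_BUMP = float(np.pi * (0.5 - 2.0 / np.pi**2))

#: default off-axis carrier (cycles/pixel); diagonal keeps the sideband and
#: its window inside Nyquist on both axes
DEFAULT_CARRIER = (0.3, 0.3)


class Fate(str, Enum):
    NO_CHANGE = "no_change"
    INCREASE = "increase"
    DECREASE = "decrease"


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic time-lapse cohort."""

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.64  # micrometres
    cell_count: int = 100
    class_fractions: tuple[float, float, float] = (0.44, 0.32, 0.24)  # (no_change, increase, decrease)
    mass_mean: float = 450.0  # pg
    mass_cv: float = 0.12
    decrease_mass_factor: float = 1.3
    n_frames: int = 120
    frame_interval: float = 1.0  # minutes
    seed: int = 0
    # peak phase of a mean-mass cell; > 2 pi so unwrapping does real work,
    # kept moderate so phase gradients stay inside the sideband bandwidth
    target_peak: float = 6.5

    def __post_init__(self) -> None:
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {self.class_fractions}")
        if min(self.class_fractions) < 0:
            raise ValueError("class_fractions must be nonnegative")
        if self.mass_mean < 0:
            raise ValueError(f"mass_mean must be >= 0, got {self.mass_mean}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.cell_count < 0:
            raise ValueError("cell_count must be >= 0")


@dataclass
class CellPhantom:
    """One synthetic cell: per-frame phase patches plus ground truth."""

    cell_id: int
    fate: Fate
    center: tuple[float, float]  # (row, col) in image coordinates
    origin: tuple[int, int]  # top-left of the patch in the image
    phase_patch_series: np.ndarray  # (T, h, w) float32, radians, >= 0
    true_mass_series: np.ndarray  # pg, constant by construction
    true_area_series: np.ndarray  # support pixels per frame
    bleb_events: list[tuple[int, tuple[float, float], float]] = field(default_factory=list)

    def add_to(self, canvas: np.ndarray, frame: int) -> None:
        patch = self.phase_patch_series[frame]
        r0, c0 = self.origin
        h, w = patch.shape
        rs, cs = max(r0, 0), max(c0, 0)
        re, ce = min(r0 + h, canvas.shape[0]), min(c0 + w, canvas.shape[1])
        if re <= rs or ce <= cs:
            return
        canvas[rs:re, cs:ce] += patch[rs - r0 : re - r0, cs - c0 : ce - c0]


@dataclass
class HologramFrame:
    """Raw off-axis interferogram plus carrier metadata."""

    intensity: np.ndarray
    carrier: tuple[float, float]  # cycles/pixel
    object_amp: float = 1.0
    reference_amp: float = 1.0
    noise_sd: float = 0.0


def largest_remainder_counts(fractions, total: int) -> list[int]:
    """Deterministic rounding of ``fractions * total`` to integer counts."""
    raw = [f * total for f in fractions]
    base = [math.floor(x) for x in raw]
    short = total - sum(base)
    # largest fractional part first; ties by position
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


# ---------------------------------------------------------------------------
# cell phantom construction


def _draw_cell_params(spec: PhantomSpec, fate: Fate, rng: np.random.Generator) -> dict:
    """Draw all per-cell random parameters in a fixed order."""
    calib = Calibration()
    sigma = math.sqrt(math.log(1.0 + spec.mass_cv**2)) if spec.mass_cv > 0 else 0.0
    z = rng.standard_normal()
    mass = spec.mass_mean * math.exp(sigma * z - 0.5 * sigma**2)
    mass = float(np.clip(mass, 0.70 * spec.mass_mean, 1.40 * spec.mass_mean))
    if fate is Fate.DECREASE:
        mass *= spec.decrease_mass_factor
    # decrease-fate cells start flatter: their density rises as they shrink,
    # and the lower initial peak keeps late-frame phase gradients inside the
    # demodulation bandwidth
    peak = spec.target_peak * (0.82 if fate is Fate.DECREASE else 1.0)
    r0 = math.sqrt(mass / (calib.kappa * C_BUMP * peak)) if mass > 0 and peak > 0 else 0.0
    ar = float(rng.uniform(1.0, 1.08))
    phase0 = float(rng.uniform(0, 2 * np.pi))
    n_blebs = int(rng.integers(4, 8))
    blebs = [
        {
            "angle": float(rng.uniform(0, 2 * np.pi)),
            "rho": float(rng.uniform(4.0, 7.0)),
            "amp_frac": float(rng.uniform(0.2, 0.4)),
        }
        for _ in range(n_blebs)
    ]
    n_sat = int(rng.integers(3, 7))
    sats = [
        {"angle": float(rng.uniform(0, 2 * np.pi)), "dist": float(rng.uniform(0.25, 0.38))}
        for _ in range(n_sat)
    ]
    return {
        "mass": mass,
        "r0": r0,
        "ar": ar,
        "phase0": phase0,
        "blebs": blebs,
        "sats": sats,
    }


def _envelope_radius(spec: PhantomSpec, fate: Fate, params: dict) -> float:
    ry = params["r0"] * params["ar"]
    if fate is Fate.INCREASE:
        return 0.97 * 1.28 * ry + 7.0 + 2.0
    return 1.02 * ry + 2.0


def _bump(yy, xx, cy, cx, ry, rx):
    if ry <= 0 or rx <= 0:
        return np.zeros_like(yy, dtype=float)
    rho = np.hypot((yy - cy) / ry, (xx - cx) / rx)
    out = np.zeros_like(rho)
    inside = rho < 1.0
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * rho[inside]))
    return out


def _build_cell(
    spec: PhantomSpec,
    center: tuple[float, float],
    fate: Fate,
    params: dict,
    cell_id: int = 0,
) -> CellPhantom:
    calib = Calibration()
    T = spec.n_frames
    r0, ar = params["r0"], params["ar"]
    ry, rx = r0 * ar, r0 / ar
    half = int(math.ceil(_envelope_radius(spec, fate, params)))
    size = 2 * half + 1
    origin = (int(round(center[0])) - half, int(round(center[1])) - half)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = center[0] - origin[0]
    cx = center[1] - origin[1]
    series = np.zeros((T, size, size), dtype=np.float32)
    mass = params["mass"]
    target_sum = mass / calib.kappa
    bleb_events: list[tuple[int, tuple[float, float], float]] = []
    born: set[int] = set()

    for t in range(T):
        u = t / (T - 1)
        if fate is Fate.NO_CHANGE:
            g = 1.0 + 0.01 * math.sin(2 * np.pi * u + params["phase0"])
        elif fate is Fate.INCREASE:
            g = 1.0 + 0.28 * u
        else:
            g = 1.0 - 0.18 * u
        shape = _bump(yy, xx, cy, cx, g * ry, g * rx)

        if fate is Fate.INCREASE:
            n_active = math.floor(len(params["blebs"]) * u)
            for j in range(n_active):
                b = params["blebs"][j]
                # ellipse radius towards the bleb angle
                s, c = math.sin(b["angle"]), math.cos(b["angle"])
                by = cy + 0.97 * g * ry * s
                bx = cx + 0.97 * g * rx * c
                shape += b["amp_frac"] * _bump(yy, xx, by, bx, b["rho"], b["rho"])
                if j not in born:
                    born.add(j)
                    bleb_events.append(
                        (t, (by + origin[0], bx + origin[1]), b["amp_frac"])
                    )
        elif fate is Fate.DECREASE and u >= 0.7:
            w = 0.4 * (u - 0.7) / 0.3
            frag = 0.5 * _bump(yy, xx, cy, cx, 0.85 * g * ry, 0.85 * g * rx)
            k = len(params["sats"])
            for sdef in params["sats"]:
                s, c = math.sin(sdef["angle"]), math.cos(sdef["angle"])
                sy = cy + sdef["dist"] * g * ry * s
                sx = cx + sdef["dist"] * g * rx * c
                frag += (0.5 / k) * _bump(yy, xx, sy, sx, 0.62 * g * ry, 0.62 * g * rx)
            shape = (1.0 - w) * shape + w * frag

        tot = shape.sum()
        if tot > 0 and target_sum > 0:
            series[t] = (shape * (target_sum / tot)).astype(np.float32)
        # else: zero-mass phantom stays all-zero

    # exact truth, recomputed by summation from the stored float32 maps
    masses = series.reshape(T, -1).sum(axis=1, dtype=np.float64) * calib.kappa
    areas = (series > 0).reshape(T, -1).sum(axis=1)
    # scale bleb amplitudes into radians using the birth-frame normalisation
    events = []
    for (t, pos, frac) in bleb_events:
        peak_t = float(series[t].max())
        events.append((t, pos, frac * peak_t))
    return CellPhantom(
        cell_id=cell_id,
        fate=fate,
        center=center,
        origin=origin,
        phase_patch_series=series,
        true_mass_series=masses,
        true_area_series=areas.astype(np.int64),
        bleb_events=events,
    )


def make_cell_phantom(
    spec: PhantomSpec,
    center: tuple[float, float],
    fate: Fate | str,
    seed: int,
) -> CellPhantom:
    """Build one cell phantom with a smooth, mass-conserving phase series."""
    fate = Fate(fate)
    h, w = spec.image_shape
    if not (0 <= center[0] < h and 0 <= center[1] < w):
        raise ValueError(f"cell center {center} lies outside image of shape {spec.image_shape}")
    rng = np.random.default_rng(seed)
    params = _draw_cell_params(spec, fate, rng)
    return _build_cell(spec, center, fate, params)


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class Cohort:
    spec: PhantomSpec
    cells: list[CellPhantom]
    truth: pd.DataFrame  # cell_id, frame, fate, area_px, mass_pg, centroid_row, centroid_col

    def phase_frame(self, frame: int) -> np.ndarray:
        canvas = np.zeros(self.spec.image_shape, dtype=np.float64)
        for cell in self.cells:
            cell.add_to(canvas, frame)
        return canvas

    def phase_series(self) -> np.ndarray:
        return np.stack(
            [self.phase_frame(t) for t in range(self.spec.n_frames)]
        ).astype(np.float32)


def _shelf_pack(
    radii: list[float],
    image_shape: tuple[int, int],
    rng: np.random.Generator,
    gap: float = 2.0,
    margin: float = 10.0,
) -> list[tuple[float, float]]:
    """Deterministic shelf packing of circles (sorted large-to-small).

    Returns centers in the order of ``radii``; raises if the shelves
    overflow the image. ``margin`` keeps footprints clear of the border
    (reconstruction edge artifacts are excluded downstream).
    """
    H, W = image_shape[0] - margin, image_shape[1] - margin
    order = sorted(range(len(radii)), key=lambda i: (-radii[i], i))
    centers: list[tuple[float, float] | None] = [None] * len(radii)
    y = margin
    x = margin
    row_h = 0.0
    for i in order:
        r = radii[i]
        if x + 2 * r + gap > W:
            y += row_h + gap
            x = margin
            row_h = 0.0
        if x + 2 * r + gap > W or y + 2 * r + gap > H:
            raise ValueError(
                f"packing failure: cannot place {len(radii)} cells of these sizes "
                f"in an image of shape {image_shape}"
            )
        jy = float(rng.uniform(0, gap / 2))
        jx = float(rng.uniform(0, gap / 2))
        centers[i] = (y + r + jy, x + r + jx)
        x += 2 * r + gap
        row_h = max(row_h, 2 * r + gap / 2)
    return centers  # type: ignore[return-value]


def simulate_timelapse_cohort(spec: PhantomSpec) -> Cohort:
    """Generate a non-overlapping cohort with exact per-fate counts.

    Per-fate counts follow deterministic largest-remainder rounding of the
    class fractions; cells are placed by shelf packing of their motion
    envelopes, so footprints never collide at any frame.
    """
    rng = np.random.default_rng(spec.seed)
    counts = largest_remainder_counts(spec.class_fractions, spec.cell_count)
    fates = (
        [Fate.NO_CHANGE] * counts[0] + [Fate.INCREASE] * counts[1] + [Fate.DECREASE] * counts[2]
    )
    perm = rng.permutation(spec.cell_count)
    fates = [fates[i] for i in perm]
    seeds = rng.integers(0, 2**63 - 1, size=spec.cell_count)
    params = [
        _draw_cell_params(spec, fates[i], np.random.default_rng(seeds[i]))
        for i in range(spec.cell_count)
    ]
    radii = [_envelope_radius(spec, fates[i], params[i]) for i in range(spec.cell_count)]
    centers = _shelf_pack(radii, spec.image_shape, rng)

    cells = []
    rows = []
    calib = Calibration()
    for i in range(spec.cell_count):
        cell = _build_cell(spec, centers[i], fates[i], params[i], cell_id=i)
        cells.append(cell)
        for t in range(spec.n_frames):
            patch = cell.phase_patch_series[t].astype(np.float64)
            tot = patch.sum()
            if tot > 0:
                yy, xx = np.mgrid[0 : patch.shape[0], 0 : patch.shape[1]]
                cr = float((patch * yy).sum() / tot) + cell.origin[0]
                cc = float((patch * xx).sum() / tot) + cell.origin[1]
            else:
                cr, cc = cell.center
            rows.append(
                {
                    "cell_id": i,
                    "frame": t,
                    "fate": fates[i].value,
                    "area_px": int(cell.true_area_series[t]),
                    "mass_pg": float(cell.true_mass_series[t]),
                    "centroid_row": cr,
                    "centroid_col": cc,
                }
            )
    truth = pd.DataFrame(rows)
    return Cohort(spec=spec, cells=cells, truth=truth)


# ---------------------------------------------------------------------------
# hologram rendering


def render_hologram(
    phase_map: np.ndarray,
    carrier: tuple[float, float] = DEFAULT_CARRIER,
    amps: tuple[float, float] = (1.0, 1.0),
    noise_sd: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> HologramFrame:
    """Ideal two-beam off-axis interference of a phase object.

    ``I = A_o^2 + A_r^2 + 2 A_o A_r cos(2 pi (f_x x + f_y y) - phi) + noise``

    ``noise_sd`` defaults to 1% of the fringe amplitude ``2 A_o A_r``;
    intensities are clipped at zero after adding noise.
    """
    fmag = float(np.hypot(*carrier))
    if not (0.1 <= fmag <= 0.45):
        raise ValueError(
            f"carrier magnitude {fmag:.3f} cycles/pixel violates the separability "
            "bounds [0.1, 0.45]"
        )
    a_o, a_r = amps
    phase_map = np.asarray(phase_map, dtype=float)
    h, w = phase_map.shape
    yy, xx = np.mgrid[0:h, 0:w]
    fringe = 2.0 * a_o * a_r
    intensity = a_o**2 + a_r**2 + fringe * np.cos(
        2 * np.pi * (carrier[0] * xx + carrier[1] * yy) - phase_map
    )
    if noise_sd is None:
        noise_sd = 0.01 * fringe
    if noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    np.clip(intensity, 0.0, None, out=intensity)
    return HologramFrame(
        intensity=intensity,
        carrier=(float(carrier[0]), float(carrier[1])),
        object_amp=a_o,
        reference_amp=a_r,
        noise_sd=float(noise_sd),
    )


# ---------------------------------------------------------------------------
# flow-cytometry event simulation

#: class-conditional log-normal channel parameters: (median, log-sd).
#: Apoptotic events sit at low FSC, oncotic at high FSC (both annexin-high /
#: PI-low); necrotic are double-positive with intermediate FSC; debris are
#: small PI-positive fragments.
DEFAULT_CLASS_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "viable": {"fsc": (500, 0.25), "ssc": (300, 0.30), "fl1": (8, 0.50), "fl3": (10, 0.40)},
    "apoptotic": {"fsc": (200, 0.22), "ssc": (260, 0.30), "fl1": (400, 0.45), "fl3": (10, 0.40)},
    "oncotic": {"fsc": (900, 0.22), "ssc": (400, 0.30), "fl1": (400, 0.45), "fl3": (10, 0.40)},
    "necrotic": {"fsc": (450, 0.25), "ssc": (430, 0.30), "fl1": (400, 0.45), "fl3": (400, 0.50)},
    "debris": {"fsc": (80, 0.40), "ssc": (100, 0.40), "fl1": (8, 0.50), "fl3": (300, 0.60)},
}

_CHANNELS = {"fsc": "FSC", "ssc": "SSC", "fl1": "FL1", "fl3": "FL3"}


def simulate_fcm_events(
    n_events: int,
    class_mix: dict[str, float],
    class_params: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Class-conditional log-normal event table (FSC, SSC, FL1, FL3)."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError(f"class_mix must sum to 1, got {sum(class_mix.values())}")
    params = class_params or DEFAULT_CLASS_PARAMS
    for cls in class_mix:
        for ch, (med, sig) in params[cls].items():
            if med <= 0 or sig <= 0:
                raise ValueError(f"non-positive distribution scale for {cls}/{ch}")
    rng = np.random.default_rng(seed)
    names = list(class_mix.keys())
    counts = largest_remainder_counts([class_mix[c] for c in names], n_events)
    frames = []
    for cls, cnt in zip(names, counts):
        if cnt == 0:
            continue
        cols = {}
        for ch, col in _CHANNELS.items():
            med, sig = params[cls][ch]
            cols[col] = np.exp(rng.normal(math.log(med), sig, size=cnt))
        cols["true_class"] = [cls] * cnt
        frames.append(pd.DataFrame(cols))
    if not frames:
        return pd.DataFrame(columns=["FSC", "SSC", "FL1", "FL3", "true_class"])
    table = pd.concat(frames, ignore_index=True)
    return table.iloc[rng.permutation(len(table))].reset_index(drop=True)


def simulate_unstained_control(n_events: int, seed: int = 0) -> pd.DataFrame:
    """Unstained gating control: viable scatter, broadened autofluorescence."""
    rng = np.random.default_rng(seed)
    p = DEFAULT_CLASS_PARAMS["viable"]
    out = pd.DataFrame(
        {
            "FSC": np.exp(rng.normal(math.log(p["fsc"][0]), p["fsc"][1], size=n_events)),
            "SSC": np.exp(rng.normal(math.log(p["ssc"][0]), p["ssc"][1], size=n_events)),
            "FL1": np.exp(rng.normal(math.log(p["fl1"][0]), 0.60, size=n_events)),
            "FL3": np.exp(rng.normal(math.log(p["fl3"][0]), 0.60, size=n_events)),
        }
    )
    out["true_class"] = "viable"
    return out
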