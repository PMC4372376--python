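"""Numerical reconstruction of quantitative phase from off-axis holograms.

The chain is: carrier estimation -> Fourier sideband demodulation ->
quality-guided phase unwrapping -> first-order background flattening.
A simulated DIC display (1D phase gradient plus bias) is also provided.

Conventions: coordinates are 0-based row-major; spatial frequencies are in
cycles/pixel with the origin at the spectrum centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import fft as sfft
from scipy import ndimage

__all__ = [
    "WrappedPhase",
    "PhaseImage",
    "SidebandFilter",
    "estimate_carrier",
    "design_filter",
    "demodulate",
    "unwrap_phase",
    "flatten_background",
    "simulated_dic",
    "reconstruct",
]

TWO_PI = 2.0 * np.pi

#: radius (cycles/pixel) of the DC exclusion disk used in carrier search
DC_EXCLUSION = 0.05


@dataclass
class WrappedPhase:
    """Demodulated phase in (-pi, pi] plus the demodulated magnitude."""

    values: np.ndarray
    amplitude: np.ndarray


@dataclass
class PhaseImage:
    """Continuous (unwrapped, flattened) phase map in radians."""

    values: np.ndarray
    pixel_size: float = 0.64
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SidebandFilter:
    """Circular sideband window.

    ``taper="tukey"`` is flat out to 70% of the radius with a cosine
    roll-off beyond (preserves in-band phase content); ``taper="hann"`` is
    the full raised-cosine profile.
    """

    center: tuple[float, float]  # (f_x, f_y) cycles/pixel
    radius: float  # cycles/pixel
    taper: str = "tukey"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"filter radius must be > 0, got {self.radius}")
        if float(np.hypot(*self.center)) <= self.radius:
            raise ValueError("sideband circle must exclude DC")
        if self.taper not in ("tukey", "hann"):
            raise ValueError(f"unknown taper {self.taper!r}")

    @property
    def flat_fraction(self) -> float:
        return 0.7 if self.taper == "tukey" else 0.0


def _wrap(values: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.mod(-np.asarray(values) + np.pi, TWO_PI)
    return np.pi - out


def _parabolic_offset(m_minus: float, m0: float, m_plus: float) -> float:
    denom = m_minus - 2.0 * m0 + m_plus
    if abs(denom) < 1e-300:
        return 0.0
    off = 0.5 * (m_minus - m_plus) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_carrier(intensity: np.ndarray) -> tuple[float, float]:
    """Locate the off-axis carrier as the strongest off-DC spectral peak.

    The peak is refined to sub-bin precision by separable quadratic fits and
    canonicalised to the half-plane with f_x > 0 (or f_x == 0, f_y > 0).

    Raises
    ------
    ValueError
        If no off-DC peak exceeds 3x the median spectral magnitude
        ("no carrier detected").
    """
    intensity = np.asarray(intensity, dtype=float)
    spec = sfft.fft2(intensity)
    mag = np.abs(spec)
    fy = sfft.fftfreq(intensity.shape[0])
    fx = sfft.fftfreq(intensity.shape[1])
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    dist = np.hypot(FX, FY)
    search = mag.copy()
    search[dist <= DC_EXCLUSION] = 0.0
    peak_flat = int(np.argmax(search))
    iy, ix = np.unravel_index(peak_flat, mag.shape)
    peak = search[iy, ix]
    floor = 3.0 * float(np.median(mag))
    if peak <= floor or peak <= 0:
        raise ValueError("no carrier detected: no off-DC spectral peak")
    ny, nx = mag.shape
    dy = _parabolic_offset(mag[(iy - 1) % ny, ix], mag[iy, ix], mag[(iy + 1) % ny, ix])
    dx = _parabolic_offset(mag[iy, (ix - 1) % nx], mag[iy, ix], mag[iy, (ix + 1) % nx])
    f_y = fy[iy] + dy / ny
    f_x = fx[ix] + dx / nx
    if f_x < 0 or (f_x == 0 and f_y < 0):
        f_x, f_y = -f_x, -f_y
    return (float(f_x), float(f_y))


def design_filter(carrier: tuple[float, float], radius: float | None = None) -> SidebandFilter:
    """Default sideband window: 0.45x the carrier-to-DC distance, Hann taper."""
    if radius is None:
        radius = 0.45 * float(np.hypot(*carrier))
    return SidebandFilter(center=(float(carrier[0]), float(carrier[1])), radius=float(radius))


def demodulate(intensity: np.ndarray, filt: SidebandFilter) -> WrappedPhase:
    """Fourier sideband demodulation of an off-axis hologram.

    The spectrum is windowed around ``filt.center`` with a Hann-tapered
    circular mask, inverse transformed, and the carrier is removed by an
    exact analytic demodulation (no integer-bin roll), so sub-bin carriers
    leave no residual phase ramp.
    """
    intensity = np.asarray(intensity, dtype=float)
    h, w = intensity.shape
    hp = _next_even_fast_len(h)
    wp = _next_even_fast_len(w)
    padded = np.zeros((hp, wp), dtype=float)
    padded[:h, :w] = intensity
    spec = sfft.fft2(padded)
    fy = sfft.fftfreq(hp)
    fx = sfft.fftfreq(wp)
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    d = np.hypot(FX - filt.center[0], FY - filt.center[1])
    # the frequency torus: also measure distance across the Nyquist wrap
    for sx in (-1.0, 0.0, 1.0):
        for sy in (-1.0, 0.0, 1.0):
            if sx == 0.0 and sy == 0.0:
                continue
            d = np.minimum(d, np.hypot(FX + sx - filt.center[0], FY + sy - filt.center[1]))
    if abs(filt.center[0]) + filt.radius > 0.5 or abs(filt.center[1]) + filt.radius > 0.5:
        warnings.warn(
            "sideband filter clipped by the spectrum edge; proceeding with the clipped mask",
            stacklevel=2,
        )
    mask = np.zeros_like(d)
    flat = filt.flat_fraction * filt.radius
    mask[d < flat] = 1.0
    ramp = (d >= flat) & (d < filt.radius)
    mask[ramp] = 0.5 * (1.0 + np.cos(np.pi * (d[ramp] - flat) / (filt.radius - flat)))
    field_c = sfft.ifft2(spec * mask)[:h, :w]
    yy, xx = np.mgrid[0:h, 0:w]
    field_c = field_c * np.exp(-2j * np.pi * (filt.center[0] * xx + filt.center[1] * yy))
    # sideband term is A_o*A_r/2 * exp(i(2 pi f.x - phi)); after carrier
    # removal the argument is -phi
    wrapped = _wrap(-np.angle(field_c))
    return WrappedPhase(values=wrapped, amplitude=np.abs(field_c))


def _next_even_fast_len(n: int) -> int:
    m = sfft.next_fast_len(n, real=False)
    while m % 2:
        m = sfft.next_fast_len(m + 1, real=False)
    return m


@njit(cache=True)
def _flood_unwrap(wrapped, quality, seed_idx):  # pragma: no cover - jitted
    h, w = wrapped.shape
    n = h * w
    out = np.zeros(n, dtype=np.float64)
    state = np.zeros(n, dtype=np.uint8)  # 0 unknown, 1 queued, 2 done
    heap_q = np.empty(n, dtype=np.float64)
    heap_i = np.empty(n, dtype=np.int64)
    size = 0

    # binary max-heap on (quality, -index): ties broken by lower pixel index
    def _less(a_q, a_i, b_q, b_i):
        if a_q != b_q:
            return a_q < b_q
        return a_i > b_i

    heap_q[0] = quality.flat[seed_idx]
    heap_i[0] = seed_idx
    size = 1
    state[seed_idx] = 1
    out[seed_idx] = wrapped.flat[seed_idx]

    wflat = wrapped.ravel()
    qflat = quality.ravel()
    two_pi = 2.0 * np.pi

    while size > 0:
        top_q = heap_q[0]
        top_i = heap_i[0]
        size -= 1
        heap_q[0] = heap_q[size]
        heap_i[0] = heap_i[size]
        pos = 0
        while True:
            l = 2 * pos + 1
            r = l + 1
            best = pos
            if l < size and _less(heap_q[best], heap_i[best], heap_q[l], heap_i[l]):
                best = l
            if r < size and _less(heap_q[best], heap_i[best], heap_q[r], heap_i[r]):
                best = r
            if best == pos:
                break
            heap_q[pos], heap_q[best] = heap_q[best], heap_q[pos]
            heap_i[pos], heap_i[best] = heap_i[best], heap_i[pos]
            pos = best
        cur = top_i
        if state[cur] == 2:
            continue
        state[cur] = 2
        cy = cur // w
        cx = cur % w
        for k in range(4):
            if k == 0:
                ny_, nx_ = cy - 1, cx
            elif k == 1:
                ny_, nx_ = cy + 1, cx
            elif k == 2:
                ny_, nx_ = cy, cx - 1
            else:
                ny_, nx_ = cy, cx + 1
            if ny_ < 0 or ny_ >= h or nx_ < 0 or nx_ >= w:
                continue
            nb = ny_ * w + nx_
            if state[nb] != 0:
                continue
            d = wflat[nb] - wflat[cur]
            d -= two_pi * np.rint(d / two_pi)
            out[nb] = out[cur] + d
            state[nb] = 1
            # push
            pos = size
            heap_q[pos] = qflat[nb]
            heap_i[pos] = nb
            size += 1
            while pos > 0:
                parent = (pos - 1) // 2
                if _less(heap_q[parent], heap_i[parent], heap_q[pos], heap_i[pos]):
                    heap_q[pos], heap_q[parent] = heap_q[parent], heap_q[pos]
                    heap_i[pos], heap_i[parent] = heap_i[parent], heap_i[pos]
                    pos = parent
                else:
                    break
    return out.reshape((h, w))


def _background_mode(values: np.ndarray, bin_width: float = 0.01) -> float:
    """Histogram-peak offset (bins of ``bin_width`` rad)."""
    v = np.asarray(values, dtype=float).ravel()
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < bin_width:
        return float(np.median(v))
    nbins = int(np.ceil((hi - lo) / bin_width))
    counts, edges = np.histogram(v, bins=nbins, range=(lo, lo + nbins * bin_width))
    k = int(np.argmax(counts))
    return 0.5 * (edges[k] + edges[k + 1])


def unwrap_phase(
    wrapped: WrappedPhase, pixel_size: float = 0.64, remove_offset: bool = True
) -> PhaseImage:
    """Quality-guided flood-fill phase unwrapping.

    Quality is the demodulated amplitude divided by the local variance of
    the wrapped phase gradients (3x3 window); integration starts at the
    highest-quality pixel and proceeds through a deterministic max-heap
    (ties broken by row-major pixel index). With ``remove_offset`` the
    global offset is removed by zeroing the background mode (0.01 rad
    histogram bins); without it the result differs from the true phase by
    an exact 2-pi multiple.
    """
    values = np.asarray(wrapped.values, dtype=float)
    amp = np.asarray(wrapped.amplitude, dtype=float)
    if not np.any(amp > 0):
        raise ValueError("no reliable seed: amplitude map is all zero")
    gx = _wrap(np.diff(values, axis=1, append=values[:, -1:]))
    gy = _wrap(np.diff(values, axis=0, append=values[-1:, :]))
    var = np.zeros_like(values)
    for g in (gx, gy):
        mean = ndimage.uniform_filter(g, size=3, mode="nearest")
        mean_sq = ndimage.uniform_filter(g * g, size=3, mode="nearest")
        var += np.maximum(mean_sq - mean * mean, 0.0)
    quality = (amp / amp.max()) / (1e-6 + var)
    seed = int(np.argmax(quality))
    out = _flood_unwrap(values, quality, seed)
    if remove_offset:
        out = out - _background_mode(out)
    return PhaseImage(values=out, pixel_size=pixel_size, provenance={"step": "unwrap"})


def flatten_background(
    phase: PhaseImage,
    exclude_mask: np.ndarray | None = None,
    percentile: float = 60.0,
) -> PhaseImage:
    """Remove a first-order background plane and zero the background median.

    Background pixels are those outside ``exclude_mask`` when given,
    otherwise those below a robust percentile of the phase; the plane fit is
    refined once on the residual.
    """
    values = np.asarray(phase.values, dtype=float)
    h, w = values.shape
    yy, xx = np.mgrid[0:h, 0:w]
    if exclude_mask is not None:
        exclude_mask = np.asarray(exclude_mask, dtype=bool)
        n_bg = int((~exclude_mask).sum())
        if n_bg < 0.1 * values.size:
            raise ValueError("exclude_mask covers more than 90% of the image")
        bg = ~exclude_mask
    else:
        bg = values <= np.percentile(values, percentile)

    resid = values
    plane = np.zeros_like(values)
    for _ in range(2):
        A = np.column_stack(
            [np.ones(int(bg.sum())), yy[bg].astype(float), xx[bg].astype(float)]
        )
        coef, *_ = np.linalg.lstsq(A, resid[bg], rcond=None)
        plane = plane + coef[0] + coef[1] * yy + coef[2] * xx
        resid = values - plane
        if exclude_mask is None:
            mad = np.median(np.abs(resid[bg] - np.median(resid[bg])))
            bg = np.abs(resid - np.median(resid[bg])) < max(3.0 * 1.4826 * mad, 1e-12)
            if bg.sum() < 0.05 * values.size:  # pathological; keep previous fit
                break
    out = resid - np.median(resid[bg]) if bg.any() else resid
    prov = dict(phase.provenance)
    prov["flattened"] = True
    return PhaseImage(values=out, pixel_size=phase.pixel_size, provenance=prov)


def simulated_dic(phase: PhaseImage, axis: str = "col", bias: float = 0.0) -> np.ndarray:
    """DIC-like display: forward difference along one axis plus a bias.

    The trailing line is padded by edge replication so the output shape
    matches the input.
    """
    values = np.asarray(phase.values, dtype=float)
    if axis == "col":
        grad = np.diff(values, axis=1, append=values[:, -1:])
        grad[:, -1] = grad[:, -2] if values.shape[1] > 1 else 0.0
    elif axis == "row":
        grad = np.diff(values, axis=0, append=values[-1:, :])
        grad[-1, :] = grad[-2, :] if values.shape[0] > 1 else 0.0
    else:
        raise ValueError(f"axis must be 'row' or 'col', got {axis!r}")
    return grad + bias


def reconstruct(
    intensity: np.ndarray,
    carrier: tuple[float, float] | None = None,
    radius: float | None = None,
    pixel_size: float = 0.64,
) -> PhaseImage:
    """Full chain: (estimate carrier ->) demodulate -> unwrap -> flatten."""
    if carrier is None:
        carrier = estimate_carrier(intensity)
    filt = design_filter(carrier, radius)
    wrapped = demodulate(intensity, filt)
    phase = unwrap_phase(wrapped, pixel_size=pixel_size)
    flat = flatten_background(phase)
    flat.provenance.update(
        {"carrier": [float(carrier[0]), float(carrier[1])], "radius": filt.radius}
    )
    return flat
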