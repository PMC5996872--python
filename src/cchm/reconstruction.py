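"""Off-axis hologram reconstruction and quantitative phase imaging.

Processing chain: 2-D Fourier transform of the interferogram, windowing of
the sideband around the carrier frequency fc (circular disc with a radial
Hanning taper), recentring of the sideband to zero frequency, and inverse
transform to the complex amplitude wD(i, j).  |wD| is the amplitude image,
Arg(wD) the phase image; a quantitative phase image follows after 2-D phase
unwrapping and polynomial background compensation.

The field-averaged modulus ``mean_modulus`` (w-bar-D) is the alignment
objective used throughout the auto-alignment procedures; the QPI noise
resolution is ``r = 2 * sigma_phi`` measured over a background window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import fft as sp_fft
from skimage.restoration import unwrap_phase as _sk_unwrap

from .holo_sim import Hologram
from .signal_model import OpticsConfig

__all__ = [
    "ReconstructedField",
    "QpiImage",
    "CarrierNotFoundError",
    "WindowError",
    "fourier_spectrum",
    "estimate_carrier",
    "extract_sideband",
    "reconstruct",
    "mean_modulus",
    "unwrap_phase",
    "compensate_background",
    "qpi_resolution",
    "quantitative_phase",
]


class CarrierNotFoundError(RuntimeError):
    """No sideband peak above the detection threshold."""


class WindowError(ValueError):
    """Requested sideband disc touches the DC term or exceeds Nyquist."""


@dataclass
class ReconstructedField:
    """Complex image amplitude wD(i, j) with the carrier and window used."""

    wd: np.ndarray
    fc: Tuple[float, float]  # cycles/um at the output plane
    radius: float  # cycles/um
    optics: Optional[OpticsConfig] = None

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.wd)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.wd)


@dataclass
class QpiImage:
    """Unwrapped, background-compensated quantitative phase image (rad)."""

    phase: np.ndarray
    background_coeffs: np.ndarray
    mask: np.ndarray
    quality_ok: bool = True


# ---------------------------------------------------------------------------


def fourier_spectrum(h) -> np.ndarray:
    """Centered 2-D DFT of a hologram (DC term at the center index)."""
    data = h.data if isinstance(h, Hologram) else np.asarray(h, dtype=float)
    if data.size == 0:
        raise ValueError("empty image")
    return sp_fft.fftshift(sp_fft.fft2(data))


def _bins_per_cyc_um(shape, pitch_um: float) -> Tuple[float, float]:
    return shape[0] * pitch_um, shape[1] * pitch_um


def estimate_carrier(
    spectrum: np.ndarray,
    pitch_um: float,
    dc_exclusion_radius: Optional[float] = None,
    min_peak_ratio: float = 10.0,
) -> Tuple[float, float]:
    """Locate the sideband carrier frequency from a centered spectrum.

    Searches for the largest spectral magnitude outside a DC exclusion disc
    and refines the location to sub-bin precision with a quadratic fit of
    the log magnitude over the 3x3 neighborhood.  The representative in the
    half-plane with positive first (x) component is returned (positive y
    breaks the tie on the axis), in cycles/um.

    ``min_peak_ratio`` guards against featureless (single-arm) images: the
    peak must exceed that multiple of the median out-of-DC magnitude.
    """
    ny, nx = spectrum.shape
    cy, cx = ny // 2, nx // 2
    if dc_exclusion_radius is None:
        dc_r = max(4.0, 0.04 * min(ny, nx))
    else:
        dc_r = dc_exclusion_radius * pitch_um * min(ny, nx)  # cycles/um -> bins (approx)
    yy, xx = np.mgrid[0:ny, 0:nx]
    rho = np.hypot(yy - cy, xx - cx)
    mag = np.abs(spectrum)
    search = np.where(rho > dc_r, mag, 0.0)
    j = int(np.argmax(search))
    py, px = divmod(j, nx)
    floor = np.median(mag[rho > dc_r])
    if search[py, px] <= min_peak_ratio * max(floor, 1e-300):
        raise CarrierNotFoundError("no sideband peak above the noise floor")

    # quadratic sub-bin refinement on log magnitude
    def _refine(i: int, lo_v: float, c_v: float, hi_v: float) -> float:
        denom = lo_v - 2.0 * c_v + hi_v
        if denom >= 0 or abs(denom) < 1e-300:
            return float(i)
        return i + 0.5 * (lo_v - hi_v) / denom

    lm = np.log(np.clip(mag, 1e-300, None))
    fy = _refine(py, lm[py - 1, px], lm[py, px], lm[(py + 1) % ny, px]) - cy
    fx = _refine(px, lm[py, px - 1], lm[py, px], lm[py, (px + 1) % nx]) - cx
    by, bx = _bins_per_cyc_um(spectrum.shape, pitch_um)
    fyu, fxu = fy / by, fx / bx
    if fxu < 0 or (fxu == 0 and fyu < 0):
        fxu, fyu = -fxu, -fyu
    return (fxu, fyu)


def default_sideband_radius(fc: Tuple[float, float], pitch_um: float) -> float:
    """Default window radius: min(|fc|/2, distance from fc to Nyquist)."""
    fmag = float(np.hypot(*fc))
    nyq = 0.5 / pitch_um
    return min(0.5 * fmag, nyq - fmag)


def extract_sideband(
    spectrum: np.ndarray,
    fc: Tuple[float, float],
    radius: float,
    pitch_um: float,
) -> np.ndarray:
    """Window the sideband around fc and recentre it to zero frequency.

    The disc of the given radius (cycles/um) around fc is kept, multiplied
    by a radial Hanning taper (1 at the center, 0 at the radius), and rolled
    so the carrier bin lands on the DC index.  The disc must exclude the DC
    bin and stay inside the Nyquist square.
    """
    ny, nx = spectrum.shape
    cy, cx = ny // 2, nx // 2
    by, bx = _bins_per_cyc_um(spectrum.shape, pitch_um)
    fby, fbx = fc[1] * by, fc[0] * bx  # bins
    rby, rbx = radius * by, radius * bx
    if radius <= 0:
        raise WindowError("radius must be positive")
    if float(np.hypot(*fc)) <= radius:
        raise WindowError("sideband disc touches the DC term")
    nyq = 0.5 / pitch_um
    if abs(fc[0]) + radius > nyq or abs(fc[1]) + radius > nyq:
        raise WindowError("sideband disc exceeds the Nyquist boundary")

    iy, ix = int(round(fby)), int(round(fbx))
    yy, xx = np.mgrid[0:ny, 0:nx]
    # radial distance from the carrier in frequency units (cycles/um)
    rho = np.hypot((yy - cy - iy) / by, (xx - cx - ix) / bx)
    taper = np.where(rho <= radius, 0.5 * (1.0 + np.cos(np.pi * rho / radius)), 0.0)
    out = spectrum * taper
    return np.roll(out, (-iy, -ix), axis=(0, 1))


def reconstruct(
    h: Hologram,
    fc: Optional[Tuple[float, float]] = None,
    radius: Optional[float] = None,
) -> ReconstructedField:
    """Full chain: spectrum -> sideband window -> inverse transform.

    ``fc`` defaults to the hologram's configured carrier; pass ``fc=None``
    with ``estimate=True`` semantics by calling :func:`estimate_carrier`
    explicitly when the carrier is unknown.
    """
    optics = h.optics
    pitch = optics.pixel_pitch_um
    spec = fourier_spectrum(h)
    if fc is None:
        fc = optics.fc
    if radius is None:
        radius = default_sideband_radius(fc, pitch)
    windowed = extract_sideband(spec, fc, radius, pitch)
    wd = sp_fft.ifft2(sp_fft.ifftshift(windowed))
    return ReconstructedField(wd, tuple(fc), float(radius), optics)


def mean_modulus(f: ReconstructedField) -> float:
    """Field-averaged modulus w-bar-D = sum |wD(i,j)| / (NI * NJ)."""
    if f.wd.size == 0:
        raise ValueError("empty field")
    return float(np.mean(np.abs(f.wd)))


def unwrap_phase(phase: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """2-D phase unwrapping (reliability-guided).

    Returns ``(unwrapped, quality_mask)``; the mask flags pixels where the
    rewrapped result disagrees with the input (unresolved residues) instead
    of raising.
    """
    unwrapped = np.asarray(_sk_unwrap(np.asarray(phase, dtype=float)))
    rewrapped = np.angle(np.exp(1j * unwrapped))
    ok = np.isclose(rewrapped, np.angle(np.exp(1j * phase)), atol=1e-6)
    return unwrapped, ok


def _poly_design(shape, order: int, mask: np.ndarray) -> np.ndarray:
    ny, nx = shape
    y = (np.arange(ny) - ny / 2.0) / max(ny / 2.0, 1)
    x = (np.arange(nx) - nx / 2.0) / max(nx / 2.0, 1)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cols = [
        (yy**i * xx**j)[mask]
        for i in range(order + 1)
        for j in range(order + 1 - i)
    ]
    return np.column_stack(cols)


def compensate_background(
    unwrapped: np.ndarray,
    order: int = 2,
    mask: Optional[np.ndarray] = None,
) -> QpiImage:
    """Fit and subtract a 2-D polynomial background over the mask.

    The fit is least squares on the masked pixels; the full-field polynomial
    is subtracted everywhere and the masked mean of the residual is zero by
    construction (the constant term belongs to the basis).
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    unwrapped = np.asarray(unwrapped, dtype=float)
    if mask is None:
        mask = np.ones(unwrapped.shape, dtype=bool)
    n_terms = (order + 1) * (order + 2) // 2
    if mask.sum() < max(3 * n_terms, 8):
        raise ValueError("mask too small for a stable background fit")
    a = _poly_design(unwrapped.shape, order, mask)
    coeffs, *_ = np.linalg.lstsq(a, unwrapped[mask], rcond=None)
    full = _poly_design(unwrapped.shape, order, np.ones_like(mask, dtype=bool))
    bg = (full @ coeffs).reshape(unwrapped.shape)
    out = unwrapped - bg
    out -= out[mask].mean()  # exact masked zero mean
    return QpiImage(out, coeffs, mask)


def qpi_resolution(q: QpiImage, window: Optional[np.ndarray] = None) -> float:
    """QPI noise resolution r = 2 * sigma_phi over a background window.

    ``window`` is a boolean mask (default: the image's own mask); it should
    cover background (object-free) pixels only.
    """
    win = window if window is not None else q.mask
    vals = q.phase[win]
    if vals.size == 0:
        raise ValueError("empty window")
    return 2.0 * float(np.std(vals))


def quantitative_phase(
    f: ReconstructedField,
    order: int = 2,
    mask: Optional[np.ndarray] = None,
    unwrap: bool = True,
) -> QpiImage:
    """Phase image -> (optional) unwrapping -> background compensation."""
    ph = f.phase
    ok = np.ones(ph.shape, dtype=bool)
    if unwrap:
        ph, ok = unwrap_phase(ph)
    q = compensate_background(ph, order=order, mask=mask)
    q.quality_ok = bool(ok.all())
    return q
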