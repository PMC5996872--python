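"""Theoretical reconstructed holographic signal of a partially coherent interferometric microscope.

The coherence-controlled holographic microscope (CCHM) forms an off-axis
hologram between an object arm and a reference arm.  With a spatially and
temporally partially coherent source, the modulus of the reconstructed
holographic signal ``w`` falls off as the two arm images are laterally
displaced by ``qf = (xf, yf)`` (object-plane micrometres) or as the optical
path difference ``dl`` between the arms grows.  For an empty (sample-free)
field the signal factorizes into a Hankel-type integral over the source
radius (lateral/spatial coherence) and a Fourier-type integral over the
source spectrum (temporal coherence):

    w(qf, dl) = 2*pi * int_0^inf iK(K) exp(-2*pi*i*K*dl)
                * int_0^{NAs/n} iT(kappa) J0(2*pi*K*kappa*|qf|) kappa dkappa dK

with ``K = 1/lambda`` the wavenumber (cycles/um), ``kappa = Kt/K`` the
normalized transverse wavenumber of a source point, ``iT`` the radial source
intensity profile and ``iK`` the spectral density.  ``|w|`` is maximal at the
aligned state ``qf = 0, dl = 0``, which is what makes it a usable objective
function for automated alignment.

All public signal values are normalized so that the aligned state yields 1.
Lengths are micrometres internally; wavelengths enter in nanometres at the
dataclass interface and are converted once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import integrate, optimize, special

__all__ = [
    "SourceModel",
    "OpticsConfig",
    "MisalignmentState",
    "SignalMap",
    "radial_source_intensity",
    "spectral_density",
    "lateral_coherence",
    "temporal_coherence",
    "theoretical_signal",
    "signal_map",
    "first_side_maximum",
    "max_inclination",
    "inclination_phase_error",
]

_NM_PER_UM = 1e3


@dataclass(frozen=True)
class SourceModel:
    """Illumination source: spectrum and radial intensity profile.

    Parameters
    ----------
    wavelength_nm
        Center wavelength lambda0 (nm).
    spectral_shape
        ``"gaussian"`` or ``"rectangular"`` analytic stand-ins for a
        narrowband interference filter.  The rectangular shape produces the
        sinc-like temporal-coherence envelope with side maxima; the gaussian
        shape produces a smooth, lobe-free envelope.
    fwhm_nm
        Spectral full width at half maximum (nm); must be << wavelength_nm.
    alpha
        Reciprocal-width parameter of the Gaussian radial profile:
        ``iT(kappa) = exp(-kappa^2 / (2 sigma^2))`` with
        ``sigma = (NAs/n)/alpha``, truncated at ``kappa = NAs/n``.
        ``alpha=None`` selects a uniform (flat-disc) profile.
    na_s
        Effective illumination numerical aperture (the smallest of the
        condenser and reference-objective apertures).
    n
        Refractive index of the object space.
    """

    wavelength_nm: float = 650.0
    spectral_shape: Literal["gaussian", "rectangular"] = "gaussian"
    fwhm_nm: float = 10.0
    alpha: Optional[float] = 2.5
    na_s: float = 0.30
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be positive")
        if self.fwhm_nm >= 0.2 * self.wavelength_nm:
            raise ValueError("fwhm_nm must be narrow relative to wavelength_nm")
        if not 0 < self.na_s <= 1:
            raise ValueError("na_s must be in (0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive (or None for a flat disc)")
        if self.spectral_shape not in ("gaussian", "rectangular"):
            raise ValueError(f"unknown spectral_shape {self.spectral_shape!r}")

    # -- derived quantities (um units) -------------------------------------
    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm / _NM_PER_UM

    @property
    def k0(self) -> float:
        """Central wavenumber 1/lambda0 (cycles/um)."""
        return 1.0 / self.wavelength_um

    @property
    def kappa_max(self) -> float:
        """Support radius NAs/n of the radial profile."""
        return self.na_s / self.n

    @property
    def sigma_kappa(self) -> Optional[float]:
        """Standard deviation of the Gaussian radial profile (None = flat)."""
        if self.alpha is None:
            return None
        return self.kappa_max / self.alpha

    @property
    def spectral_fwhm_k(self) -> float:
        """FWHM of the spectral density on the wavenumber axis (cycles/um)."""
        dlam = self.fwhm_nm / _NM_PER_UM
        return dlam / self.wavelength_um**2

    @property
    def coherence_length_um(self) -> float:
        """lambda0^2 / dlambda, the temporal-envelope length scale."""
        return self.wavelength_um**2 / (self.fwhm_nm / _NM_PER_UM)


@dataclass(frozen=True)
class OpticsConfig:
    """Imaging/interference geometry of the virtual microscope.

    ``fc`` is the off-axis carrier frequency in cycles/um at the output
    plane; ``pixel_pitch_um`` is the detector pixel pitch in the same plane.
    The object-plane sampling is ``pixel_pitch_um / magnification``.
    """

    na: float = 0.30
    magnification: float = 10.0
    fc: Tuple[float, float] = (1.0 / 8.485, 1.0 / 8.485)
    ni: int = 512
    nj: int = 512
    pixel_pitch_um: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.na <= 1.5:
            raise ValueError("na out of range")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.ni < 8 or self.nj < 8:
            raise ValueError("detector too small")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.fc_mag >= self.nyquist:
            raise ValueError("carrier frequency violates the Nyquist limit")
        if self.fc_mag <= 0:
            raise ValueError("carrier frequency must be nonzero")

    @property
    def fc_mag(self) -> float:
        return float(np.hypot(*self.fc))

    @property
    def nyquist(self) -> float:
        """Nyquist frequency at the output plane (cycles/um)."""
        return 0.5 / self.pixel_pitch_um

    @property
    def dx_object_um(self) -> float:
        """Object-plane sampling interval (um/pixel)."""
        return self.pixel_pitch_um / self.magnification

    @classmethod
    def bin_aligned(
        cls,
        n: int = 512,
        dx_object_um: float = 0.6,
        magnification: float = 10.0,
        na: float = 0.30,
        fringe_px: float = 6.0,
    ) -> "OpticsConfig":
        """Build a config whose carrier lands on integer FFT bins.

        The carrier is oriented along the detector diagonal with roughly
        ``fringe_px`` pixels per fringe, rounded so that an integer number of
        fringe cycles fits across the field on each axis.  Bin-aligned
        carriers keep the empty-field sideband a single spectral spike, which
        makes reconstructions exactly uniform.
        """
        pitch = dx_object_um * magnification
        cycles = max(1, round(n / (fringe_px * math.sqrt(2.0))))
        f = cycles / (n * pitch)
        return cls(
            na=na,
            magnification=magnification,
            fc=(f, f),
            ni=n,
            nj=n,
            pixel_pitch_um=pitch,
        )


@dataclass
class MisalignmentState:
    """The 3-D alignment coordinate: lateral image displacement and path difference.

    ``qf = (xf, yf)`` is the mutual lateral displacement of the two arm
    images expressed in object-plane micrometres; ``dl`` is the signed
    optical path difference of the arms (um, image space).
    """

    xf: float = 0.0
    yf: float = 0.0
    dl: float = 0.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.xf, self.yf, self.dl))):
            raise ValueError("misalignment state must be finite")

    @property
    def qf(self) -> np.ndarray:
        return np.array([self.xf, self.yf], dtype=float)

    @property
    def qf_mag(self) -> float:
        return float(np.hypot(self.xf, self.yf))

    def copy(self) -> "MisalignmentState":
        return MisalignmentState(self.xf, self.yf, self.dl)


@dataclass
class SignalMap:
    """Normalized |w| sampled on a (|qf|, dl) grid; max over the grid is 1."""

    qf_um: np.ndarray
    dl_um: np.ndarray
    values: np.ndarray  # shape (len(qf_um), len(dl_um))
    normalization: float = 1.0


# ---------------------------------------------------------------------------
# quadrature nodes (cached per-source)

_N_KAPPA = 96
_N_K = 64
_GAUSS_SUPPORT_FWHM = 2.5  # half-width of the spectral window in FWHM units


def _kappa_rule(source: SourceModel, n: int = _N_KAPPA):
    """Gauss-Legendre nodes/weights on [0, kappa_max] with iT(kappa)*kappa folded in."""
    x, w = leggauss(n)
    a, b = 0.0, source.kappa_max
    kap = 0.5 * (b - a) * x + 0.5 * (b + a)
    wt = 0.5 * (b - a) * w * radial_source_intensity(kap, source) * kap
    return kap, wt


def _k_rule(source: SourceModel, n: Optional[int] = None):
    """Gauss-Legendre nodes/weights on the spectral support with iK(K) folded in."""
    if n is None:
        # the gaussian support window is ~5 FWHM wide; extra nodes keep the
        # oscillatory transform accurate out to large path differences
        n = _N_K if source.spectral_shape == "rectangular" else 2 * _N_K
    x, w = leggauss(n)
    if source.spectral_shape == "rectangular":
        lam = source.wavelength_um
        dlam = source.fwhm_nm / _NM_PER_UM
        a = 1.0 / (lam + 0.5 * dlam)
        b = 1.0 / (lam - 0.5 * dlam)
    else:
        half = _GAUSS_SUPPORT_FWHM * source.spectral_fwhm_k
        a = max(source.k0 - half, 1e-9)
        b = source.k0 + half
    kk = 0.5 * (b - a) * x + 0.5 * (b + a)
    wt = 0.5 * (b - a) * w * spectral_density(kk, source)
    wt = wt / wt.sum()  # discrete unit mass: exact normalization at dl=0
    return kk, wt


# ---------------------------------------------------------------------------
# elementary profile functions


def radial_source_intensity(kappa, source: SourceModel):
    """Radial intensity profile iT(kappa) of the effective source.

    Gaussian ``exp(-kappa^2/(2 sigma^2))`` with ``sigma = (NAs/n)/alpha``,
    truncated to zero outside the aperture support ``kappa <= NAs/n``; or a
    flat disc on the same support when ``alpha is None``.  ``iT(0) = 1``.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be nonnegative")
    inside = kappa <= source.kappa_max
    if source.alpha is None:
        out = inside.astype(float)
    else:
        sig = source.sigma_kappa
        out = np.where(inside, np.exp(-(kappa**2) / (2.0 * sig**2)), 0.0)
    return out if out.ndim else float(out)


def spectral_density(k, source: SourceModel):
    """Spectral density iK(K) on the wavenumber axis, unit integral.

    Gaussian: mean 1/lambda0, FWHM dlambda/lambda0^2.  Rectangular: constant
    on [1/(lambda0 + dlambda/2), 1/(lambda0 - dlambda/2)].
    """
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("wavenumber K must be positive")
    if source.spectral_shape == "rectangular":
        lam = source.wavelength_um
        dlam = source.fwhm_nm / _NM_PER_UM
        lo = 1.0 / (lam + 0.5 * dlam)
        hi = 1.0 / (lam - 0.5 * dlam)
        out = np.where((k >= lo) & (k <= hi), 1.0 / (hi - lo), 0.0)
    else:
        sig = source.spectral_fwhm_k / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        out = np.exp(-((k - source.k0) ** 2) / (2.0 * sig**2)) / (
            sig * math.sqrt(2.0 * math.pi)
        )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# coherence factors


def _lateral_raw(qf_mag: float, k: float, source: SourceModel, epsabs: float = 1e-12) -> float:
    """Unnormalized 2*pi * int iT(kappa) J0(2 pi K kappa q) kappa dkappa (adaptive)."""
    def f(kap: float) -> float:
        return float(
            radial_source_intensity(kap, source) * special.j0(2.0 * np.pi * k * kap * qf_mag) * kap
        )

    val, err = integrate.quad(f, 0.0, source.kappa_max, epsabs=epsabs, epsrel=1e-11, limit=200)
    if not math.isfinite(val) or err > max(1e-6, 1e-4 * abs(val)):
        raise ArithmeticError(
            f"lateral coherence quadrature did not converge: value={val}, err={err}"
        )
    return 2.0 * math.pi * val


def lateral_coherence(qf, k: float, source: SourceModel) -> float:
    """Normalized lateral (spatial) coherence factor at wavenumber K.

    ``2 pi int_0^{NAs/n} iT(kappa) J0(2 pi K kappa |qf|) kappa dkappa``
    divided by its ``qf = 0`` value.  Real by rotational symmetry of iT.
    For a flat-disc profile this is the Airy pattern ``2 J1(x)/x`` with
    ``x = 2 pi K (NAs/n) |qf|``.
    """
    q = float(np.hypot(*np.atleast_1d(qf))) if np.ndim(qf) else float(abs(qf))
    return _lateral_raw(q, k, source) / _lateral_raw(0.0, k, source)


def temporal_coherence(dl: float, source: SourceModel) -> complex:
    """Normalized temporal coherence factor gamma(dl) = int iK(K) e^{-2 pi i K dl} dK.

    Normalized by its ``dl = 0`` value; ``|gamma| <= 1``.  For a rectangular
    spectrum the modulus is the |sinc| envelope with first zero at
    ``lambda0^2/dlambda``; for a gaussian spectrum it is a gaussian in dl.
    """
    kk, wt = _k_rule(source)
    val = complex(np.sum(wt * np.exp(-2j * np.pi * kk * dl)))
    if not (math.isfinite(val.real) and math.isfinite(val.imag)):
        raise ArithmeticError("temporal coherence quadrature failed")
    return val


# ---------------------------------------------------------------------------
# the full signal


def theoretical_signal(state: MisalignmentState, source: SourceModel) -> complex:
    """Complex reconstructed holographic signal w(qf, dl), normalized to the origin.

    Evaluates the double integral (K outer, kappa inner) with a fixed
    Gauss-Legendre rule on each axis; both integrands are smooth, so the
    result is deterministic and accurate to well below 1e-6.
    """
    kk, wk = _k_rule(source)
    kap, wkap = _kappa_rule(source)
    # inner Hankel integral for every K node: shape (nK,)
    arg = 2.0 * np.pi * np.outer(kk, kap) * state.qf_mag
    inner = special.j0(arg) @ wkap
    norm = float(wkap.sum())  # inner integral at qf=0 (J0=1); spectral weights sum to 1
    w = np.sum(wk * np.exp(-2j * np.pi * kk * state.dl) * inner)
    return complex(w / norm)


def signal_map(qf_grid, dl_grid, source: SourceModel) -> SignalMap:
    """Normalized |w| on the outer product of a |qf| grid and a dl grid.

    ``qf_grid`` may hold scalars (radial distances) or 2-vectors.  The map is
    renormalized so its maximum is exactly 1.
    """
    qf_grid = np.asarray(qf_grid, dtype=float)
    dl_grid = np.atleast_1d(np.asarray(dl_grid, dtype=float))
    if qf_grid.size == 0 or dl_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if qf_grid.ndim == 2:
        q_mags = np.hypot(qf_grid[:, 0], qf_grid[:, 1])
    else:
        q_mags = np.abs(np.atleast_1d(qf_grid))

    kk, wk = _k_rule(source)
    kap, wkap = _kappa_rule(source)
    norm = float(wkap.sum())
    # inner integrals: shape (nq, nK)
    arg = 2.0 * np.pi * q_mags[:, None, None] * kk[None, :, None] * kap[None, None, :]
    inner = special.j0(arg) @ wkap
    phase = np.exp(-2j * np.pi * np.outer(kk, dl_grid))  # (nK, ndl)
    vals = np.abs((wk[None, :] * inner) @ phase) / norm
    peak = float(vals.max())
    return SignalMap(q_mags, dl_grid, vals / peak, normalization=peak)


def first_side_maximum(
    source: SourceModel, scan_factor: float = 6.0, n_scan: int = 4096
) -> Optional[Tuple[float, float]]:
    """Location and height of the first side maximum of |gamma(dl)| for dl > 0.

    Scans the temporal-coherence envelope out to ``scan_factor`` coherence
    lengths, finds the first local maximum after the envelope's first
    descent, and refines it by bounded scalar optimization.  Returns
    ``(dl_l1, height)`` or ``None`` when the envelope is monotone (gaussian
    spectrum).  The height is on the normalized scale (main maximum = 1).
    """
    lc = source.coherence_length_um
    dls = np.linspace(0.0, scan_factor * lc, n_scan)
    kk, wt = _k_rule(source)
    env = np.abs(np.exp(-2j * np.pi * np.outer(dls, kk)) @ wt)
    # interior local maxima; the floor rejects quadrature-truncation ripple,
    # which sits orders of magnitude below any physical side lobe
    interior = (env[1:-1] > env[:-2]) & (env[1:-1] >= env[2:]) & (env[1:-1] > 1e-3)
    idx = np.flatnonzero(interior) + 1
    if idx.size == 0:
        return None
    i = int(idx[0])
    lo, hi = dls[max(i - 2, 0)], dls[min(i + 2, n_scan - 1)]

    def neg_env(dl: float) -> float:
        return -abs(temporal_coherence(dl, source))

    res = optimize.minimize_scalar(neg_env, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-9})
    return float(res.x), float(-res.fun)


# ---------------------------------------------------------------------------
# small-angle bookkeeping


def max_inclination(na_eff: float, magnification: float) -> float:
    """Maximum beam inclination in image space: psi = arcsin(NA_eff / M)."""
    ratio = na_eff / magnification
    if not 0 <= ratio < 1:
        raise ValueError("NA_eff / M must lie in [0, 1)")
    return math.asin(ratio)


def inclination_phase_error(wavelength_nm: float, dl_um: float, psi_rad: float) -> float:
    """Phase-shift difference 2 pi K dl (1 - cos psi) between axial and inclined beams.

    When this is much smaller than pi the path-difference phase may be
    treated as independent of beam inclination, which is what permits the
    scalar dl in the signal integral.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    k = _NM_PER_UM / wavelength_nm  # cycles/um
    return 2.0 * math.pi * k * dl_um * (1.0 - math.cos(psi_rad))
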