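"""Virtual coherence-controlled holographic microscope.

Synthesizes what the detector of an off-axis holographic microscope sees as
a function of a *hidden* misalignment state (lateral image displacement
``qf`` and arm path difference ``dl``), so that alignment procedures can be
exercised and verified without hardware.  Two forward models are provided:

* a fast coherence-envelope model in which the fringe contrast is the
  product of the analytic temporal and lateral coherence factors
  ``|gamma(dl)| * |mu(qf)|`` (exact for the empty field, the regime in which
  the factorized signal integral is derived); and
* a brute-force incoherent mode-sum oracle that discretizes the source disc
  and the spectrum, propagates each tilted plane-wave mode through both
  arms, and sums intensities — no analytic coherence factors anywhere.

The interferometer is achromatic: the diffraction-grating geometry gives
the same fringe carrier frequency ``fc`` for every wavelength, so in the
mode sum each spectral mode interferes at the common carrier.

Alignment code must drive the microscope only through images and actuator
commands; the true misalignment is private and exposed solely via
:meth:`VirtualMicroscope.ground_truth` for test harnesses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Tuple

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import fft as sp_fft

from .signal_model import (
    MisalignmentState,
    OpticsConfig,
    SourceModel,
    _k_rule,
    lateral_coherence,
    radial_source_intensity,
    temporal_coherence,
)

__all__ = [
    "PhaseObject",
    "Hologram",
    "NoiseModel",
    "Actuator",
    "DriftProcess",
    "VirtualMicroscope",
    "ActuatorError",
    "ShutterError",
    "make_phase_object",
    "synthesize_hologram",
    "mode_sum_hologram",
    "single_arm_image",
    "apply_drift",
    "move_o2",
    "move_m2",
]


class ActuatorError(RuntimeError):
    """Commanded move exceeds the actuator travel range."""


class ShutterError(RuntimeError):
    """Image request inconsistent with the shutter state."""


@dataclass
class PhaseObject:
    """Sampled complex transmission of the object plane.

    ``amplitude`` in [0, 1] and ``phase`` in radians on a regular grid with
    spacing ``pixel_size_um`` (object-plane micrometres).
    """

    amplitude: np.ndarray
    phase: np.ndarray
    pixel_size_um: float
    kind: str = "flat"

    def __post_init__(self) -> None:
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase grids must match")
        if not (np.all(np.isfinite(self.amplitude)) and np.all(np.isfinite(self.phase))):
            raise ValueError("phase object must be finite")

    @property
    def transmission(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)

    @property
    def is_flat(self) -> bool:
        return bool(
            np.all(self.amplitude == self.amplitude.flat[0])
            and np.all(self.phase == self.phase.flat[0])
        )


@dataclass
class Hologram:
    """Real nonnegative detector frame plus the acquisition metadata."""

    data: np.ndarray
    optics: OpticsConfig
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.data < 0):
            raise ValueError("hologram counts must be nonnegative")


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: Gaussian read noise (fraction of mean intensity) and optional shot noise."""

    read_noise_frac: float = 0.01
    shot_noise: bool = False


@dataclass
class Actuator:
    """Quantized linear actuator with symmetric travel limits.

    Commanded moves are rounded to the nearest multiple of ``min_step_um``;
    a move that would leave ``[-travel_um, travel_um]`` raises
    :class:`ActuatorError` without moving.
    """

    min_step_um: float
    travel_um: float
    position_um: float = 0.0

    def quantize(self, delta: float) -> float:
        return round(delta / self.min_step_um) * self.min_step_um

    def move(self, delta: float) -> float:
        step = self.quantize(delta)
        target = self.position_um + step
        if abs(target) > self.travel_um + 1e-9:
            raise ActuatorError(
                f"move to {target:.3f} um exceeds travel +/-{self.travel_um} um"
            )
        self.position_um = target
        return step


@dataclass
class DriftProcess:
    """Slow drift of the hidden alignment: deterministic ramp + seeded random walk.

    Rates are per tick; axes are (xf, yf, dl) in micrometres.
    """

    ramp_um_per_tick: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    walk_std_um: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    def step(self) -> np.ndarray:
        ramp = np.asarray(self.ramp_um_per_tick, dtype=float)
        std = np.asarray(self.walk_std_um, dtype=float)
        return ramp + self._rng.normal(0.0, 1.0, size=3) * std


# ---------------------------------------------------------------------------
# phase objects


def make_phase_object(
    kind: Literal["flat", "checker", "cells-phantom", "sighting-pattern"],
    shape: Tuple[int, int],
    pixel_size_um: float,
    seed: Optional[int] = None,
    **params,
) -> PhaseObject:
    """Build a synthetic object-plane transmission.

    kinds
    -----
    ``flat``
        Unit amplitude, zero phase (the empty field).
    ``checker``
        Alternating phase blocks; ``block_px`` (default 16) and
        ``phase_rad`` (default 1.0).  Edges are softened by a small Gaussian
        blur (``soften_px``, default 2) so the pattern stays within the
        imaging band.
    ``cells-phantom``
        ``n_blobs`` smooth Gaussian phase blobs with peak phase drawn
        uniformly from ``phase_range`` (default (0.5, 3.0) rad), mimicking
        adherent cells; seeded.
    ``sighting-pattern``
        High-contrast absorbing crosshair-plus-ring fiducial of half-size
        ``half_px`` (default 15), used for shutter-gated arm registration.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    amp = np.ones(shape, dtype=float)
    phase = np.zeros(shape, dtype=float)

    if kind == "flat":
        pass
    elif kind == "checker":
        block = int(params.get("block_px", 16))
        amp_phase = float(params.get("phase_rad", 1.0))
        soften = float(params.get("soften_px", 2.0))
        mask = ((yy // block) + (xx // block)) % 2
        phase = amp_phase * mask.astype(float)
        if soften > 0:
            from scipy.ndimage import gaussian_filter

            phase = gaussian_filter(phase, soften, mode="nearest")
    elif kind == "cells-phantom":
        n_blobs = int(params.get("n_blobs", 8))
        lo, hi = params.get("phase_range", (0.5, 3.0))
        sig_px = params.get("sigma_px", (6.0, 14.0))
        rng = np.random.default_rng(seed)
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0.15, 0.85, 2) * (ny, nx)
            s = rng.uniform(*sig_px)
            pk = rng.uniform(lo, hi)
            phase += pk * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2)))
    elif kind == "sighting-pattern":
        half = int(params.get("half_px", 15))
        absorb = float(params.get("absorption", 0.85))
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        dy, dx = yy - cy, xx - cx
        r = np.hypot(dy, dx)
        cross = ((np.abs(dy) <= 1.5) | (np.abs(dx) <= 1.5)) & (r <= half)
        ring = np.abs(r - 0.7 * half) <= 1.2
        amp = 1.0 - absorb * (cross | ring).astype(float)
    else:
        raise ValueError(f"unknown phase-object kind {kind!r}")

    return PhaseObject(amp, phase, pixel_size_um, kind=kind)


# ---------------------------------------------------------------------------
# the microscope


class VirtualMicroscope:
    """Simulated off-axis holographic microscope with hidden misalignment.

    The public surface mirrors what alignment software sees on the real
    instrument: acquire images (hologram or shutter-gated single arm),
    insert/remove the sighting pattern, and command the O2 lateral stage and
    the M2 axial stage.  Shutter ``"s1"`` sits in the reference arm and
    ``"s2"`` in the object arm.

    The O2 stage convention is that commanding ``move_o2(-qf_measured)``
    nulls the lateral offset; M2 moves are expressed directly in path-
    difference micrometres (the mirror fold factor is absorbed into the
    actuator calibration).
    """

    def __init__(
        self,
        source: SourceModel,
        optics: OpticsConfig,
        state: Optional[MisalignmentState] = None,
        phase_object: Optional[PhaseObject] = None,
        noise: NoiseModel = NoiseModel(),
        o2_min_step_um: float = 0.05,
        o2_travel_um: float = 250.0,
        m2_min_step_um: float = 0.05,
        m2_travel_um: float = 400.0,
        pattern_offsets_um: Tuple[Tuple[float, float], Tuple[float, float]] = (
            (0.0, 0.0),
            (0.0, 0.0),
        ),
        seed: int = 0,
    ) -> None:
        if source.na_s > optics.na + 1e-12:
            raise ValueError("na_s must not exceed the objective na")
        self.source = source
        self.optics = optics
        self.noise = noise
        self.seed = seed
        self._true = (state or MisalignmentState()).copy()
        self._o2x = Actuator(o2_min_step_um, o2_travel_um)
        self._o2y = Actuator(o2_min_step_um, o2_travel_um)
        self._m2 = Actuator(m2_min_step_um, m2_travel_um)
        self.shutters = {"s1": True, "s2": True}  # True = open
        self.pattern_inserted = False
        self.pattern_offsets_um = pattern_offsets_um  # (object-arm, reference-arm)
        self._pattern: Optional[PhaseObject] = None
        self._object = phase_object or make_phase_object(
            "flat", (optics.ni, optics.nj), optics.dx_object_um
        )
        self._frame_counter = 0
        self._drift_log = [self._true.copy()]

    # -- plumbing ----------------------------------------------------------
    @property
    def phase_object(self) -> PhaseObject:
        return self._object

    def set_phase_object(self, obj: PhaseObject) -> None:
        if obj.amplitude.shape != (self.optics.ni, self.optics.nj):
            raise ValueError("phase object grid must match the detector")
        self._object = obj

    def ground_truth(self) -> MisalignmentState:
        """Hidden misalignment — for test harnesses and reporting only."""
        return self._true.copy()

    def drift_log(self):
        """Recorded hidden-state trajectory (test-harness use)."""
        return [s.copy() for s in self._drift_log]

    def _rng_for_frame(self) -> np.random.Generator:
        rng = np.random.default_rng([self.seed, self._frame_counter])
        self._frame_counter += 1
        return rng

    # -- shutters & pattern ------------------------------------------------
    def set_shutter(self, name: str, open_: bool) -> None:
        if name not in self.shutters:
            raise KeyError(name)
        self.shutters[name] = open_

    def insert_pattern(self, pattern: Optional[PhaseObject] = None) -> None:
        self._pattern = pattern or make_phase_object(
            "sighting-pattern", (self.optics.ni, self.optics.nj), self.optics.dx_object_um
        )
        self.pattern_inserted = True

    def remove_pattern(self) -> None:
        self.pattern_inserted = False
        self._pattern = None

    # -- actuators -----------------------------------------------------------
    def move_o2(self, delta_um) -> Tuple[float, float]:
        """Shift objective O2 by (dx, dy) object-plane micrometres."""
        dx, dy = float(delta_um[0]), float(delta_um[1])
        sx = self._o2x.move(dx)
        sy = self._o2y.move(dy)
        self._true.xf += sx
        self._true.yf += sy
        return sx, sy

    def move_m2(self, delta_um: float) -> float:
        """Shift mirror M2, expressed directly in path-difference micrometres."""
        s = self._m2.move(float(delta_um))
        self._true.dl += s
        return s

    # -- imaging -----------------------------------------------------------
    def _object_coords(self):
        n_i, n_j = self.optics.ni, self.optics.nj
        dx = self.optics.dx_object_um
        y = (np.arange(n_i) - n_i / 2.0) * dx
        x = (np.arange(n_j) - n_j / 2.0) * dx
        return np.meshgrid(y, x, indexing="ij")

    def _carrier_phase(self) -> np.ndarray:
        yy, xx = self._object_coords()
        m = self.optics.magnification
        fy, fx = self.optics.fc[1], self.optics.fc[0]
        # fc is cycles/um at the output plane; output coords are M * object coords
        return 2.0 * np.pi * m * (fx * xx + fy * yy)

    def _pupil_filter(self, fld: np.ndarray) -> np.ndarray:
        """Band-limit a field by the objective pupil (coherent cutoff NA/lambda0)."""
        dx = self.optics.dx_object_um
        n_i, n_j = fld.shape
        fy = sp_fft.fftfreq(n_i, d=dx)
        fx = sp_fft.fftfreq(n_j, d=dx)
        rho = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
        cutoff = self.optics.na / self.source.wavelength_um
        spec = sp_fft.fft2(fld)
        spec[rho > cutoff] = 0.0
        return sp_fft.ifft2(spec)

    def _render(self, obj: PhaseObject, shift_um: Tuple[float, float]) -> np.ndarray:
        """Sample a phase object's transmission shifted by (dx, dy) object um."""
        t = obj.transmission
        dx_px = shift_um[0] / obj.pixel_size_um
        dy_px = shift_um[1] / obj.pixel_size_um
        if dx_px == 0 and dy_px == 0:
            return t
        from scipy.ndimage import shift as nd_shift

        re = nd_shift(t.real, (dy_px, dx_px), order=1, mode="constant", cval=1.0)
        im = nd_shift(t.imag, (dy_px, dx_px), order=1, mode="constant", cval=0.0)
        return re + 1j * im

    def _arm_fields(self) -> Tuple[np.ndarray, np.ndarray]:
        """Band-limited object-arm and reference-arm fields at the output plane.

        The reference arm images an empty reference object; the hidden
        lateral offset shifts everything seen through that arm, including
        the sighting pattern when it is inserted.
        """
        off_o, off_r = self.pattern_offsets_um
        o = self._render(self._object, (0.0, 0.0))
        if self.pattern_inserted and self._pattern is not None:
            o = o * self._render(self._pattern, off_o)
        r = np.ones_like(o)
        if self.pattern_inserted and self._pattern is not None:
            qf = self._true.qf
            r = r * self._render(
                self._pattern, (off_r[0] + qf[0], off_r[1] + qf[1])
            )
        needs_filter = not (self._object.is_flat and not self.pattern_inserted)
        if needs_filter:
            o = self._pupil_filter(o)
            r = self._pupil_filter(r) if self.pattern_inserted else r
        return o, r

    def _finish(self, intensity: np.ndarray, meta: Dict) -> Hologram:
        rng = self._rng_for_frame()
        out = intensity.astype(float)
        if self.noise.shot_noise:
            scale = meta.get("shot_scale", 1000.0)
            out = rng.poisson(np.clip(out, 0, None) * scale) / scale
        if self.noise.read_noise_frac > 0:
            sigma = self.noise.read_noise_frac * float(out.mean())
            out = out + rng.normal(0.0, sigma, size=out.shape)
        out = np.clip(out, 0.0, None)
        meta = dict(meta, seed=self.seed, frame=self._frame_counter - 1)
        return Hologram(out, self.optics, meta)

    def acquire(self) -> Hologram:
        """Capture a frame honoring the current shutter state."""
        s1, s2 = self.shutters["s1"], self.shutters["s2"]
        if s1 and s2:
            return synthesize_hologram(self)
        if not s1 and not s2:
            return self._finish(
                np.zeros((self.optics.ni, self.optics.nj)), {"mode": "dark"}
            )
        return single_arm_image(self, closed_shutter="s1" if not s1 else "s2")

    def acquire_hologram(self) -> Hologram:
        if not (self.shutters["s1"] and self.shutters["s2"]):
            raise ShutterError("both shutters must be open for a hologram")
        return synthesize_hologram(self)


# ---------------------------------------------------------------------------
# forward models (module-level operations)


def synthesize_hologram(
    mic: VirtualMicroscope,
    coherence_override: Optional[Tuple[complex, float]] = None,
) -> Hologram:
    """Fast coherence-envelope hologram.

    ``I = |o|^2 + |r|^2 + 2 |gamma| |mu| Re[o r* exp(i (carrier + arg gamma))]``
    with ``gamma = temporal_coherence(dl)`` and ``mu = lateral_coherence(qf)``
    evaluated at the central wavenumber.  Exact for the empty field; for
    structured objects the factorized contrast is an approximation (the
    mode-sum model is the authority there).

    ``coherence_override=(gamma, mu)`` substitutes explicit coherence
    factors (testing hook for the fully coherent limit).
    """
    if not (mic.shutters["s1"] and mic.shutters["s2"]):
        raise ShutterError("both shutters must be open for a hologram")
    st = mic._true
    if coherence_override is not None:
        gamma, mu = complex(coherence_override[0]), float(coherence_override[1])
    else:
        gamma = temporal_coherence(st.dl, mic.source)
        mu = lateral_coherence(st.qf, mic.source.k0, mic.source)
    o, r = mic._arm_fields()
    carrier = mic._carrier_phase()
    cross = o * np.conj(r) * np.exp(1j * carrier) * (gamma * abs(mu))
    intensity = np.abs(o) ** 2 + np.abs(r) ** 2 + 2.0 * np.real(cross)
    meta = {
        "mode": "envelope",
        "state": (st.xf, st.yf, st.dl),
        "gamma": abs(gamma),
        "mu": abs(mu),
    }
    return mic._finish(intensity, meta)


def _source_modes(source: SourceModel, n_source_modes: int):
    """Polar quadrature of the source disc: (kappa_x, kappa_y, weight) triples."""
    n_az = max(8, int(round(math.sqrt(2.0 * n_source_modes))))
    n_rad = max(1, int(math.ceil(n_source_modes / n_az)))
    x, w = leggauss(n_rad)
    kap = 0.5 * source.kappa_max * (x + 1.0)
    wrad = 0.5 * source.kappa_max * w * radial_source_intensity(kap, source) * kap
    th = 2.0 * np.pi * np.arange(n_az) / n_az
    kx = np.outer(kap, np.cos(th)).ravel()
    ky = np.outer(kap, np.sin(th)).ravel()
    wt = np.repeat(wrad / n_az, n_az)
    return kx, ky, wt / wt.sum()


def mode_sum_hologram(
    mic: VirtualMicroscope,
    n_source_modes: int = 208,
    n_spectral_modes: int = 21,
) -> Hologram:
    """Brute-force incoherent-sum hologram: the oracle for the envelope model.

    Discretizes the source disc (weights ``iT``) and the spectrum (weights
    ``iK``); each mode is a tilted plane wave sent through both arms — the
    reference copy laterally shifted by the hidden ``qf`` and delayed by
    ``exp(-2 pi i K dl)`` — interfering at the common (achromatic) carrier.
    Mode intensities are summed with their weights.  The analytic coherence
    factors are never used.

    A single on-axis mode at a single wavelength reduces to the fully
    coherent hologram.
    """
    if n_source_modes < 1 or n_spectral_modes < 1:
        raise ValueError("mode counts must be >= 1")
    if not (mic.shutters["s1"] and mic.shutters["s2"]):
        raise ShutterError("both shutters must be open for a hologram")
    st = mic._true
    src = mic.source

    if n_source_modes == 1:
        kx = np.array([0.0]); ky = np.array([0.0]); ws = np.array([1.0])
    else:
        kx, ky, ws = _source_modes(src, n_source_modes)
    if n_spectral_modes == 1:
        kk = np.array([src.k0]); wk = np.array([1.0])
    else:
        kk, wk = _k_rule(src, n=n_spectral_modes)

    low_modes = (n_source_modes > 1 and n_source_modes < 64) or (
        1 < n_spectral_modes < 7
    )

    carrier = np.exp(1j * mic._carrier_phase())
    o_base, r_base = mic._arm_fields()
    yy, xx = mic._object_coords()
    intensity = np.zeros((mic.optics.ni, mic.optics.nj))

    flat = mic._object.is_flat and not mic.pattern_inserted
    if flat:
        # plane waves pass the pupil unchanged; per-mode cross terms collapse
        # to a single complex contrast coefficient
        amp2 = np.abs(o_base) ** 2 + np.abs(r_base) ** 2
        coeff = 0.0 + 0.0j
        for K, wK in zip(kk, wk):
            tilt_qf = np.exp(
                2j * np.pi * K * (kx * st.xf + ky * st.yf)
            )  # o r* tilt mismatch
            coeff += wK * np.exp(-2j * np.pi * K * st.dl) * np.sum(ws * tilt_qf)
        intensity = amp2 + 2.0 * np.real(
            o_base * np.conj(r_base) * carrier * coeff
        )
    else:
        for K, wK in zip(kk, wk):
            delay = np.exp(-2j * np.pi * K * st.dl)
            for cx, cy, wm in zip(kx, ky, ws):
                tilt = np.exp(2j * np.pi * K * (cx * xx + cy * yy))
                o = mic._pupil_filter(o_base * tilt)
                r_tilt = np.exp(
                    2j * np.pi * K * (cx * (xx - st.xf) + cy * (yy - st.yf))
                )
                r = r_base * r_tilt
                if mic.pattern_inserted:
                    r = mic._pupil_filter(r)
                w = wK * wm
                intensity += w * (
                    np.abs(o) ** 2
                    + np.abs(r) ** 2
                    + 2.0 * np.real(o * np.conj(r) * carrier * delay)
                )

    meta = {
        "mode": "mode-sum",
        "state": (st.xf, st.yf, st.dl),
        "n_source_modes": int(n_source_modes),
        "n_spectral_modes": int(n_spectral_modes),
        "low_mode_warning": bool(low_modes),
    }
    return mic._finish(intensity, meta)


def single_arm_image(mic: VirtualMicroscope, closed_shutter: str) -> Hologram:
    """Intensity of the arm whose shutter is still open (no fringes).

    ``closed_shutter="s1"`` blocks the reference arm (object-arm image);
    ``"s2"`` blocks the object arm (reference-arm image).  The shutters are
    driven to the requested state and left there.
    """
    if closed_shutter not in ("s1", "s2"):
        raise ShutterError("closed_shutter must be 's1' or 's2'")
    other = "s2" if closed_shutter == "s1" else "s1"
    mic.set_shutter(closed_shutter, False)
    mic.set_shutter(other, True)
    o, r = mic._arm_fields()
    fld = o if closed_shutter == "s1" else r
    intensity = np.abs(fld) ** 2
    meta = {"mode": "single-arm", "closed": closed_shutter}
    return mic._finish(intensity, meta)


def apply_drift(mic: VirtualMicroscope, drift: DriftProcess, ticks: int) -> None:
    """Advance the hidden state by ``ticks`` drift increments (ramp + walk)."""
    if ticks < 0:
        raise ValueError("ticks must be >= 0")
    for _ in range(int(ticks)):
        d = drift.step()
        mic._true.xf += d[0]
        mic._true.yf += d[1]
        mic._true.dl += d[2]
        mic._drift_log.append(mic._true.copy())


def move_o2(mic: VirtualMicroscope, delta_um) -> Tuple[float, float]:
    return mic.move_o2(delta_um)


def move_m2(mic: VirtualMicroscope, delta_um: float) -> float:
    return mic.move_m2(delta_um)
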