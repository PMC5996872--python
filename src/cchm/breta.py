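"""BReTA: basic realignment three-dimensional algorithm.

Automated alignment of the holographic microscope by maximizing the
field-averaged modulus of the reconstructed holographic signal (w-bar-D)
over the three alignment coordinates (xf, yf, dl):

* **initial alignment** — shutter-gated sighting-pattern registration nulls
  the lateral offset (the reference-arm pattern center minus the object-arm
  pattern center, divided by the magnification, is the required O2
  correction), then a stepped path-difference walk raises the signal above
  the threshold ``k * w_l1`` that separates the main coherence lobe from
  side maxima;
* **advanced alignment** — lateral raster scan or heuristic hill climb of
  O2, then an axial coarse/fine search of M2, iterated until the signal
  gain stalls;
* **maintenance** — a symmetric three-point dither on each axis, moving an
  element only when a neighboring position measures a strictly higher
  signal, which tracks slow drift during long-term experiments;
* **benchmark** — repeated randomized misalignment plus realignment,
  reporting the relative signal w-bar-D,s = 100 * w_final / w_reference.

All procedures drive the microscope exclusively through images and
actuator commands (shutters, pattern, O2/M2 moves) — never through the
simulator's hidden state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from skimage.feature import match_template

from . import holo_sim
from .holo_sim import VirtualMicroscope, ActuatorError, make_phase_object
from .reconstruction import mean_modulus, reconstruct
from .signal_model import MisalignmentState, OpticsConfig, first_side_maximum

__all__ = [
    "BretaParams",
    "AlignmentTrace",
    "SightingObservation",
    "PatternNotFoundError",
    "SignalMeter",
    "detect_pattern_centers",
    "initial_alignment",
    "lateral_raster_align",
    "lateral_hillclimb",
    "axial_align",
    "advanced_alignment",
    "maintenance_step",
    "maintenance_run",
    "benchmark_realignment",
    "BenchmarkResult",
]


class PatternNotFoundError(RuntimeError):
    """Sighting-pattern correlation peak below the detection threshold."""


@dataclass
class BretaParams:
    """Tunable parameters of the alignment procedures (lengths in um).

    Defaults follow the published operating points of the instrument: a
    10 um initial path-difference step, a 5x5 lateral raster with 0.5 um
    steps, an axial search refined down to 1 um, and 100/200 nm maintenance
    dither steps.  ``k`` is the safety factor applied to the first-side-
    maximum height when forming the initial-alignment threshold;
    ``noise_floor_rel`` replaces that height when the spectrum has no side
    maximum (gaussian envelope).
    """

    k: float = 1.2
    initial_dl_step_um: float = 10.0
    pattern_tolerance_um: float = 0.5
    max_pattern_iters: int = 10
    raster_n: int = 5
    raster_step_um: float = 0.5
    hill_step_um: float = 0.5
    revisit_count: int = 3
    stationarity_window: int = 5
    stationarity_ratio: float = 0.995
    max_iterations: int = 200
    axial_coarse_um: float = 10.0
    axial_fine_um: float = 1.0
    maint_lateral_um: float = 0.1
    maint_axial_um: float = 0.2
    noise_floor_rel: float = 0.05
    lateral_mode: str = "raster"  # or "hillclimb"
    advanced_rounds_eps: float = 0.01
    max_rounds: int = 3
    dl_scan_halfwidth_lc: float = 1.5  # stall-recovery scan, units of coherence length
    pattern_match_threshold: float = 0.35

    def __post_init__(self) -> None:
        if self.k <= 1:
            raise ValueError("safety factor k must exceed 1")
        for name in (
            "initial_dl_step_um", "raster_step_um", "hill_step_um",
            "axial_coarse_um", "axial_fine_um", "maint_lateral_um", "maint_axial_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.axial_fine_um > self.axial_coarse_um:
            raise ValueError("axial_fine_um must not exceed axial_coarse_um")
        if self.raster_n % 2 == 0:
            raise ValueError("raster_n must be odd")


@dataclass
class TraceRecord:
    step: int
    phase: str
    axis: str
    move_um: float
    wd: float
    wd_rel: float = float("nan")


@dataclass
class AlignmentTrace:
    """Time-ordered record of moves and signal measurements."""

    records: List[TraceRecord] = dc_field(default_factory=list)
    status: str = "running"  # success | threshold-not-reached | travel-exhausted
    final_rel_pct: float = float("nan")

    def add(self, phase: str, axis: str, move_um: float, wd: float,
            wd_rel: float = float("nan")) -> None:
        self.records.append(
            TraceRecord(len(self.records), phase, axis, float(move_um), float(wd),
                        float(wd_rel))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.step, r.phase, r.axis, r.move_um, r.wd, r.wd_rel) for r in self.records],
            columns=["step", "phase", "axis", "move_um", "wD_bar", "wD_bar_rel"],
        )

    def extend(self, other: "AlignmentTrace") -> None:
        for r in other.records:
            self.add(r.phase, r.axis, r.move_um, r.wd, r.wd_rel)


@dataclass
class SightingObservation:
    """Per-arm sighting-pattern centers and the derived lateral offset.

    ``po``/``pr`` are output-plane pixel coordinates (x, y); ``qf_prime_um``
    is their difference in output-plane micrometres; ``qf_um`` is the
    object-plane offset after dividing by the magnification.
    """

    po: Tuple[float, float]
    pr: Tuple[float, float]
    qf_prime_um: Tuple[float, float]
    qf_um: Tuple[float, float]

    @property
    def qf_mag_um(self) -> float:
        return float(np.hypot(*self.qf_um))


# ---------------------------------------------------------------------------
# measurement plumbing


class SignalMeter:
    """Measure w-bar-D from a freshly acquired hologram.

    Thin wrapper over acquire -> reconstruct -> mean modulus; the carrier
    and window radius default to the instrument's configured values.
    """

    def __init__(self, fc: Optional[Tuple[float, float]] = None,
                 radius: Optional[float] = None) -> None:
        self.fc = fc
        self.radius = radius

    def __call__(self, mic) -> float:
        h = mic.acquire_hologram()
        return mean_modulus(reconstruct(h, fc=self.fc, radius=self.radius))


def _single_arm(mic, arm: str) -> np.ndarray:
    """Shutter-gated capture of one arm: arm='obj' closes s1, arm='ref' closes s2."""
    closed = "s1" if arm == "obj" else "s2"
    other = "s2" if closed == "s1" else "s1"
    mic.set_shutter(closed, False)
    mic.set_shutter(other, True)
    img = mic.acquire()
    return img.data


def _open_shutters(mic) -> None:
    mic.set_shutter("s1", True)
    mic.set_shutter("s2", True)


def default_pattern_template(optics: OpticsConfig, half_px: int = 15,
                             margin_px: int = 8) -> np.ndarray:
    """Intensity template of the sighting pattern for cross-correlation."""
    pat = make_phase_object(
        "sighting-pattern", (optics.ni, optics.nj), optics.dx_object_um, half_px=half_px
    )
    c_i, c_j = optics.ni // 2, optics.nj // 2
    h = half_px + margin_px
    return (pat.amplitude[c_i - h:c_i + h, c_j - h:c_j + h]) ** 2


def _subpixel_peak_1d(lo: float, c: float, hi: float) -> float:
    denom = lo - 2.0 * c + hi
    if denom >= 0 or abs(denom) < 1e-300:
        return 0.0
    return float(np.clip(0.5 * (lo - hi) / denom, -1.0, 1.0))


def _locate(image: np.ndarray, template: np.ndarray, threshold: float) -> Tuple[float, float]:
    corr = match_template(image, template, pad_input=True)
    j = int(np.argmax(corr))
    py, px = divmod(j, corr.shape[1])
    if corr[py, px] < threshold:
        raise PatternNotFoundError(
            f"correlation peak {corr[py, px]:.2f} below threshold {threshold}"
        )
    dy = dx = 0.0
    if 0 < py < corr.shape[0] - 1:
        dy = _subpixel_peak_1d(corr[py - 1, px], corr[py, px], corr[py + 1, px])
    if 0 < px < corr.shape[1] - 1:
        dx = _subpixel_peak_1d(corr[py, px - 1], corr[py, px], corr[py, px + 1])
    return px + dx, py + dy  # (x, y)


def detect_pattern_centers(
    obj_img: np.ndarray,
    ref_img: np.ndarray,
    template: np.ndarray,
    optics: OpticsConfig,
    threshold: float = 0.35,
) -> SightingObservation:
    """Locate the sighting-pattern center in each arm image.

    Normalized cross-correlation against the template, refined to sub-pixel
    precision by a quadratic fit on the correlation peak.  The lateral
    offset is ``qf' = Pr - Po`` in output-plane units and ``qf = qf'/M`` in
    object-plane micrometres.
    """
    po = _locate(np.asarray(obj_img, float), template, threshold)
    pr = _locate(np.asarray(ref_img, float), template, threshold)
    pitch = optics.pixel_pitch_um
    qf_prime = ((pr[0] - po[0]) * pitch, (pr[1] - po[1]) * pitch)
    m = optics.magnification
    return SightingObservation(po, pr, qf_prime, (qf_prime[0] / m, qf_prime[1] / m))


# ---------------------------------------------------------------------------
# initial alignment


def initial_alignment(
    mic,
    params: Optional[BretaParams] = None,
    meter: Optional[SignalMeter] = None,
    template: Optional[np.ndarray] = None,
) -> AlignmentTrace:
    """Coarse alignment: pattern-based lateral nulling, then the dl walk.

    1. Insert the sighting pattern; alternately shutter the arms, locate the
       per-arm pattern centers, and command O2 by ``-qf`` until the residual
       offset is below the tolerance.
    2. Remove the pattern, calibrate the expected aligned signal from the
       two single-arm mean intensities (``sqrt(I_obj * I_ref)``), and form
       the threshold ``k * w_l1`` on that scale (``w_l1`` from the source's
       first temporal side maximum, or the configured noise floor for a
       lobe-free spectrum).
    3. If the measured signal is below threshold, walk the mirror M2 in the
       direction of increasing signal; a stall on a side-lobe summit
       triggers a coarse rescan one coherence length wide to hop toward the
       main lobe.
    """
    params = params or BretaParams()
    meter = meter or SignalMeter()
    trace = AlignmentTrace()

    mic.insert_pattern()
    tmpl = template if template is not None else default_pattern_template(mic.optics)
    try:
        for _ in range(params.max_pattern_iters):
            img_o = _single_arm(mic, "obj")
            img_r = _single_arm(mic, "ref")
            obs = detect_pattern_centers(
                img_o, img_r, tmpl, mic.optics, threshold=params.pattern_match_threshold
            )
            trace.add("pattern", "xy", obs.qf_mag_um, float("nan"))
            if obs.qf_mag_um <= params.pattern_tolerance_um:
                break
            mic.move_o2((-obs.qf_um[0], -obs.qf_um[1]))
    finally:
        mic.remove_pattern()

    # arm-intensity calibration of the aligned-signal scale
    i_obj = float(_single_arm(mic, "obj").mean())
    i_ref = float(_single_arm(mic, "ref").mean())
    _open_shutters(mic)
    w_hat_max = math.sqrt(max(i_obj, 0.0) * max(i_ref, 0.0))

    fsm = first_side_maximum(mic.source)
    w_l1_rel = fsm[1] if fsm is not None else params.noise_floor_rel
    threshold = params.k * w_l1_rel * w_hat_max

    w = meter(mic)
    trace.add("dl-walk", "dl", 0.0, w)
    if w > threshold:
        trace.status = "success"
        return trace

    _dl_threshold_walk(mic, meter, params, threshold, trace)
    return trace


def _dl_threshold_walk(mic, meter: SignalMeter, params: BretaParams,
                       threshold: float, trace: AlignmentTrace) -> None:
    """Uphill dl walk with stall recovery, until w-bar-D exceeds the threshold."""
    step = params.initial_dl_step_um
    lc = mic.source.coherence_length_um
    scan_half = params.dl_scan_halfwidth_lc * lc
    budget = params.max_iterations

    def move(d: float) -> float:
        s = mic.move_m2(d)
        return s

    def measure(mv: float) -> float:
        w = meter(mic)
        trace.add("dl-walk", "dl", mv, w)
        return w

    w_here = trace.records[-1].wd
    direction = 0.0
    while budget > 0:
        if direction == 0.0:
            # probe both neighbors to pick the uphill direction
            move(+step); w_p = measure(+step); budget -= 1
            if w_p > threshold:
                trace.status = "success"; return
            move(-2 * step); w_m = measure(-2 * step); budget -= 1
            if w_m > threshold:
                trace.status = "success"; return
            if w_p < w_here and w_m < w_here:
                # stalled on a local (side) maximum below threshold:
                # coarse rescan one coherence length to each side
                move(step)  # back to the stall point
                if not _dl_stall_rescan(mic, meter, params, threshold, trace,
                                        scan_half, step):
                    return
                w_here = trace.records[-1].wd
                if w_here > threshold:
                    trace.status = "success"; return
                continue
            if w_p >= w_m:
                move(2 * step)
                direction, w_here = +1.0, w_p
            else:
                direction, w_here = -1.0, w_m
            continue
        try:
            move(direction * step)
        except ActuatorError:
            trace.status = "travel-exhausted"; return
        w = measure(direction * step); budget -= 1
        if w > threshold:
            trace.status = "success"; return
        if w < w_here:
            direction = 0.0  # re-probe; may be a stall
        w_here = w
    trace.status = "threshold-not-reached"


def _dl_stall_rescan(mic, meter: SignalMeter, params: BretaParams, threshold: float,
                     trace: AlignmentTrace, scan_half: float, step: float) -> bool:
    """Serpentine coarse scan +/- scan_half around the stall; jump to the argmax.

    Returns False (setting the trace status) when travel runs out.
    """
    n = int(math.ceil(scan_half / step))
    offsets = [j * step for j in range(1, n + 1)] + [-j * step for j in range(1, n + 1)]
    best_off, best_w = 0.0, trace.records[-1].wd
    pos = 0.0
    try:
        for off in offsets:
            delta = off - pos
            mic.move_m2(delta)
            pos = off
            w = meter(mic)
            trace.add("dl-scan", "dl", delta, w)
            if w > best_w:
                best_off, best_w = off, w
        mic.move_m2(best_off - pos)
    except ActuatorError:
        trace.status = "travel-exhausted"
        return False
    trace.add("dl-scan", "dl", best_off - pos, best_w)
    if best_off == 0.0 and best_w <= threshold:
        trace.status = "threshold-not-reached"
        return False
    return True


# ---------------------------------------------------------------------------
# advanced alignment


def lateral_raster_align(
    mic,
    n_per_axis: int = 5,
    step_um: float = 0.5,
    meter: Optional[SignalMeter] = None,
    trace: Optional[AlignmentTrace] = None,
) -> Tuple[Tuple[float, float], AlignmentTrace]:
    """Serpentine n x n raster of O2 around the current position; move to the argmax.

    Ties are broken toward the grid center, then in row-major order.
    Returns the chosen offset (relative to the starting position) and the
    trace.
    """
    if n_per_axis % 2 == 0:
        raise ValueError("n_per_axis must be odd")
    meter = meter or SignalMeter()
    trace = trace if trace is not None else AlignmentTrace()
    c = n_per_axis // 2
    pos = np.zeros(2)
    best = None  # (w, dist2, order, offset)
    order = 0
    for i in range(n_per_axis):
        js = range(n_per_axis) if i % 2 == 0 else range(n_per_axis - 1, -1, -1)
        for j in js:
            target = np.array([(j - c) * step_um, (i - c) * step_um])
            mic.move_o2(target - pos)
            pos = target
            w = meter(mic)
            trace.add("raster", "xy", float(np.hypot(*(target))), w)
            d2 = float(target @ target)
            if (best is None or w > best[0]
                    or (w == best[0] and d2 < best[1])):
                best = (w, d2, order, target.copy())
            order += 1
    mic.move_o2(best[3] - pos)
    trace.add("raster", "xy", float(np.hypot(*(best[3] - pos))), best[0])
    return (float(best[3][0]), float(best[3][1])), trace


_HEADINGS = ((1.0, 0.0), (0.0, -1.0), (-1.0, 0.0), (0.0, 1.0))  # clockwise cycle


def lateral_hillclimb(
    mic,
    step_um: float = 0.5,
    params: Optional[BretaParams] = None,
    meter: Optional[SignalMeter] = None,
    trace: Optional[AlignmentTrace] = None,
) -> Tuple[Tuple[float, float], AlignmentTrace]:
    """Heuristic lateral walker: keep heading while the signal grows, turn right on a drop.

    Terminates when the best lattice position has been revisited
    ``revisit_count`` times, when the last ``stationarity_window``
    measurements have min/max ratio above ``stationarity_ratio``, or at the
    iteration cap — whichever occurs first; the walker then returns to the
    best visited position.
    """
    params = params or BretaParams()
    meter = meter or SignalMeter()
    trace = trace if trace is not None else AlignmentTrace()

    pos = np.zeros(2)
    w_prev = meter(mic)
    trace.add("hillclimb", "xy", 0.0, w_prev)
    key = (0, 0)
    visits: Dict[Tuple[int, int], int] = {key: 1}
    best_w, best_pos = w_prev, pos.copy()
    recent = [w_prev]
    heading = 0

    for _ in range(params.max_iterations):
        h = np.array(_HEADINGS[heading])
        try:
            mic.move_o2(h * step_um)
        except ActuatorError:
            trace.status = "travel-exhausted"
            break
        pos = pos + h * step_um
        w = meter(mic)
        trace.add("hillclimb", "x" if h[1] == 0 else "y",
                  float(step_um * (h[0] + h[1])), w)
        key = (round(pos[0] / step_um), round(pos[1] / step_um))
        visits[key] = visits.get(key, 0) + 1
        if w > best_w:
            best_w, best_pos = w, pos.copy()
        if w < w_prev:
            heading = (heading + 1) % 4  # the turn-right rule
        w_prev = w
        recent.append(w)
        if len(recent) > params.stationarity_window:
            recent.pop(0)
        best_key = (round(best_pos[0] / step_um), round(best_pos[1] / step_um))
        if visits.get(best_key, 0) >= params.revisit_count:
            break
        if (len(recent) == params.stationarity_window
                and min(recent) / max(recent) >= params.stationarity_ratio):
            break

    mic.move_o2(best_pos - pos)
    trace.add("hillclimb", "xy", float(np.hypot(*(best_pos - pos))), best_w)
    return (float(best_pos[0]), float(best_pos[1])), trace


def axial_align(
    mic,
    coarse_step_um: float = 10.0,
    fine_step_um: float = 1.0,
    meter: Optional[SignalMeter] = None,
    trace: Optional[AlignmentTrace] = None,
    max_steps: int = 100,
) -> Tuple[float, AlignmentTrace]:
    """Axial search of M2: coarse uphill walk to bracket the peak, then a fine scan.

    Returns the final offset of dl relative to the starting value.
    """
    meter = meter or SignalMeter()
    trace = trace if trace is not None else AlignmentTrace()
    pos = 0.0
    samples: Dict[float, float] = {}

    def measure_at(target: float) -> float:
        nonlocal pos
        mic.move_m2(target - pos)
        pos = target
        w = meter(mic)
        trace.add("axial", "dl", target, w)
        samples[round(target, 9)] = w
        return w

    w0 = meter(mic)
    trace.add("axial", "dl", 0.0, w0)
    samples[0.0] = w0
    w_p = measure_at(+coarse_step_um)
    if w_p >= w0:
        direction, w_prev, cur = +1.0, w_p, +coarse_step_um
    else:
        w_m = measure_at(-coarse_step_um)
        if w_m >= w0:
            direction, w_prev, cur = -1.0, w_m, -coarse_step_um
        else:
            direction, w_prev, cur = 0.0, w0, 0.0  # already bracketed around 0

    if direction != 0.0:
        for _ in range(max_steps):
            try:
                w = measure_at(cur + direction * coarse_step_um)
            except ActuatorError:
                trace.status = "travel-exhausted"
                break
            if w < w_prev:
                break
            cur += direction * coarse_step_um
            w_prev = w

    best_coarse = max(samples, key=lambda t: samples[t])
    lo, hi = best_coarse - coarse_step_um, best_coarse + coarse_step_um
    n_fine = int(round((hi - lo) / fine_step_um))
    for j in range(n_fine + 1):
        t = lo + j * fine_step_um
        if round(t, 9) in samples:
            continue
        try:
            measure_at(t)
        except ActuatorError:
            trace.status = "travel-exhausted"
            break
    best = max(samples, key=lambda t: samples[t])
    mic.move_m2(best - pos)
    pos = best
    trace.add("axial", "dl", best, samples[best])
    return float(best), trace


def advanced_alignment(
    mic,
    params: Optional[BretaParams] = None,
    meter: Optional[SignalMeter] = None,
) -> AlignmentTrace:
    """Lateral search followed by axial search, iterated until the gain stalls.

    The two searches are independent near the (smooth) global maximum, so
    their order is immaterial; rounds repeat while the relative signal gain
    per round exceeds ``advanced_rounds_eps`` (up to ``max_rounds``).
    """
    params = params or BretaParams()
    meter = meter or SignalMeter()
    trace = AlignmentTrace()
    w_before = meter(mic)
    trace.add("advanced", "", 0.0, w_before)
    for _ in range(params.max_rounds):
        if params.lateral_mode == "hillclimb":
            lateral_hillclimb(mic, params.hill_step_um, params, meter, trace)
        else:
            lateral_raster_align(mic, params.raster_n, params.raster_step_um, meter, trace)
        axial_align(mic, params.axial_coarse_um, params.axial_fine_um, meter, trace)
        w_after = trace.records[-1].wd
        if w_before > 0 and (w_after - w_before) / w_before < params.advanced_rounds_eps:
            break
        w_before = w_after
    trace.status = "success" if trace.status == "running" else trace.status
    return trace


# ---------------------------------------------------------------------------
# maintenance


def maintenance_step(
    mic,
    params: Optional[BretaParams] = None,
    meter: Optional[SignalMeter] = None,
    trace: Optional[AlignmentTrace] = None,
) -> Dict[str, float]:
    """One dither cycle: for each axis measure at -step, 0, +step and keep the argmax.

    An element moves only when a neighboring position measures a strictly
    higher signal; ties keep the current position.  Returns the applied
    correction per axis.
    """
    params = params or BretaParams()
    meter = meter or SignalMeter()
    trace = trace if trace is not None else AlignmentTrace()
    decisions: Dict[str, float] = {}

    axes = (
        ("x", params.maint_lateral_um, lambda d: mic.move_o2((d, 0.0))),
        ("y", params.maint_lateral_um, lambda d: mic.move_o2((0.0, d))),
        ("dl", params.maint_axial_um, lambda d: mic.move_m2(d)),
    )
    for name, step, mover in axes:
        try:
            w0 = meter(mic)
            mover(+step)
            w_p = meter(mic)
            mover(-2 * step)
            w_m = meter(mic)
        except ActuatorError:
            decisions[name] = float("nan")
            trace.add("maintain", name, 0.0, float("nan"))
            continue
        # currently at -step
        if w_p > w0 and w_p >= w_m:
            mover(+2 * step)
            applied = +step
            w_fin = w_p
        elif w_m > w0 and w_m > w_p:
            applied = -step
            w_fin = w_m
        else:
            mover(+step)
            applied = 0.0
            w_fin = w0
        decisions[name] = applied
        trace.add("maintain", name, applied, w_fin)
    return decisions


def maintenance_run(
    mic,
    drift: holo_sim.DriftProcess,
    n_ticks: int,
    params: Optional[BretaParams] = None,
    meter: Optional[SignalMeter] = None,
    maintain: bool = True,
) -> pd.DataFrame:
    """Drift the microscope for n_ticks, optionally running maintenance each tick.

    Returns a frame with the per-tick signal normalized to the initial
    (aligned) measurement.
    """
    params = params or BretaParams()
    meter = meter or SignalMeter()
    w_ref = meter(mic)
    rows = [(0, w_ref, 100.0)]
    for t in range(1, n_ticks + 1):
        holo_sim.apply_drift(mic, drift, 1)
        if maintain:
            maintenance_step(mic, params, meter)
        w = meter(mic)
        rows.append((t, w, 100.0 * w / w_ref))
    return pd.DataFrame(rows, columns=["tick", "wD_bar", "wD_bar_rel"])


# ---------------------------------------------------------------------------
# benchmark


@dataclass
class BenchmarkResult:
    trials: pd.DataFrame  # trial, status, wD_s
    histogram: pd.DataFrame  # bin_low, bin_high, count
    summary: Dict[str, float]


def benchmark_realignment(
    mic_factory: Callable[[MisalignmentState, int], "VirtualMicroscope"],
    n_trials: int = 20,
    misalign_magnitude_um: float = 100.0,
    seed: int = 0,
    params: Optional[BretaParams] = None,
    meter: Optional[SignalMeter] = None,
    bin_width: float = 5.0,
) -> BenchmarkResult:
    """Randomized realignment benchmark.

    Each trial builds a fresh microscope misaligned by the stated magnitude
    (lateral direction uniform on the circle, axial sign random), runs
    initial plus advanced alignment, and records the relative signal
    ``wD_s = 100 * w_final / w_reference`` where the reference is measured
    on an aligned instrument from the same factory.  Trial failures become
    their own histogram outcome (wD_s = 0) instead of exceptions.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = params or BretaParams()
    meter = meter or SignalMeter()
    rng = np.random.default_rng(seed)

    ref_mic = mic_factory(MisalignmentState(0.0, 0.0, 0.0), -1)
    w_ref = meter(ref_mic)

    rows = []
    for t in range(n_trials):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        st = MisalignmentState(
            misalign_magnitude_um * math.cos(theta),
            misalign_magnitude_um * math.sin(theta),
            sign * misalign_magnitude_um,
        )
        mic = mic_factory(st, t)
        try:
            tr = initial_alignment(mic, params, meter)
            if tr.status not in ("success",):
                rows.append((t, tr.status, 0.0))
                continue
            advanced_alignment(mic, params, meter)
            w_fin = meter(mic)
            rows.append((t, "success", 100.0 * w_fin / w_ref))
        except (PatternNotFoundError, ActuatorError) as exc:
            rows.append((t, type(exc).__name__, 0.0))

    trials = pd.DataFrame(rows, columns=["trial", "status", "wD_s"])
    edges = np.arange(0.0, 105.0 + bin_width, bin_width)
    counts, _ = np.histogram(trials["wD_s"], bins=edges)
    hist = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    ok = trials[trials["status"] == "success"]["wD_s"]
    summary = {
        "n_trials": float(n_trials),
        "n_success": float((trials["status"] == "success").sum()),
        "wD_s_min": float(ok.min()) if len(ok) else 0.0,
        "wD_s_mean": float(ok.mean()) if len(ok) else 0.0,
        "wD_s_median": float(ok.median()) if len(ok) else 0.0,
    }
    return BenchmarkResult(trials, hist, summary)
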