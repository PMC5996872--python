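# Methods

## The signal model

For a sample-free field, the reconstructed holographic signal of an off-axis
interferometric microscope under partially coherent Köhler illumination is

w(q_f, ΔL) = 2π ∫ i_K(K) e^(−2πiKΔL) ∫₀^{NA_s/n} i_T(κ) J₀(2πKκ|q_f|) κ dκ dK,

with K = 1/λ the wavenumber (cycles/μm), κ the normalized transverse
wavenumber of a source point, q_f the mutual lateral displacement of the arm
images in object-plane μm, and ΔL the signed optical path difference of the
arms. The inner Hankel integral is the lateral (spatial) coherence factor
set by the source's radial intensity i_T; the outer Fourier integral is the
temporal coherence factor set by the spectrum i_K. |w| is maximal at
q_f = 0, ΔL = 0 and all public values are normalized to that origin value.

Assumptions baked into this expression and the code:

* the objective pupil (NA ≥ NA_s) drops out of the sample-free integral;
* the path-difference phase is treated as inclination-independent. This is
  justified by the smallness of 2πKΔL(1 − cos ψ) for the maximum beam
  inclination ψ = arcsin(NA_eff/M): with λ = 650 nm, ΔL = 100 μm and
  ψ = arcsin(0.75/20) ≈ 0.038 rad the worst-case phase spread is ≈ 0.216π
  rad — `max_inclination` and `inclination_phase_error` expose exactly this
  bookkeeping;
* i_T is rotationally symmetric, so w depends on |q_f| only.

**Source parameterization.** i_T(κ) = exp(−κ²/2σ_κ²) truncated at the
aperture support κ ≤ NA_s/n. The reciprocal-width parameter α defines
σ_κ = (NA_s/n)/α; α = 2.5 is the default (a fit-derived value for the real
instrument's illumination), and `alpha=None` selects a uniform disc, whose
lateral coherence is the Airy pattern 2J₁(x)/x — one of the closed-form
oracles in the test suite. The published description of α leaves its exact
normalization open; the σ_κ = (NA_s/n)/α mapping is this package's
documented choice.

**Spectrum.** Two analytic narrowband shapes stand in for a physical
interference filter (a manufacturer-tabulated spectrum is out of scope):

* `rectangular` — constant on [1/(λ₀+Δλ/2), 1/(λ₀−Δλ/2)]. Its temporal
  envelope is |sinc(ΔK·ΔL)| with first zero at ≈ λ₀²/Δλ (42.25 μm for
  650/10 nm) and first side maximum 0.2172 at 1.4303·λ₀²/Δλ — the side
  maxima that the initial-alignment threshold must clear;
* `gaussian` — mean 1/λ₀, FWHM Δλ/λ₀² on the wavenumber axis; its envelope
  is a lobe-free Gaussian (and `first_side_maximum` correctly returns
  nothing).

**Quadrature.** Fixed Gauss–Legendre rules: 96 nodes on κ over the aperture
support; 64 nodes on K over the exact rectangular band or 128 nodes over
±2.5 FWHM of the Gaussian. The integrands are smooth, so the rules are
deterministic and accurate to ≲10⁻⁸ (verified against adaptive quadrature,
the closed forms above, and an independent dense Riemann double sum).
`lateral_coherence` itself uses adaptive Gauss–Kronrod with 10⁻¹² absolute
tolerance since it is called per-point.

## The virtual microscope

`VirtualMicroscope` holds a *hidden* misalignment state (x_f, y_f, ΔL) and
produces images only; alignment code talks to it through the same surface a
real instrument controller would expose: acquire frames, gate per-arm
shutters (s1 = reference arm, s2 = object arm), insert/remove a sighting
pattern, and command the O2 lateral stage and M2 axial stage. Moves are
quantized to the actuator minimum step (50 nm default) and bounded by
travel limits; `ground_truth()` exists for test harnesses only.

Two forward models generate holograms:

* **Envelope model** (`synthesize_hologram`):
  I = |o|² + |r|² + 2|γ(ΔL)||μ(q_f)| Re[o r* e^{i(2πf_c·q + arg γ)}], with
  γ the temporal and μ the lateral coherence factor evaluated at the central
  wavenumber. The factorization is exact for the empty field — the regime
  the signal integral is derived for — and approximate for structured
  objects.
* **Mode-sum oracle** (`mode_sum_hologram`): the source disc is discretized
  on a polar quadrature grid (radial Gauss–Legendre weighted by i_T(κ)κ,
  uniform azimuth) and the spectrum on a Gauss–Legendre rule weighted by
  i_K; every mode is a tilted plane wave propagated through both arms (the
  reference copy shifted by q_f and delayed by e^{−2πiKΔL}) and the mode
  intensities are summed. No analytic coherence factor appears anywhere, so
  the comparison of reconstructed w̄_D between the two models (≤ 3% RMS
  demanded, ≈ 0.7% measured) is a genuine two-route check. The μ factor in
  the fast path is evaluated at K₀ only; the K-dependence of the J₀ kernel
  across a 10 nm band is below 1.6% and is carried fully by the oracle.

The interferometer is **achromatic**: the diffraction-grating geometry of
this microscope family gives every wavelength the same fringe carrier f_c,
so each spectral mode in the oracle interferes at the common carrier. (A
chromatic carrier would make fringe contrast position-dependent and the two
forward models would diverge at the field edges.)

Defaults: 512×512 detector, carrier along the detector diagonal with ~6
px/fringe, rounded onto integer FFT bins so the empty-field sideband is a
single spectral spike; Gaussian read noise of 1% of the mean intensity
(shot noise optional), with a per-frame counter-derived RNG so identical
configs and seeds give bit-identical frames. The M2 actuator speaks ΔL
units directly — any mirror fold factor is part of the actuator
calibration. Drift is a per-axis deterministic ramp plus a seeded random
walk; defaults (0.05, 0, 0.15) μm/tick ramp with (0.01, 0.01, 0.02) μm/tick
walk emulate slow thermal drift that degrades an unmaintained instrument
within tens of maintenance periods while staying within the per-tick
correction capacity of the dither steps.

What the simulator deliberately does **not** model: aberrations of the
output optics (the real instrument's lateral asymmetries), chromatic
aberration (broadband peak broadening), the diffraction grating itself,
reflection mode, and numerical refocusing. Passing tests therefore
demonstrate correctness of the alignment logic and reconstruction chain
under an ideal achromatic instrument, not robustness to aberrated optics.

## Reconstruction

Centered 2-D FFT → sideband windowing → recentring → inverse FFT. The
window is a disc of default radius min(|f_c|/2, Nyquist − |f_c|) around the
carrier, multiplied by a radial Hanning taper (1 at the center, 0 at the
radius); both radius and carrier are arguments. The carrier can also be
estimated from the spectrum itself (largest out-of-DC magnitude, sub-bin
quadratic refinement, positive-x half-plane convention). Recentring is by
integer-bin roll; any sub-bin carrier residue appears as a linear phase ramp
that the polynomial background compensation removes.

w̄_D = Σ|w_D(i,j)|/(N_I N_J) is always computed over the full field; only
theory-comparison tests exclude an apodization border. The Hanning taper
costs in-band contrast for structured objects (a softened checker pattern
is recovered with ≈ 0.06 rad RMS against the raw pattern but matches the
taper-filtered linear prediction to < 10⁻³ rad) — a documented resolution
cost of the windowing, not an implementation defect.

Phase unwrapping uses a standard reliability-guided 2-D method
(scikit-image); unresolved residues are flagged in a quality mask rather
than raised. Background compensation fits a 2-D polynomial (default order
2) by least squares over a mask (default: whole field) and subtracts it,
leaving an exactly zero masked mean. The QPI noise resolution is
r = 2σ_φ over a background-only window; on ≥ 22,000 pixels of injected
Gaussian phase noise the identity holds within sampling error (±5%).

## Alignment procedures

**Initial alignment.** With the sighting pattern inserted, the arms are
shuttered alternately, the per-arm pattern centers are located by
normalized cross-correlation with sub-pixel quadratic refinement, and O2 is
commanded by −q_f = −(P_r − P_o)/M until |q_f| is below the tolerance
(0.5 μm, the acceptable lateral misalignment for ~90% signal). Then the
threshold w̄_D′ = k · w̄_l1 · ŵ_max is formed: w̄_l1 is the normalized first
side maximum from the signal model (or a configured noise floor for a
lobe-free spectrum), k = 1.2 clears the 0.217 sinc side lobe to 0.26 while
staying far below the main lobe, and ŵ_max = √(Ī_obj · Ī_ref) is the
aligned-signal scale calibrated from the two single-arm mean intensities —
exact for uniform empty-field arms, since the sideband modulus at perfect
alignment is |o||r| per pixel. If the measured signal is below threshold,
M2 walks in 10 μm steps in the direction of increasing w̄_D.

A pure uphill walk can stall on a side-lobe summit that is still below
threshold (starting at |ΔL| = 100 μm places the instrument near the third
sinc lobe, where both neighbors measure lower). On such a stall the walk
performs a serpentine coarse rescan ±1.5 coherence lengths around the stall
point and jumps to its argmax; because side-lobe heights increase strictly
toward ΔL = 0, each rescan moves at least one lobe toward the center and
the walk terminates on the main lobe.

**Advanced alignment.** A lateral search — 5×5 serpentine raster with
0.5 μm steps (ties broken toward the grid center, then row-major) or a
heuristic hill climb (keep heading while the signal grows, turn 90°
clockwise on a drop; terminate on best-position revisits ≥ 3, a min/max
ratio ≥ 0.995 over the last 5 measurements, or a 200-iteration cap,
whichever occurs first) — followed by an axial search (coarse 10 μm uphill
walk to bracket the peak, then a 1 μm fine scan across the bracket). Near
the smooth global maximum the two searches are independent, so their order
is immaterial (tested); rounds repeat while the per-round signal gain
exceeds 1%.

**Maintenance.** Per axis (x_f, y_f, ΔL): measure at the current position
and symmetrically at ±step (100 nm lateral, 200 nm axial), move to the
argmax, ties keeping the current position. Because decisions are made on
the same measurements, every accepted move has a measured signal not lower
than the departed position's.

**Benchmark.** Per trial: a fresh instrument is misaligned by 100 μm
laterally (uniform random direction) and 100 μm axially (random sign),
initial plus advanced alignment run, and w̄_D,s = 100·w̄_final/w̄_reference
recorded, with the reference measured on an aligned instrument from the
same factory. Twenty seeded trials land at w̄_D,s ≥ 99% (the acceptance
level is the 90% good-QPI threshold); failures would enter the histogram
as their own outcome rather than raising.

## Problem sizes and numerical choices

The default 512×512 detector is used for interactive work; the test suite
and the acceptance script run at sizes chosen to keep every study cheap
while preserving the physics: 256×256 with 1.0 μm object sampling wherever
±100 μm misalignments must keep the sighting pattern inside the field
(benchmark, initial-alignment studies), and 128×128 with 0.6 μm sampling
for the signal-surface, oracle-equivalence and maintenance studies. The
signal-surface grid is 5 |q_f| values × 9 ΔL values over
(|q_f| ≤ 2 μm) × (ΔL ≤ 40 μm); the mode-sum oracle uses 208 source modes ×
21 spectral modes. Maintenance runs 60 drift ticks.

Other conventions: 0-based pixel indices, spatial frequencies in cycles/μm,
centered spectra; lengths in μm internally, wavelengths entered in nm;
`move_o2(−q_f_measured)` nulls the lateral offset; commanded moves round to
the nearest actuator step; hologram counts are clipped at zero after noise.

## Known limitations

* The envelope model's contrast factorization is exact only for the empty
  field; structured-object holograms are trustworthy to the extent the
  mode-sum oracle agrees (tested for the empty field; structured objects
  rely on the per-mode propagation path, which is exact but slow).
* No aberration model: the real instrument's measured lateral asymmetries
  and broadband peak broadening have no analog here.
* The sighting-pattern registration assumes the pattern stays inside the
  field of view; the field must be chosen to cover the expected capture
  range (the wide-field test geometry covers ±100 μm).
* `first_side_maximum` ignores envelope features below 10⁻³ of the peak,
  which suppresses quadrature-truncation ripple but would also hide
  physically tiny side lobes of a nearly-Gaussian spectrum.
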