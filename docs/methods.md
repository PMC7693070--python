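# Methods

## Problem and model

In 2D spoiled multi-echo gradient-echo (mGRE) imaging, a macroscopic
through-slice field gradient `Gz` dephases the magnetization within the
slice and accelerates the apparent signal decay, biasing R2* estimates.
The signal at echo time `TE_i` is modelled as

    S(TE_i) = S0 · exp(−R2*·TE_i) · F_zshim(TE_i)

with the dephasing function

    F_zshim(TE_i) = ∫ M_xy(z) · exp(i γ (Gz + Ḡ_c,i) z TE_i) dz
                    ─────────────────────────────────────────────
                              ∫ M_xy(z) dz

where `M_xy(z)` is the complex slice profile and `Ḡ_c,i` the *mean
compensation gradient* of the z-shim train at echo i.  A train of
inter-echo compensation moments `m_c,k` (gradient area, T·s/m) is
equivalent, for modelling, to a constant gradient acting over the whole
echo time:  `Σ_{k≤i} m_c,k = Ḡ_c,i · TE_i`.  This duality is the basis of
the `patterns` module and is exact to machine precision by construction.

Normalizing F by `∫ M_xy dz` is this package's convention: it fixes
`F(TE→0) = 1`, so `S0` absorbs the profile integral and remains
interpretable as the extrapolated TE = 0 signal.  S0 comparisons across
methods are meaningful only within this convention.

## Shim schemes

* **off** — no compensation gradients.
* **global** — alternating pairs `(g⁺, 0, g⁻, 0, …)` of mean gradients
  after the unshimmed leading echoes; each pair is rewound so every second
  shimmed echo is an ordinary GRE image (zero net moment).
* **adaptive** — per-slice extrema `(g⁺ₙ, g⁻ₙ)` estimated from a prescan
  are split into fractions `(1/3, 2/3, 3/3)` applied on consecutive
  echoes, followed by a moment-nulling echo; when one extremum is zero the
  other is split into five fractions `(1/5 … 5/5)` instead.  For the
  16-echo head protocol the accumulated moment is zero at echoes 8, 12
  and 16.

Moments are attributed to the interval immediately preceding each echo;
their placement within the interval is irrelevant to the model and not
represented.  If the echo train ends mid-block the block is truncated.
A configurable hardware amplitude check (`|m|/t_c` against a limit) warns
rather than errors, since no universal limit exists.

## Slice profiles

`M_xy(z)` is computed by hard-pulse Bloch integration of the RF envelope
under the slice-select gradient `Gslice = TBW/(T_pulse·γ̄·Δz)`, with the
slice-refocusing lobe (area `−Gslice·T_pulse/2`) applied explicitly as a
free precession.  Defaults: 512 sub-pulses, 2048-point z-grid over
±3·Δz.  The envelope amplitude is calibrated so the on-resonance flip
equals `α·ξ`, where ξ is the transmit (B1+) scale.  Checks: the
on-resonance magnitude equals sin(α·ξ) to <1 %, the small-tip profile
correlates >0.999 with the Fourier transform of the envelope, and
doubling either discretization changes results by ≪0.1 %.

Three secondary effects are supported:

* **B1+** — multiplicative flip-angle scale ξ.
* **TR/T1** — spoiled-GRE steady-state weighting
  `(1−E1)/(1−E1·cosθ(z))`, `E1 = exp(−TR/T1)`, with `cosθ(z)` the local
  longitudinal component after the pulse.
* **λ-rescaling** — a background gradient superimposed on `Gslice`
  changes the spatial encoding to `z′ = z·λ`, `λ = Gslice/(Gz+Gslice)`;
  the cached Gslice-only profile is coordinate-rescaled rather than
  re-simulated (≈100× cheaper; `Gz = −Gslice` is rejected as singular).
  The compensation gradients do **not** enter λ: they act between
  excitations, not during.

Neglected: T2 relaxation during the 2 ms pulse (≪ T2), relaxation during
the pulse in the steady-state weighting, and non-ideal spoiling.

## Dephasing evaluation and lookup table

F is evaluated by trapezoidal quadrature on the profile grid.  Because
λ-rescaling only scales coordinates, F reduces to a function of the
scalar phase-ramp slope `u = γ(Gz+Ḡ_c,i)·λ(Gz)·TE_i` on the unscaled
grid, enabling vectorized voxelwise evaluation.  For reconstruction a
table over a uniform Gz grid (default ±300 µT/m at 10 µT/m, matching the
prescan quantization) is precomputed and linearly interpolated; queries
outside the grid flag the voxel as excluded.

Numerical notes measured on the default protocols:

* Quadrature is converged: doubling the z-grid changes F by ~1e-10.
* Table interpolation is accurate to <0.5 % (absolute in |F|) for the
  head TE schedule (≤60.6 ms).  For the 20-echo phantom schedule
  (TE ≤ 98.8 ms) it degrades to ~2 % near |Gz| = 300 µT/m; such
  voxels are strongly dephased and noise-dominated in practice.
* |F| can marginally exceed 1 (max 1.0018 at 60°) because the Bloch
  profile retains ~0.2 rad of nonlinear large-tip phase that a small
  linear phase ramp can partially compensate; for flat-phase profiles
  |F| ≤ 1 holds exactly.

## Prescan processing

The 3-echo prescan (TE = 2.7/4.8/6.9 ms) is processed as: 3D phase
unwrapping (quality-guided, from scikit-image; only spatial gradients of
the result are used, so per-region 2π offsets cancel) → field map
`(φ₃−φ₁)/(2π·ΔTE)` → magnitude mask (Otsu by default, or explicit
threshold, or an externally supplied mask) eroded slicewise with a disk
element (2D "disk" reading of the erosion; radius 5 px default) →
through-slice central differences inside the mask (one-sided at volume
and mask edges; voxels with no in-mask z-neighbour are dropped) →
masked, normalized 3D Gaussian smoothing (σ = 1 voxel) → quantization to
10 µT/m **bin centres** `q = (floor(g/Δ)+½)·Δ` → per-slice selection.

Quantizing to bin centres (odd multiples of 5 µT/m) rather than nearest
multiples of 10 is deliberate: selected gradients are then never exactly
zero and the rule is idempotent.

Selection sign convention: the compensation must *oppose* the field
gradient, so `g⁺ₙ = −min(Gzₙ < 0)` (0 if none negative) and
`g⁻ₙ = −max(Gzₙ > 0)` (0 if none positive).  An empty slice mask yields
(0, 0) with a warning, i.e. no shimming for that slice.

## Synthetic data

The generator produces voxelwise images from the signal model; in-plane
readout encoding is not simulated because the model is purely
through-slice.  Phase-encode "shots" exist as the unit of physiological
fluctuation: each (line, slice) shot carries one global field offset δB
shared by its echoes and navigator.  The default fluctuation is a
respiration-like 0.3 Hz sinusoid of 5 nT amplitude sampled at
`t = shot·TR` (sub-TR slice-timing offsets are neglected; δB varies on a
~3 s scale).  Noise is complex Gaussian per channel, so magnitude images
are Rician by construction (background magnitude follows the Rayleigh
law).

Built-in phantoms:

* `uniform-agar` — homogeneous cylinder, R2* = 6.4 1/s, 4 mm slices,
  quadratic-in-z b0 whose through-slice gradient ramps ≈ −200 → +150
  µT/m across 26 slices in 14 µT/m steps (deliberately off the 10 µT/m
  quantization-bin edges, where the bin assignment of an exactly
  boundary-valued gradient would be decided by floating-point round-off).
* `layered-r2star` — five in-plane layers, R2* 5–40 1/s, zero field.
* `invivo-like` — elliptical head: white matter 19 1/s, cortical rim
  22 1/s, two deep-nucleus blobs 31 and 38 1/s, 3 mm slices, plus two
  smooth gradient pockets (≈ +120 and −150 µT/m) emulating sinus fields.

What passing tests on these phantoms do **not** show: robustness to
in-plane dephasing, motion, parallel-imaging artifacts, imperfect
spoiling, multi-compartment decay, or coil-combination phase errors —
none of which the generator emulates.

## Fitting

Per voxel, `Σ_i (|S_i| − S0·e^{−R2*·TE_i}·|F_i|)²` is minimized over
`S0 ≥ 0`, `R2* ∈ [0, 500] 1/s` (trust-region reflective least squares
with analytic Jacobian, relative step tolerance 1e-8, 200 function
evaluations).  |F| enters the magnitude objective; the phase of F is
discarded.  Initialization is a log-linear regression on the leading
unshimmed echoes — deterministic, and least F-contaminated at small Gz.
Rician bias is accepted at the simulated SNRs; all echoes are fitted.
Excluded voxels (Gz outside the table, empty signal, masked out) are
flagged, never silently zeroed.  B1+ and TR/T1 enter, when requested,
through the profile used to build the table; the default is ξ = 1,
TR/T1 = ∞.  Region summaries report median and IQR with linear
interpolation between order statistics.

## Navigator correction

For shot s, `Δφ(s)` is the navigator phase relative to the first shot;
echo i is multiplied by `exp(−i·Δφ(s)·TE_i/TE_navi)` (the fluctuation
phase is linear in TE).  Magnitude-only input is returned unchanged with
a warning.  A shot-constant δB is removed exactly; the residual global
phase common to all shots does not affect magnitude fitting.

## Sensitivity analysis

The mismodelling grid forward-simulates the noiseless decay with a
reference model containing B1+ (ξ), λ and the steady state, then refits
R2* with (a) a full model that includes ξ and λ but neglects TR/T1 and
(b) a reduced model with nominal flip and λ = 1.  Both fitting variants
neglect TR/T1, so short-TR rows isolate the T1 bias.  Defaults:
α ∈ {30, 60, 90}°, ξ ∈ {0.6 … 1.4}, TR/T1 ∈ {2, 5}, R2* = 30 1/s,
head TE schedule, Gz ±200 µT/m at 10 µT/m.  With the reduced model at
α = 60°, TR/T1 = 5, ξ ∈ {0.8, 1, 1.2} and |Gz| ≤ 100 µT/m the maximum
relative R2* error computed here is ≈ 7 %; with the full model it is
≈ 0.1 %.

## Problem sizes and determinism

Desk-scale defaults keep every end-to-end check in seconds to a couple
of minutes on one core: 16×16×26 agar phantom, 24×24×12 head phantom,
2048-point profiles, 61-point tables.  All stochastic steps draw from
`numpy.random.default_rng(seed)`; identical seeds give bit-identical
outputs.  Paper-style protocol presets interpolate their TE lists
linearly between the printed first/last values of each echo block
(the printed spacings are nominal and not exactly arithmetic); TE lists
are always taken from configuration, never regenerated from spacings.

## Known limitations

* Through-slice effects only; in-plane gradients and voxel spread are
  out of scope.
* The unwrapper is a generic quality-guided 3D algorithm; pathological
  wraps at very low SNR may differ from dedicated tools.
* The slice-profile cache assumes the same pulse/flip for all slices.
* Erosion is slicewise 2D; a 3D structuring element is not offered.
* The mask threshold for phantom data defaults to Otsu; explicit
  thresholds are recommended for synthetic data with known background.
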