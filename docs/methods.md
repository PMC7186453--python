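# Methods

## Signal model

A direct current I applied during an MR acquisition induces a static
magnetic field; MRI phase is sensitive to the component along the main
field axis, Bz. At echo time TE the accrued phase is

    φ(v, t) = (γ · Bz(v) · I(t) · TE) mod 2π,       γ = 2.6752218744×10⁸ rad/s/T

so a field of 1 nT at TE₂ = 26 ms accrues 6.956×10⁻³ rad (0.39°). Because
the induced field is linear in the applied current (Ampère's law), the
per-voxel regression slope of unwrapped phase on current, divided by γ·TE₂,
is the induced field per milliampere (nT/mA). The echo-2 magnitude of the
same acquisition carries BOLD contrast; its dependence on the applied
current quantifies current-locked effects (wanted: neurovascular; unwanted:
dephasing confounds).

Units are fixed throughout: mm for geometry, mA for current, nT for field,
seconds for time, radians for phase.

## Forward simulation

`biot_savart_bz` sums the exact closed form for the field of a finite
straight segment,

    B = (μ₀ I / 4π d) (cos θ₁ − cos θ₂) φ̂,

over the segments of a polyline current path, evaluated at voxel centres
and reduced to the z-component. The closed form (rather than quadrature)
makes desk-scale results exact to floating point, so superposition and
current-reversal antisymmetry hold bit-exactly. Voxels closer than
`min_distance` to any segment are masked out; the default of half the
smallest voxel spacing removes only the voxels where the 1/d divergence
makes a point measurement meaningless. The wire-phantom fixture places a
horizontal wire through the midplane of a cylindrical water volume; the
wire extends 40× the grid extent beyond the grid, so within the grid it is
indistinguishable (< 1%) from the infinite-wire closed form
`Bz = (μ₀I/2π)·Δy/(Δy²+Δz²)` used as the independent oracle. The physical
wire radius only enlarges the exclusion region; the current is treated as a
line current, and no claim is made about the current density inside the
wire.

Volumetric current densities from FEM head models are out of scope; such
fields enter the pipeline only as precomputed NIfTI field maps.

## Synthetic acquisition

`simulate_series` generates the complex signal per voxel, volume and echo:

    baseline · exp(i[ω₀(v)·TEₑ + γ·Bz(v)·I(t)·10⁻⁹·TEₑ + drift·t + shift(scan)])

plus independent complex Gaussian noise on the real and imaginary parts;
magnitude and wrapped phase (canonical interval [−π, π)) are stored, and
the noise-free unwrapped phase is retained as ground truth. Choices that
matter:

* **Static background ω₀** — a seeded Gaussian random field smoothed over
  3 voxels, scaled to a target SD of 120 rad/s (a plausible post-shim B0
  inhomogeneity at 3 T), then rescaled down if needed so no neighbouring
  voxels differ by more than π/2 of phase at the longest echo. A shimmed
  field is spatially smooth; without this constraint small grids can
  produce background phase that no algorithm could unwrap, which would test
  the generator rather than the method.
* **Echo scaling** — the background and current-induced phase are both
  proportional to TE (field-inhomogeneity-dominated regime), which is what
  makes the short echo usable as an unwrapping anchor. Instrumental drift
  (rad/volume) and between-scan level shifts are applied equally to both
  echoes.
* **BOLD injection** — a multiplicative effect on the echo-2 magnitude
  only (the echo-1 magnitude is not used downstream):
  `1 + effect_per_mA · (I ⊛ HRF)(t)` inside a region. The HRF is a
  double-gamma (peak 6 s, undershoot 16 s, 6:1 amplitude ratio) sampled at
  TR and normalized to unit sum, so the convolved waveform plateaus at the
  block's current level and `effect_per_mA` reads as fractional change per
  mA.
* **Noise level** — the default phantom and cohort settings use complex
  SNR 50 (baseline magnitude 100, noise SD 2), a conservative EPI
  time-series SNR.

Block designs come from `make_waveform`: each scan holds the given current
levels once (or repeatedly) in a seeded pseudo-random order, each level for
one block. The phantom protocol is levels {0, 0.5, 1, 1.5} mA, 180 s blocks,
TR 4 s, three 12-minute scans; the faster human-like protocol is levels
{0, 1, 1.5, 2} mA, 90 s blocks, TR 2 s.

The cohort fixture emulates a bilateral electrode montage: two Gaussian
field lobes of opposite sign (peak 2 nT/mA) under left/right patches, a
lognormal per-subject amplitude jitter (SD 0.2), and a BOLD injection under
the negative ("cathodal") lobe. The injected effect is −0.15 per mA with a
between-subject SD of 0.05: group statistics on real cohorts are dominated
by between-subject variability of the response, and a cohort with zero
effect variance would make the group standard error degenerate
(measurement-noise-only), turning any tiny systematic — e.g. the Rician
bias of magnitude data, here ~10⁻⁴ — into a spurious group effect. Each
subject's realized effect is recorded in the series ground truth so that
parameter-recovery tests compare estimates against the realized target.

What the generator does **not** emulate: EPI distortion and k-space
artifacts, physiological noise, motion (realignment is out of scope; motion
parameters are consumed as an input table), intravoxel dephasing itself,
and spatially structured resting-state fluctuations. Passing tests
therefore demonstrate correctness of the estimation chain under the stated
noise model, not robustness to every artifact of real acquisitions.

## Phase unwrapping

The internals of published 4D region-growth unwrappers are not fully
specified, so the algorithm here is defined by this package:

1. **Quality map** — per voxel, 1/(1 + Σ over axes of squared wrapped
   second differences): 1 for locally linear phase, low at noise spikes and
   aliasing. Invariant to global offsets.
2. **Spatial pass (echo 1, volume 1)** — region growth from the
   highest-quality voxel (per connected mask component), visiting voxels in
   decreasing quality order; each new voxel is shifted by the 2π multiple
   closest to the mean of its already-unwrapped neighbours.
3. **Echo bootstrap (echo 2, volume 1)** — the echo-1 phase predicts the
   echo-2 phase scaled by TE₂/TE₁ (≈ 2.36). The prediction inherits the
   echo-1 global-cycle ambiguity, which after scaling is *not* a 2π
   multiple, so a global circular offset between prediction and wrapped
   echo-2 phase is estimated (resultant angle over the mask) and removed
   before per-voxel cycle selection; one spatial-consistency growth pass
   then repairs isolated errors. Voxels whose residual against the
   prediction exceeds π/2 are flagged; if more than 20% of the mask is
   flagged the series is rejected as unusable (`ExcessivePhaseWrapsError`).
   The 20% threshold is this package's explicit rejection rule.
4. **Temporal pass (volumes 2…T)** — per voxel, each volume is shifted by
   the 2π multiple nearest the previous volume, valid when phase changes
   less than half a cycle per TR (at TE₂ = 26 ms that allows current-step
   field changes up to ~65 nT, far above the nT-scale fields of interest).

Every output is congruent to its input modulo 2π to ~10⁻¹⁰ rad, and the
remaining global cycle is fixed by putting the masked median of volume 1
into (−π, π] — the GLM slope is invariant to this convention.

Between-scan level shifts are detected on the mask-mean phase trace: a scan
boundary whose jump exceeds 3× the robust SD (1.4826×MAD) of ordinary
volume-to-volume jumps gets a 0/1 step regressor.

## Field and magnitude GLMs

Per-voxel ordinary least squares of the unwrapped phase on: intercept, one
centred linear trend per scan, the applied current (mA), and optional
nuisance columns (6 motion parameters, the mask-mean global signal,
detected level-shift steps). All scans are fitted in one concatenated model
with scan-wise trend columns rather than averaging per-scan fits.
Numerically all-zero columns are dropped with a log record — in particular
the current column of a Sham session, after which slope inference is
refused rather than silently returning zeros. Rank-deficient designs are
rejected with the offending columns named. No autocorrelation prewhitening
is applied: with 45-volume blocks the current regressor's power is at
frequencies where EPI phase noise is near-white, and the estimator's
unbiasedness (not its SE calibration) is what the validation relies on;
this is a known simplification.

The global-signal regressor is the masked mean of the quantity being
modelled (phase or magnitude). For the phantom's mirror-antisymmetric field
the mask-mean field is ~0, so this column does not absorb the effect of
interest; for arbitrary field patterns it can, which is inherent to
global-signal regression.

The magnitude GLM uses the same design on the echo-2 magnitude; slopes are
scaled by the voxel's session-mean signal into percent per mA (so an
injected fractional effect e appears as 100·e/(1 + e·Ī) with Ī the mean
applied current), and family-wise error is controlled by Bonferroni over
the mask — the simplest valid choice, deliberately conservative.

## Dephasing confound models

A field difference across a voxel of |∇Bz| (nT per voxel) spreads the
intravoxel phase by φ = γ·|∇Bz|·10⁻⁹·TE₂ per mA. Two closed forms bound the
resulting fractional magnitude loss: Model 1, `1 − cos(φ/2)`, concentrates
the spread at the voxel's extremes (worst case, small-angle behaviour
φ²/8); Model 2, `1 − sin(φ/2)/(φ/2)`, assumes a linear spread (φ²/24). Their
small-angle ratio is 3. The gradient is computed by central differences in
nT per voxel step — the dephasing span across one voxel is what matters,
not the per-mm gradient — and the worst case is its maximum over the
analysis region (a percentile option is provided). At the observed
worst-case |∇Bz| ≈ 1 nT/mA the ratios of modelled confound to observed
per-mA BOLD changes of −0.15/−0.11 are 4.0×10⁻⁵/5.5×10⁻⁵ (Model 1) and
1.3×10⁻⁵/1.8×10⁻⁵ (Model 2): dephasing cannot explain the observed effects.

## Validation statistics

* **Spatial Pearson** over a mask, with two-tailed p.
* **Range-restricted regression**: OLS of measured on reference over voxels
  with |reference| ≤ bound, for descending bounds (default ∞/10/5/1 nT);
  rows with fewer than 3 voxels are flagged, not fitted.
* **Paired t-test** of per-subject mean field strengths (two-sided);
  degenerate zero-variance differences return p = 1 (zero mean) or 0.
* **ICC(2,1)**: two-way random-effects, absolute-agreement,
  single-measurement intraclass correlation with voxels as targets and
  sessions as raters, computed from the ANOVA mean squares. This variant
  (among the Shrout–Fleiss family) is fixed by design and cross-checked
  against an independent implementation in the tests.
* **Cluster thresholding**: voxels below a p threshold, 26-connected
  components smaller than a minimum size removed (SPM-like connectivity).
* **DICE** overlap; an error when both masks are empty.
* **Component–current group test** (dual-regression style): stage 1
  projects each volume onto a variance-normalized spatial component map
  (least squares, so a one-voxel map returns that voxel's timecourse up to
  scale); stage 2 regresses the timecourse on the HRF-convolved current
  waveform (a raw-waveform option exists — the induced field follows the
  block design directly, the BOLD response follows its convolution). The
  per-subject effect is slope/intercept: fractional signal change per mA
  relative to the zero-current baseline, which is what an injected
  fractional effect equals; a z-scoring option is provided but makes the
  effect scale-dependent. A one-sample two-tailed t-test across subjects
  gives the group result.

## Problem sizes and numerical choices

The phantom validation runs at 32×32×12 voxels (3.4×3.4×5 mm) with three
scans of 180 volumes per session — the full protocol — in well under a
minute. Unit tests use reduced grids (8–16 voxels per axis) and shorter
series; the Monte-Carlo calibrations use 200 repetitions (GLM bias), 100
repetitions (family-wise error), and 10 cohort seeds (group-test null),
sizes at which the binomial slack of each assertion is explicit in the
test. Tolerances: wrap congruence 10⁻¹⁰ rad; noise-free round trips 10⁻⁶
nT/mA; offset/trend invariance 10⁻¹⁰ nT/mA.

Tie-breaks and degenerate inputs: region growth breaks quality ties by
insertion order (deterministic); disconnected mask components are each
grown from their own seed; singleton axes contribute zero gradient; voxels
with zero mean magnitude are excluded from percent scaling; Model 2's
removable singularity at φ = 0 returns exactly 0 via the sinc form.

## Known limitations

* Only Bz is measured/modelled; reconstructing the full current density
  would require all three field components (multi-orientation acquisition)
  or model fitting, neither implemented here.
* Axis-aligned NIfTI affines only; oblique acquisitions are rejected
  explicitly.
* OLS without prewhitening understates standard errors under temporal
  autocorrelation; slopes remain unbiased.
* Bonferroni FWE is conservative relative to random-field methods.
* The synthetic cohort's "component map" for the group test is the known
  injection region; real analyses obtain component maps from group ICA,
  which is out of scope (maps are accepted as inputs).
* The 1-SE parameter-recovery check compares against the realized mean of
  the jittered per-subject effects; against the population value the
  1-SE interval would have only ~68% coverage by construction.
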