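# Methods

This note records the models implemented in `ukftract`, the defaults and
why they were chosen, what the synthetic phantom does and does not emulate,
and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Signal models

All tracking operates on normalized signals Sᵢ/S₀.  Tissue compartments are
cylindrical tensors — principal direction **m**, eigenvalues λ₁ ≥ λ₂ = λ₃ —
so the apparent diffusivity along gradient **g** is
λ₂ + (λ₁−λ₂)(**g**·**m**)².  The model hierarchy is strictly nested:
a free-water fraction ω = 0 reduces the free-water model to the plain
multi-tensor model, and a single tensor is the two-tensor model with both
tensors equal (or mixing fraction f ∈ {0, 1}).  The free-water diffusivity
is fixed at 3·10⁻³ mm²/s, an extracellular-fluid value; it is a constant of
the model, not a fitted parameter.

In the two-tensor models the tissue split f is fixed at 0.5 and is not part
of the filter state: the state is the 10-vector of the two tensors'
directions and eigenvalues (plus ω when free water is enabled, giving 11).
Eigenvalues are carried in units of 10⁻⁶ mm²/s (so white matter is
λ₁ ≈ 1100), which puts the process-noise rate q_L on its conventional
scale.

## Scalar measures

* FA (fractional anisotropy): normalized eigenvalue variance; for
  cylindrical tensors |λ₁−λ₂|/√(λ₁²+2λ₂²).  Degenerate all-zero input maps
  to 0.
* GA (generalized anisotropy): model-free normalized variance of the
  diffusion-weighted signals over directions,
  √(n/(n−1)·Σ(Sᵢ−S̄)²/ΣSᵢ²).  The enclosing square root is included so GA
  shares FA's [0, 1] scale, consistent with both measures being thresholded
  in the same 0.05–0.2 range; the rootless form is available
  (`ga_squared`).
* MD: trace/3.

## The unscented Kalman filter

Process model: identity dynamics with diagonal injected covariance Q —
direction components at rate `q_m` (default 0.001), eigenvalue components
at `q_l` (default 50, in (10⁻⁶ mm²/s)² per step), free-water fraction at
`q_w` (default 5·10⁻⁴).  Measurement noise R = `r_scale`·I over the
normalized signals, default `r_scale` = 0.02.  Sigma points are the
symmetric 2n+1 set with spread κ = 0.01 (points stay close to the mean,
where the constrained parametrization is well behaved); weights
w₀ = κ/(n+κ), wᵢ = 1/(2(n+κ)).

Numerical safeguards, applied every update: covariance symmetrization and
eigenvalue clipping to PSD (tolerance −10⁻¹⁰); Cholesky with a 10⁻⁸ jitter
fallback; a regularized solve if P_yy is singular.  Constraint repair on
the mean: directions renormalized (an exactly zero direction resets to the
x-axis), eigenvalues floored at 0.1·10⁻⁶ mm²/s and reordered to λ₁ ≥ λ₂,
ω clipped to [0, 1].  Within the measurement function the same clips are
applied to each sigma point without modifying the state.

### Step size and filter lag

The propagation step defaults to 0.1× the smallest voxel dimension (0.2 mm
on the phantom).  This is deliberately finer than the common 0.3×
heuristic: the filter needs several updates per voxel for its running
estimate to stay near the local stationary fit.  At 0.6 mm steps the state
visibly lags the signal where diffusivities rise into edema — λ₂ responds
before λ₁, so the tensor-1 FA transiently undershoots the local
least-squares value by roughly 0.04, and the single-tensor tracker stops
far earlier than its equilibrium behavior implies.  At 0.2 mm the state
tracks the per-voxel equilibrium (center FA ≈ 0.20 on the phantom), which
is the regime the threshold experiments are about.

### Seeding and initialization

Seeds are placed per seed-mask voxel (`seeds_per_voxel`, default 1),
jittered uniformly within the voxel by the run RNG.  Each seed state comes
from an independent log-linear least-squares tensor fit at the
trilinearly-interpolated signals: principal eigenvector, λ₂ set to the mean
of the two minor eigenvalues, both tensors equal for two-tensor models,
ω initialized at 0.05.  Both stopping thresholds also gate seeding, so
seeds in isotropic or low-signal voxels are rejected up front.  Fibers are
tracked in both directions from the seed and joined; fibers shorter than
`min_length_mm` (default 10 mm) are discarded.

### Two-tensor symmetry breaking and the swap rule

Starting from two exactly equal tensors, exchange-symmetric dynamics keep
the tensors equal forever on axially symmetric data — the symmetric
subspace is invariant, so the two compartments could never specialize.
Tensor 2 is therefore given a 4× eigenvalue process-noise rate (and
matching prior variance): it is the fast adaptor.  Entering simulated
edema, tensor 2 rounds out to absorb the isotropic signal while tensor 1
retains its orientation and higher anisotropy — the divergence the
two-tensor model is meant to provide.  For the edema-center mixture this
specialized solution (one oriented tensor, one round high-diffusivity
tensor) reproduces the data exactly, whereas the symmetric solution is only
approximate.

Tensor 1 — the tensor that is followed — is chosen per step as the tensor
whose direction is closer (absolute dot product) to the previous step.
When both are equally aligned (alignment difference ≤ 0.01, the degenerate
case of a single-orientation field) the more anisotropic tensor is
followed, with a 0.05 FA hysteresis margin so near-identical compartments
do not swap labels on noise.  Without the tie-break the filter follows the
round compartment out of the edema; with it, two-tensor tracking on
single-tensor data reproduces single-tensor trajectories to well under a
degree.

## Streamline baseline

The comparator fits the tensor field once (unweighted log-linear least
squares; voxels with non-positive signals are fit on clipped values and
flagged), then integrates the principal-eigenvector field with the midpoint
(RK2) method, interpolating directions trilinearly with per-sample sign
alignment.  The FA stopping criterion samples the precomputed FA map at the
nearest voxel ("voxel" mode, the classic rule in voxel-based streamline
implementations); trilinear FA-map and interpolated-tensor variants are
available.  The distinction matters on this phantom: the noise-free FA
minimum (0.2004) sits marginally above the 0.2 threshold, so stopping in
the edema is driven by per-voxel noise dips, and interpolating the
criterion averages 4–8 voxels, halving the dip variance — enough to let a
nontrivial fraction of fibers drift through a region the method should not
cross.

## The phantom

`PhantomSpec` defaults are the study conditions: 150 × 110 × 110 mm at
2 mm isotropic voxels (75 × 55 × 55 grid), fibers along the first axis,
λ = (1100, 450, 450)·10⁻⁶ mm²/s, d_fw = 3000·10⁻⁶ mm²/s, b = 1000 s/mm²,
81 hemisphere directions plus one baseline (S₀ = 1), SNR 15.

* ω profile: raised-cosine window over the central `edema_extent` of the
  long axis, default extent 1.0 — the free-water fraction varies along the
  entire axis, from 0 at the two ends to 0.65 at the middle.  The smooth
  full-axis ramp gives the FA profile a flat basin at its minimum rather
  than a single-voxel point minimum; a linear ramp and narrower extents are
  available.  The profile is evaluated on the first half-axis and mirrored
  so the ω map is exactly symmetric.
* Gradient scheme: deterministic electrostatic repulsion (Fibonacci
  initialization, fixed iteration count, antipodal energy), so the table
  regenerates identically without a fixture file.
* Noise: each signal, including the baseline, is replaced by
  |(S+N₁) + iN₂| with N₁, N₂ ~ N(0, (S/snr)²).  The per-signal σ rule means
  exact-zero signals stay zero; the phantom has no zero-signal voxels
  inside the mask.
* Masks: whole volume; the edematous core (ω > ω_max/2, the central ~50 %
  of the axis under the default profile); a 2-slice seed slab near one end;
  a 3-slice center slab; a 3-slice far-end target.

At the center the apparent (log-linear least-squares) tensor of the
noise-free mixture has eigenvalues ≈ (1912, 1367, 1367)·10⁻⁶ mm²/s —
FA 0.2004, MD 1548·10⁻⁶ mm²/s — matching the intended edema range; at the
ends FA is 0.5115.

What the phantom does *not* emulate: crossing fibers or any neuroanatomy,
T₁/T₂ contrast, eddy-current or motion artifacts, spatially correlated
noise, partial-volume boundaries with grey matter or CSF, or scanner
interpolation.  Passing phantom tests shows the estimator and the stopping
logic behave as designed on a controlled single-orientation field; it does
not certify performance on clinical data.

## Threshold behavior on the phantom

Two facts shape what the stopping thresholds can and cannot do here, and
the test suite computes both:

* The FA experiment is a knife edge by construction: the threshold (0.2)
  equals the phantom's minimum FA.  Streamline crossing is then decided by
  noise dips (zero crossings at the shipped settings), the single-tensor
  filter crosses only occasionally (its state FA hovers at the threshold
  through a ~40 mm basin), and the free-water filter crosses always
  (its tissue tensor keeps FA ≈ 0.5 while ω absorbs the edema signal).
  The single-tensor traversal fraction is a genuinely stochastic, small
  quantity — a few percent of seeds — and varies between phantom noise
  realizations.
* The GA thresholds 0.05–0.1 never fire on this phantom: GA of the noisy
  signals ranges from ≈ 0.19 at the ends to ≈ 0.15 at the center, far
  above the thresholds, for every model.  Bundles tracked at different
  `min_ga` values in that range are therefore identical, and the GA
  sensitivity reported for clinical data cannot be demonstrated on this
  phantom — a property of the stated phantom conditions, not of the
  implementation.  (The corresponding acceptance test asserts the strict
  length increase anyway and is expected to fail; the non-increasing part
  holds.)

## Evaluation conventions

Fiber points map to voxels by rounding the continuous index to the nearest
voxel center; fibers are point sequences, not tubes — adequate while the
step does not exceed the voxel size.  Coverage is the fraction of target
voxels containing at least one fiber point; traversal requires at least one
point in the edema mask and one in the far target.  Midline rejection drops
fibers with points beyond a configurable tolerance band on both sides of a
plane.  Fiber length is the summed point-to-point distance.

## Problem sizes used by the test suite

Unit tests run on small phantoms (30 × 8 × 8 to 40 × 12 × 12 grids, 15–21
gradient directions).  The end-to-end tests run the full-size phantom with
compact seed patches — 40 seeds for the method comparison, 16 for the
two-tensor runs — which reproduces the qualitative method ordering while
keeping a run in tens of seconds; the shipped experiment presets use the
same scale and are configurable upward.

## Known limitations

* Single b-shell data make the free-water fraction only weakly identified;
  ω trades off against the tissue eigenvalues, so the multi-compartment
  states converge more slowly and less completely than the plain
  single-tensor state (the noise-free recovery test therefore targets the
  identifiable single-tensor case).
* The filter fits in signal space while the baseline fits in log space;
  on mixture voxels the two apparent tensors differ slightly, and
  threshold-equality comparisons between methods inherit that difference.
* Tracking is sequential per seed; no parallel scheduling is provided
  beyond per-seed independence.
* Orientation handling assumes axis-aligned grids (world = origin +
  index·spacing); patient-grade orientation matrices are honored on NIfTI
  read only insofar as their column norms give spacings.
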