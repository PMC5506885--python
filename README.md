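# ukftract

Unscented-Kalman-filter (UKF) multi-tensor tractography through simulated
vasogenic edema, with the synthetic DWI phantom and evaluation machinery
needed to study it end to end — no patient data required.

## The problem

Peritumoral vasogenic edema raises the water content of white matter and
lowers its diffusion anisotropy while the axons themselves may remain
intact.  Conventional streamline tractography, which fits one diffusion
tensor per voxel independently and stops when fractional anisotropy (FA)
falls below a threshold, systematically terminates inside edema — precisely
the region that matters most for neurosurgical planning.  UKF tractography
instead estimates the diffusion model *during* tracking: the model state at
the previous step is the prior for the next one, so fibers can carry strong
orientation information into regions where an independent per-voxel fit
would be uninformative.

This package implements and compares, on a controlled synthetic testbed:

* **streamline** — independent log-linear least-squares tensor fit per
  voxel, Runge–Kutta order-2 integration along the principal eigenvector,
  FA stopping threshold;
* **1T / 2T UKF** — causal estimation of one or two cylindrical tensors
  (λ₂ = λ₃) along the fiber via an unscented Kalman filter;
* **+FW** — either UKF model augmented with an isotropic free-water
  compartment of fixed diffusivity d = 3·10⁻³ mm²/s.

## Models

Signal hierarchy for unit gradient direction **g** and b-factor b (s/mm²):

    S/S₀ = e^{−b gᵀDg}                                      (single tensor)
    S/S₀ = (1−f) e^{−b gᵀD₁g} + f e^{−b gᵀD₂g}              (two tensors)
    S/S₀ = (1−ω)[two-tensor term] + ω e^{−b d}              (+ free water)

The filter state is the concatenation of each tensor's principal direction
**m** and eigenvalues (λ₁, λ₂) — 5 components per tensor, 10 for the
two-tensor model — plus the free-water fraction ω when enabled.  At each
step the state update is

    x_s = x̄_{s|s−1} + K_s (y_s − ȳ_{s|s−1}),   K_s = P_xy P_yy⁻¹,

computed with a symmetric 2n+1 sigma-point unscented transform; the fiber
then advances along tensor 1's principal direction.  Stopping rules: FA of
tensor 1 below `min_fa`, generalized anisotropy (GA) of the local measured
signals below `min_ga`, mask exit, or a sharp turn.  The scalar measures:

    FA = |λ₁−λ₂| / √(λ₁²+2λ₂²)          (cylindrical form)
    GA = √( n/(n−1) · Σᵢ(Sᵢ−S̄)² / ΣᵢSᵢ² )
    MD = (λ₁+λ₂+λ₃)/3

## The phantom

A 150 × 110 × 110 mm box of parallel fibers at 2 mm isotropic resolution.
Each voxel mixes one cylindrical white-matter tensor
(λ₁ = 1100·10⁻⁶, λ₂ = λ₃ = 450·10⁻⁶ mm²/s, oriented along the long axis)
with an isotropic free-water compartment (d = 3000·10⁻⁶ mm²/s):

    Sᵢ/S₀ = (1−ω) e^{−b uᵢᵀ D_wm uᵢ} + ω e^{−b d}

with ω ramping smoothly from 0 at the two ends to 0.65 at the axial middle.
Signals are sampled on 81 electrostatically spread hemisphere directions at
b = 1000 s/mm² plus one baseline, and Rician noise is applied with
per-signal σ = Sᵢ/15 (SNR ≈ 15).  At the center the apparent single-tensor
fit bottoms out at FA ≈ 0.2 with MD ≈ 1.55·10⁻³ mm²/s — the range of
peritumoral edema.

## Worked example

```python
import ukftract as u
from ukftract.experiments import thin_mask

data = u.build_phantom(u.PhantomSpec(rng_seed=0))
maps = u.scalar_maps(data.dwi_clean, data.masks["phantom"])
print(f"noise-free FA minimum: {maps['FA'].min():.4f}")
print(f"noise-free MD maximum: {maps['MD'].max()*1e6:.0f} x 1e-6 mm^2/s")

seeds = thin_mask(data.masks["end_seed"], 12)   # a patch at one end
for model in ("1T", "1T+FW"):
    cfg = u.UKFConfig(model=model, min_fa=0.2, min_ga=0.1, rng_seed=0)
    bundle = u.track(data.dwi, seeds, cfg, data.masks["phantom"])
    frac, _ = u.traversal_fraction(bundle, data.masks["edema"],
                                   data.masks["far_target"])
    stats = u.length_stats(bundle)
    print(f"{model:6s} {len(bundle):2d} fibers, "
          f"edema traversal {frac:.2f}, mean length {stats['mean_mm']:.1f} mm")
```

prints

```
noise-free FA minimum: 0.2004
noise-free MD maximum: 1548 x 1e-6 mm^2/s
1T     12 fibers, edema traversal 0.17, mean length 85.8 mm
1T+FW  12 fibers, edema traversal 1.00, mean length 149.8 mm
```

With the FA stopping threshold set to the phantom's own minimum (0.2), the
plain single-tensor filter stalls inside the edema for most seeds (17 % of
fibers reach the far end; mean length 86 mm of a possible 150 mm), while
the free-water-augmented filter assigns the isotropic signal to ω and
carries every fiber through.  The streamline baseline
(`ukftract.streamline_track`) crosses in neither case.

## Command line

```sh
ukftract phantom build --out phantom/ --seed 0
ukftract fit maps --dwi phantom/dwi.nrrd --mask phantom/mask_phantom.nrrd --out maps/
ukftract ukf track --dwi phantom/dwi.nrrd --seeds phantom/mask_end_seed.nrrd \
    --model 2T+FW --min-fa 0.15 --min-ga 0.1 --qL 50 --out tracts.trk
ukftract eval traversal --tracts tracts.trk \
    --edema phantom/mask_edema.nrrd --far phantom/mask_far_target.nrrd
ukftract experiment run --preset fig3 --out runs/fig3
```

DWI volumes are read and written as NRRD with `DWMRI_gradient_NNNN`
key/value metadata (NIfTI + FSL-style bval/bvec also supported); bundles as
TrackVis TRK with per-point FA₁/FA₂/GA/ω scalars, or legacy ASCII VTK.

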