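"""Synthetic edema DWI phantom.

A box of parallel fibers (default 150 x 110 x 110 mm at 2 mm isotropic
resolution) whose per-voxel signal mixes one cylindrical white-matter tensor
(lambda1 = 1100e-6, lambda2 = lambda3 = 450e-6 mm^2/s, principal direction
along the long axis) with an isotropic free-water compartment
(d = 3000e-6 mm^2/s):

    S_i / S0 = (1 - w) exp(-b u_i^T D_wm u_i) + w exp(-b d_fw)

The free-water fraction w ramps from 0 at both ends of the long axis to
0.65 at the axial midpoint, emulating vasogenic edema: anisotropy falls to a
minimum apparent FA of ~0.2 and mean diffusivity rises to ~1.55e-3 mm^2/s at
the center.  Signals are sampled on 81 gradient directions uniformly spread
over one hemisphere at b = 1000 s/mm^2 plus one b=0 baseline, and Rician
noise is applied at SNR ~ 15 (per-signal sigma = S_i / 15).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import DWIVolume
from .models import D_FREE_WATER


@dataclass
class PhantomSpec:
    """All parameters of the synthetic edema phantom."""

    dims_mm: tuple[float, float, float] = (150.0, 110.0, 110.0)
    voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    b_value: float = 1000.0
    n_gradients: int = 81
    lambda1: float = 1100e-6
    lambda23: float = 450e-6
    d_fw: float = D_FREE_WATER
    omega_max: float = 0.65
    #: "cosine" (raised-cosine window, default) or "linear" ramp.
    omega_shape: str = "cosine"
    #: Fraction of the long axis occupied by the edema ramp, centered.
    #: The default 1.0 ramps over the whole axis: the free-water fraction
    #: varies along the entire long axis, from 0 at the two ends to its
    #: maximum in the middle.
    edema_extent: float = 1.0
    fiber_axis: int = 0
    snr: float = 15.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega_max < 1.0:
            raise ValueError("omega_max must lie in [0, 1)")
        if not (self.lambda1 >= self.lambda23 > 0):
            raise ValueError("need lambda1 >= lambda23 > 0")
        if self.d_fw <= 0 or self.snr <= 0 or self.b_value < 0:
            raise ValueError("d_fw, snr must be positive; b_value non-negative")
        if not 0.0 < self.edema_extent <= 1.0:
            raise ValueError("edema_extent must lie in (0, 1]")
        if self.omega_shape not in ("cosine", "linear"):
            raise ValueError("omega_shape must be 'cosine' or 'linear'")
        if any(d <= 0 for d in self.dims_mm) or any(v <= 0 for v in self.voxel_mm):
            raise ValueError("dimensions and voxel size must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(round(d / v)) for d, v in zip(self.dims_mm, self.voxel_mm))

    @property
    def truth_direction(self) -> np.ndarray:
        e = np.zeros(3)
        e[self.fiber_axis] = 1.0
        return e


@dataclass
class PhantomDataset:
    """Generated phantom: noisy + clean DWI, ground truth and masks."""

    dwi: DWIVolume
    dwi_clean: DWIVolume
    omega_map: np.ndarray
    truth_direction: np.ndarray
    masks: dict[str, np.ndarray]
    spec: PhantomSpec


# --------------------------------------------------------------------------
# Gradient scheme
# --------------------------------------------------------------------------

def hemisphere_directions(n: int, iterations: int = 300) -> np.ndarray:
    """`n` unit vectors uniformly spread on the upper hemisphere.

    Deterministic: Fibonacci-lattice initialization followed by a fixed number
    of antipodally symmetric electrostatic-repulsion steps (each point repels
    every other point and its antipode), then reflection into z >= 0.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    p = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    for _ in range(iterations):
        diff = p[:, None, :] - p[None, :, :]
        summ = p[:, None, :] + p[None, :, :]
        dn = np.linalg.norm(diff, axis=-1)
        sn = np.linalg.norm(summ, axis=-1)
        np.fill_diagonal(dn, np.inf)
        sn = np.where(sn < 1e-9, np.inf, sn)
        force = (diff / dn[..., None]**3).sum(axis=1) \
            + (summ / sn[..., None]**3).sum(axis=1)
        force -= (force * p).sum(axis=1, keepdims=True) * p  # tangential part
        p = p + 1e-3 * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    p[p[:, 2] < 0] *= -1.0
    return p


# --------------------------------------------------------------------------
# Signal model
# --------------------------------------------------------------------------

def omega_profile(axial_position, spec: PhantomSpec):
    """Free-water fraction at normalized axial position t in [0, 1].

    Zero at both ends, `omega_max` at t = 0.5, symmetric about the midpoint
    and monotone on each half.  The ramp occupies the central `edema_extent`
    of the axis; outside it the profile is exactly 0.
    """
    t = np.asarray(axial_position, dtype=np.float64)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("axial position must lie in [0, 1]")
    u = np.abs(t - 0.5) / (spec.edema_extent / 2.0)   # 0 center -> 1 ramp edge
    if spec.omega_shape == "linear":
        w = spec.omega_max * np.clip(1.0 - u, 0.0, 1.0)
    else:
        w = spec.omega_max * np.where(u < 1.0, np.cos(np.pi * u / 2.0)**2, 0.0)
    return w[()]


def simulate_signal(omega, directions: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Noise-free S_i/S0 for free-water fraction(s) `omega` along `directions`.

    `omega` may be scalar or any array; the result broadcasts to
    ``omega.shape + (n_directions,)``.
    """
    omega = np.asarray(omega, dtype=np.float64)
    if np.any((omega < 0) | (omega >= 1)):
        raise ValueError("omega must lie in [0, 1)")
    directions = np.asarray(directions, dtype=np.float64)
    if np.any(np.abs(np.linalg.norm(directions, axis=-1) - 1.0) > 1e-6):
        raise ValueError("gradient directions must be unit vectors")
    proj = directions @ spec.truth_direction
    adc = spec.lambda23 + (spec.lambda1 - spec.lambda23) * proj**2
    tissue = np.exp(-spec.b_value * adc)
    fw = np.exp(-spec.b_value * spec.d_fw)
    return (1.0 - omega[..., None]) * tissue + omega[..., None] * fw


def add_rician_noise(signal, snr: float, rng: np.random.Generator):
    """Rician-perturbed copy of `signal` with per-sample sigma = S / snr.

    The noisy value is |(S + N1) + i N2| with N1, N2 ~ N(0, sigma^2).
    Where S = 0 the printed rule gives sigma = 0 and the output stays 0.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    s = np.asarray(signal, dtype=np.float64)
    if np.any(s < 0):
        raise ValueError("signals must be non-negative")
    sigma = s / snr
    real = s + sigma * rng.standard_normal(s.shape)
    imag = sigma * rng.standard_normal(s.shape)
    return np.hypot(real, imag)[()]


# --------------------------------------------------------------------------
# Phantom assembly
# --------------------------------------------------------------------------

def build_phantom(spec: PhantomSpec | None = None) -> PhantomDataset:
    """Generate the phantom dataset: noisy/clean DWI, omega map and masks.

    Masks (all on the phantom grid):

    * ``phantom`` — the whole volume;
    * ``edema`` — the edematous core, voxels with omega > omega_max / 2;
    * ``end_seed`` — a 2-slice slab near one end of the fiber axis (omega
      negligible);
    * ``center_seed`` — a 3-slice slab at the axial midpoint (omega maximal);
    * ``far_target`` — a 3-slice slab at the far end.
    """
    spec = spec or PhantomSpec()
    shape = spec.grid_shape
    axis = spec.fiber_axis
    n_axis = shape[axis]

    directions = hemisphere_directions(spec.n_gradients)
    # evaluate the profile on the first half-axis and mirror it, so the
    # omega map is exactly symmetric about the midplane
    half = (n_axis + 1) // 2
    t_half = (np.arange(half) + 0.5) / n_axis       # voxel-center positions
    w_half = np.atleast_1d(omega_profile(t_half, spec))
    omega_axis = np.concatenate([w_half, w_half[:n_axis - half][::-1]])
    signals_axis = simulate_signal(omega_axis, directions, spec)  # (n_axis, G)

    # broadcast the per-slab signals over the full grid
    nvol = spec.n_gradients + 1
    data = np.empty(shape + (nvol,), dtype=np.float64)
    data[..., 0] = 1.0                               # S0 baseline
    bshape = [1, 1, 1, spec.n_gradients]
    bshape[axis] = n_axis
    data[..., 1:] = signals_axis.reshape(bshape)

    oshape = [1, 1, 1]
    oshape[axis] = n_axis
    omega_map = np.broadcast_to(omega_axis.reshape(oshape), shape).copy()

    gradients = np.vstack([np.zeros(3), directions])
    bvalues = np.concatenate([[0.0], np.full(spec.n_gradients, spec.b_value)])
    spacing = np.asarray(spec.voxel_mm, dtype=float)
    origin = np.zeros(3)

    clean = DWIVolume(data, gradients, bvalues, spacing, origin)
    rng = np.random.default_rng(spec.rng_seed)
    noisy = DWIVolume(add_rician_noise(data, spec.snr, rng),
                      gradients.copy(), bvalues.copy(), spacing.copy(),
                      origin.copy())

    masks = _build_masks(shape, axis, omega_map, spec.omega_max)
    return PhantomDataset(dwi=noisy, dwi_clean=clean, omega_map=omega_map,
                          truth_direction=spec.truth_direction, masks=masks,
                          spec=spec)


def _build_masks(shape, axis, omega_map, omega_max) -> dict[str, np.ndarray]:
    n_axis = shape[axis]
    idx = np.arange(n_axis)

    def slab(sel):
        m = np.zeros(shape, dtype=bool)
        key = [slice(None)] * 3
        key[axis] = sel
        m[tuple(key)] = True
        return m

    center = (n_axis - 1) / 2.0
    masks = {
        "phantom": np.ones(shape, dtype=bool),
        "edema": omega_map > 0.5 * omega_max if omega_max > 0
        else np.zeros(shape, dtype=bool),
        "end_seed": slab(slice(1, 3)),
        "center_seed": slab(np.abs(idx - center) <= 1.0),
        "far_target": slab(slice(n_axis - 3, n_axis)),
    }
    return masks


def spec_to_dict(spec: PhantomSpec) -> dict:
    return asdict(spec)


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    for key in ("dims_mm", "voxel_mm"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomSpec(**d)
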