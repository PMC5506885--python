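"""Baseline single-tensor streamline tractography.

The comparison method: a single tensor is fit independently at every voxel
(log-linear least squares, :mod:`ukftract.fitting`), and fibers follow the
principal-eigenvector field with second-order Runge-Kutta (midpoint)
integration.  Tracking stops when the trilinearly interpolated FA falls below
a threshold, the fiber leaves the mask or volume, or the direction turns more
sharply than ``max_angle_deg`` in one step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import TensorField, fit_tensor_volume
from .io import DWIVolume, Fiber, TractSet
from .models import LAMBDA_FLOOR, fa_full

#: Eigenvalue gap (relative to lambda1) below which a voxel's principal
#: direction is considered unreliable.
DEGENERATE_REL_GAP = 1e-3


def principal_direction_field(field: TensorField):
    """Unit principal eigenvector per voxel (sign arbitrary) + reliability mask.

    Voxels where the two largest eigenvalues nearly coincide (isotropic
    degenerate) are flagged unreliable.
    """
    evals, evecs = field.eigensystem()
    directions = evecs[..., :, 2]                  # largest eigenvalue
    lam1 = np.maximum(evals[..., 2], LAMBDA_FLOOR)
    reliable = field.mask & ((evals[..., 2] - evals[..., 1]) / lam1
                             > DEGENERATE_REL_GAP)
    directions = np.where(field.mask[..., None], directions, 0.0)
    return directions, reliable


def fa_map_of(field: TensorField) -> np.ndarray:
    evals, _ = field.eigensystem()
    evals = np.maximum(evals, LAMBDA_FLOOR)
    fa = fa_full(evals[..., 0], evals[..., 1], evals[..., 2])
    return np.where(field.mask, fa, 0.0)


class _Trilinear:
    """Trilinear scalar-field interpolation on the voxel-center grid."""

    def __init__(self, values: np.ndarray, spacing, origin):
        self.values = np.ascontiguousarray(values, dtype=np.float64)
        self.spacing = np.asarray(spacing, dtype=float)
        self.origin = np.asarray(origin, dtype=float)
        self.shape = np.array(values.shape[:3])

    def weights_at(self, point):
        ci = (point - self.origin) / self.spacing
        if np.any(ci < -0.5) or np.any(ci > self.shape - 0.5):
            return None
        ci = np.clip(ci, 0.0, self.shape - 1.0)
        i0 = np.minimum(ci.astype(np.intp), self.shape - 2)
        f = ci - i0
        wx = np.array([1 - f[0], f[0]])
        wy = np.array([1 - f[1], f[1]])
        wz = np.array([1 - f[2], f[2]])
        w = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
        return i0, w

    def __call__(self, point) -> float | None:
        iw = self.weights_at(point)
        if iw is None:
            return None
        (x, y, z), w = iw
        return float((w * self.values[x:x + 2, y:y + 2, z:z + 2]).sum())


class _NearestScalar:
    """Scalar field sampled at the nearest voxel center.

    Classic voxel-based streamline implementations evaluate threshold
    criteria against the voxel's own map value; interpolating the criterion
    smooths over per-voxel noise and systematically weakens stopping rules
    in regions that hover at the threshold.
    """

    def __init__(self, values: np.ndarray, spacing, origin):
        self.values = np.asarray(values, dtype=np.float64)
        self.spacing = np.asarray(spacing, dtype=float)
        self.origin = np.asarray(origin, dtype=float)
        self.shape = np.array(values.shape[:3])

    def __call__(self, point) -> float | None:
        ci = (point - self.origin) / self.spacing
        vox = np.floor(ci + 0.5).astype(np.intp)
        if np.any(vox < 0) or np.any(vox >= self.shape):
            return None
        return float(self.values[tuple(vox)])


class _TensorFA(_Trilinear):
    """FA evaluated on the trilinearly interpolated tensor field.

    Interpolating the six tensor components and taking the FA of the result
    (rather than interpolating a precomputed FA map) is how voxel-based
    streamline implementations typically evaluate stopping criteria at
    sub-voxel points; averaging neighboring noisy tensors lowers anisotropy
    slightly, so this form is the more conservative stopping rule.
    """

    def __call__(self, point) -> float | None:
        iw = self.weights_at(point)
        if iw is None:
            return None
        (x, y, z), w = iw
        d6 = np.einsum("xyz,xyzc->c", w, self.values[x:x + 2, y:y + 2, z:z + 2])
        from .fitting import _d6_to_matrix
        evals = np.maximum(np.linalg.eigvalsh(_d6_to_matrix(d6)), LAMBDA_FLOOR)
        return float(fa_full(evals[0], evals[1], evals[2]))


class _DirectionInterp(_Trilinear):
    """Sign-coherent trilinear interpolation of a (+/-)-ambiguous vector field."""

    def direction(self, point, reference) -> np.ndarray | None:
        iw = self.weights_at(point)
        if iw is None:
            return None
        (x, y, z), w = iw
        block = self.values[x:x + 2, y:y + 2, z:z + 2]   # (2,2,2,3)
        signs = np.sign(block @ reference)
        signs[signs == 0] = 1.0
        vec = np.einsum("xyz,xyz,xyzc->c", w, signs, block)
        n = np.linalg.norm(vec)
        return vec / n if n > 1e-12 else None


def rk2_step(dirfield: _DirectionInterp, point: np.ndarray,
             prev_dir: np.ndarray, step_mm: float):
    """Midpoint (RK2) step through the direction field.

    Returns (next_point, step_direction) or None if a sample falls outside
    the field.  Sampled directions are sign-aligned with ``prev_dir``.
    """
    d1 = dirfield.direction(point, prev_dir)
    if d1 is None:
        return None
    d2 = dirfield.direction(point + 0.5 * step_mm * d1, prev_dir)
    if d2 is None:
        return None
    return point + step_mm * d2, d2


def streamline_track(dwi: DWIVolume, seed_mask: np.ndarray,
                     fa_threshold: float = 0.2,
                     step_mm: float | None = None,
                     max_angle_deg: float = 45.0,
                     max_steps: int = 2000,
                     seeds_per_voxel: int = 1,
                     min_length_mm: float = 10.0,
                     mask: np.ndarray | None = None,
                     rng_seed: int = 0,
                     fa_sampling: str = "voxel") -> TractSet:
    """Streamline tracking over the whole seed mask.

    The tensor field is fit once on the tracking mask.  The FA stopping rule
    samples the precomputed FA map at the nearest voxel
    (``fa_sampling="voxel"``, default — the classic voxel-based stopping
    rule), or evaluates sub-voxel FA on the trilinearly interpolated tensor
    (``"tensor"``) or on a trilinearly interpolated FA map (``"map"``).
    Seeds failing the FA start threshold are rejected.
    """
    seed_mask = np.asarray(seed_mask, bool)
    mask = np.ones(dwi.shape3, dtype=bool) if mask is None \
        else np.asarray(mask, bool)
    step = step_mm if step_mm is not None else 0.1 * float(np.min(dwi.spacing))
    cos_limit = np.cos(np.deg2rad(max_angle_deg))

    if fa_sampling not in ("voxel", "tensor", "map"):
        raise ValueError("fa_sampling must be 'voxel', 'tensor' or 'map'")
    field = fit_tensor_volume(dwi, mask)
    directions, _ = principal_direction_field(field)
    if fa_sampling == "tensor":
        fa_interp = _TensorFA(field.d6, dwi.spacing, dwi.origin)
    elif fa_sampling == "map":
        fa_interp = _Trilinear(fa_map_of(field), dwi.spacing, dwi.origin)
    else:
        fa_interp = _NearestScalar(fa_map_of(field), dwi.spacing, dwi.origin)
    dir_interp = _DirectionInterp(directions, dwi.spacing, dwi.origin)

    rng = np.random.default_rng(rng_seed)
    fibers = []
    counts = {"seeds": 0, "rejected": 0, "short": 0}
    for vox in np.argwhere(seed_mask):
        for _ in range(seeds_per_voxel):
            jitter = rng.uniform(-0.5, 0.5, size=3)
            seed = dwi.index_to_world(vox + jitter)
            counts["seeds"] += 1
            fiber = _track_one(seed, dwi, mask, fa_interp, dir_interp,
                               fa_threshold, step, cos_limit, max_steps)
            if fiber is None:
                counts["rejected"] += 1
            elif fiber.length_mm() < min_length_mm:
                counts["short"] += 1
            else:
                fibers.append(fiber)
    return TractSet(fibers=fibers, spacing=dwi.spacing.copy(),
                    origin=dwi.origin.copy(), shape=dwi.shape3, step_mm=step,
                    meta={"method": "streamline", "fa_threshold": fa_threshold,
                          "counts": counts})


def _track_one(seed, dwi, mask, fa_interp, dir_interp, fa_threshold, step,
               cos_limit, max_steps):
    fa0 = fa_interp(seed)
    if fa0 is None or fa0 < fa_threshold:
        return None
    d0 = dir_interp.direction(seed, np.array([1.0, 0.0, 0.0]))
    if d0 is None:
        return None

    halves = []
    for sign in (1.0, -1.0):
        pts = [seed.copy()]
        point = seed.copy()
        prev = sign * d0
        reason = "max-steps"
        for _ in range(max_steps):
            out = rk2_step(dir_interp, point, prev, step)
            if out is None:
                reason = "left-mask"
                break
            nxt, d = out
            vox = dwi.point_to_voxel(nxt)
            if np.any(vox < 0) or np.any(vox >= dwi.shape3) \
                    or not mask[tuple(vox)]:
                reason = "left-mask"
                break
            fa_here = fa_interp(nxt)
            if fa_here is None:
                reason = "left-mask"
                break
            if fa_here < fa_threshold:
                reason = "low-FA"
                break
            if float(d @ prev) < cos_limit:
                reason = "sharp-turn"
                break
            pts.append(nxt.copy())
            point, prev = nxt, d
        halves.append((pts, reason))

    fwd, bwd = halves
    points = np.asarray(list(reversed(bwd[0][1:])) + fwd[0])
    if len(points) < 2:
        return None
    return Fiber(points=points, reasons=(bwd[1], fwd[1]))
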