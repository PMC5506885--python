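"""Per-voxel single-tensor estimation by log-linear least squares.

This is the baseline estimator of the package: independent of tracking, it
inverts the single-tensor signal model S/S0 = exp(-b g^T D g) voxel by voxel
by solving the linear system

    -ln(S_i / S0) / b  =  g_i^T D g_i   (6 unknowns, one row per gradient)

in the least-squares sense.  It provides (a) the comparison method behind
streamline tractography, (b) the seed initializer of the Kalman-filter
tracker, and (c) whole-volume FA / MD / GA scalar maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DWIVolume
from .models import LAMBDA_FLOOR, fa_full, ga, md


class SingularFitError(ValueError):
    """The gradient design does not determine a tensor (rank < 6)."""


def design_matrix(gradients: np.ndarray) -> np.ndarray:
    """(G, 6) design rows [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz]."""
    g = np.asarray(gradients, dtype=np.float64)
    return np.column_stack([
        g[:, 0]**2, g[:, 1]**2, g[:, 2]**2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])


def _d6_to_matrix(d6: np.ndarray) -> np.ndarray:
    """(..., 6) packed tensor -> (..., 3, 3) symmetric matrix."""
    d6 = np.asarray(d6)
    out = np.empty(d6.shape[:-1] + (3, 3), dtype=np.float64)
    out[..., 0, 0] = d6[..., 0]
    out[..., 1, 1] = d6[..., 1]
    out[..., 2, 2] = d6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 5]
    return out


def fit_single_tensor(signals: np.ndarray, gradients: np.ndarray, b: float,
                      s0: float = 1.0) -> np.ndarray:
    """Least-squares single tensor from one voxel's signals.

    Non-positive signals (possible in user-supplied magnitude data) are
    excluded from the fit; if fewer than 6 usable directions remain, or the
    remaining design is rank deficient, :class:`SingularFitError` is raised.

    Returns the symmetric 3x3 tensor in mm^2/s (eigenvalues not clamped).
    """
    signals = np.asarray(signals, dtype=np.float64)
    gradients = np.asarray(gradients, dtype=np.float64)
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    usable = signals > 0
    if usable.sum() < 6:
        raise SingularFitError(
            f"only {int(usable.sum())} positive signals; need >= 6")
    design = design_matrix(gradients[usable])
    y = -np.log(signals[usable] / s0) / b
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 6:
        raise SingularFitError("gradient design is rank deficient")
    return _d6_to_matrix(coef)


@dataclass
class TensorField:
    """Voxel-wise single-tensor fits over a mask, with grid geometry."""

    d6: np.ndarray              # (X, Y, Z, 6) packed tensors; 0 off-mask
    mask: np.ndarray            # (X, Y, Z) bool: voxels with a valid fit
    flagged: np.ndarray         # (X, Y, Z) bool: voxels excluded/failed
    spacing: np.ndarray
    origin: np.ndarray

    def matrices(self) -> np.ndarray:
        return _d6_to_matrix(self.d6)

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending, (X,Y,Z,3)) and eigenvectors (X,Y,Z,3,3)."""
        evals, evecs = np.linalg.eigh(self.matrices())
        return evals, evecs


def fit_tensor_volume(dwi: DWIVolume, mask: np.ndarray | None = None) -> TensorField:
    """Vectorized log-linear LS fit over every mask voxel.

    Voxels with any non-positive weighted signal are fit on clipped signals
    and flagged rather than crashing the whole volume.
    """
    shape = dwi.shape3
    mask = np.ones(shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    norm = dwi.normalized()[mask]                    # (N, G)
    flagged_vox = (norm <= 0).any(axis=1)
    norm = np.maximum(norm, 1e-12)
    design = design_matrix(dwi.weighted_gradients)
    if np.linalg.matrix_rank(design) < 6:
        raise SingularFitError("gradient design is rank deficient")
    pinv = np.linalg.pinv(design)                    # (6, G)
    y = -np.log(norm) / dwi.b_weighted               # (N, G)
    coef = y @ pinv.T                                # (N, 6)

    d6 = np.zeros(shape + (6,), dtype=np.float64)
    d6[mask] = coef
    flagged = np.zeros(shape, dtype=bool)
    flagged[mask] = flagged_vox
    return TensorField(d6=d6, mask=mask & ~flagged, flagged=flagged,
                       spacing=dwi.spacing.copy(), origin=dwi.origin.copy())


def scalar_maps(dwi: DWIVolume, mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """FA, MD (from the tensor fit) and GA (from raw signals) volumes.

    Background (off-mask) voxels are 0.  Negative fitted eigenvalues are
    clamped to a small positive floor before FA/MD, since noise can produce
    non-physical fits.
    """
    shape = dwi.shape3
    mask = np.ones(shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    field = fit_tensor_volume(dwi, mask)
    evals, _ = np.linalg.eigh(_d6_to_matrix(field.d6[mask]))
    evals = np.maximum(evals, LAMBDA_FLOOR)

    fa_map = np.zeros(shape)
    md_map = np.zeros(shape)
    ga_map = np.zeros(shape)
    fa_map[mask] = fa_full(evals[:, 0], evals[:, 1], evals[:, 2])
    md_map[mask] = md(evals[:, 0], evals[:, 1], evals[:, 2])
    ga_map[mask] = ga(dwi.normalized()[mask])
    return {"FA": fa_map, "MD": md_map, "GA": ga_map,
            "flagged": field.flagged}
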