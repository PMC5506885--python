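"""Multi-tensor diffusion signal models and scalar anisotropy measures.

The signal hierarchy, for unit gradient direction g and b-factor b (s/mm^2):

* single tensor:      S/S0 = exp(-b g^T D g)
* two tensors:        S/S0 = (1-f) exp(-b g^T D1 g) + f exp(-b g^T D2 g)
* plus free water:    S/S0 = (1-w)[two-tensor term] + w exp(-b d_fw)

with d_fw fixed at 0.003 mm^2/s (isotropic extracellular fluid).  Each tissue
tensor is cylindrical: the two minor eigenvalues are constrained equal, so a
tensor is (m, lambda1, lambda2) with unit principal direction m and
g^T D g = lambda2 + (lambda1 - lambda2)(g . m)^2.

Scalar measures:

* FA — fractional anisotropy, the normalized eigenvalue variance
  sqrt(1/2) * sqrt((l1-l2)^2+(l1-l3)^2+(l2-l3)^2) / sqrt(l1^2+l2^2+l3^2);
* MD — mean diffusivity, (l1+l2+l3)/3;
* GA — generalized anisotropy, a model-free normalized variance of the
  diffusion-weighted signals over gradient directions:
  GA = sqrt( n/(n-1) * sum_i (S_i - mean S)^2 / sum_i S_i^2 ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Diffusivity of the isotropic free-water compartment, mm^2/s.
D_FREE_WATER = 3000e-6

#: Floor applied to eigenvalues before anisotropy formulas, mm^2/s.
LAMBDA_FLOOR = 1e-7


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


@dataclass
class CylindricalTensor:
    """Axially symmetric diffusion tensor: (direction, lambda1, lambda2=lambda3)."""

    direction: np.ndarray
    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        self.direction = _unit(self.direction)
        self.lambda1 = max(float(self.lambda1), LAMBDA_FLOOR)
        self.lambda2 = max(float(self.lambda2), LAMBDA_FLOOR)
        if self.lambda1 < self.lambda2:
            self.lambda1, self.lambda2 = self.lambda2, self.lambda1

    def adc(self, gradients: np.ndarray) -> np.ndarray:
        """Apparent diffusivity g^T D g along each row of `gradients`."""
        proj = np.asarray(gradients, dtype=np.float64) @ self.direction
        return self.lambda2 + (self.lambda1 - self.lambda2) * proj**2

    def matrix(self) -> np.ndarray:
        m = self.direction
        return self.lambda2 * np.eye(3) + (self.lambda1 - self.lambda2) * np.outer(m, m)

    @property
    def fa(self) -> float:
        return fa_cylindrical(self.lambda1, self.lambda2)


@dataclass
class MultiTensorModel:
    """One or two cylindrical tensors, optionally with a free-water fraction.

    ``f`` splits the tissue signal between the two tensors (ignored with one
    tensor); ``omega_fw`` is the free-water volume fraction, ``None`` when the
    free-water compartment is disabled.
    """

    tensors: tuple[CylindricalTensor, ...]
    f: float = 0.5
    omega_fw: float | None = None
    d_fw: float = D_FREE_WATER

    def __post_init__(self) -> None:
        if not 1 <= len(self.tensors) <= 2:
            raise ValueError("model supports one or two tensors")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("tensor fraction f must lie in [0, 1]")
        if self.omega_fw is not None and not 0.0 <= self.omega_fw <= 1.0:
            raise ValueError("free-water fraction must lie in [0, 1]")


def predict_signal(model: MultiTensorModel, gradients: np.ndarray,
                   b: float) -> np.ndarray:
    """Normalized signal S/S0 of `model` along each gradient direction."""
    gradients = np.asarray(gradients, dtype=np.float64)
    if len(model.tensors) == 1:
        tissue = np.exp(-b * model.tensors[0].adc(gradients))
    else:
        t1, t2 = model.tensors
        tissue = ((1.0 - model.f) * np.exp(-b * t1.adc(gradients))
                  + model.f * np.exp(-b * t2.adc(gradients)))
    if model.omega_fw is None:
        return tissue
    w = model.omega_fw
    return (1.0 - w) * tissue + w * np.exp(-b * model.d_fw)


# --------------------------------------------------------------------------
# Scalar measures (all accept arrays and broadcast)
# --------------------------------------------------------------------------

def fa_cylindrical(lambda1, lambda2):
    """FA of a cylindrical tensor: |l1 - l2| / sqrt(l1^2 + 2 l2^2)."""
    l1 = np.maximum(np.asarray(lambda1, dtype=np.float64), LAMBDA_FLOOR)
    l2 = np.maximum(np.asarray(lambda2, dtype=np.float64), LAMBDA_FLOOR)
    return np.abs(l1 - l2) / np.sqrt(l1**2 + 2.0 * l2**2)


def fa_full(lambda1, lambda2, lambda3):
    """FA from three eigenvalues (degenerate all-zero input maps to 0)."""
    l = np.stack(np.broadcast_arrays(
        np.asarray(lambda1, dtype=np.float64),
        np.asarray(lambda2, dtype=np.float64),
        np.asarray(lambda3, dtype=np.float64)), axis=-1)
    num = ((l[..., 0] - l[..., 1])**2 + (l[..., 0] - l[..., 2])**2
           + (l[..., 1] - l[..., 2])**2)
    den = (l**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(0.5 * num / den)
    return np.where(den > 0, out, 0.0)[()]


def md(lambda1, lambda2, lambda3):
    """Mean diffusivity: (l1 + l2 + l3) / 3."""
    return (np.asarray(lambda1, dtype=np.float64)
            + np.asarray(lambda2) + np.asarray(lambda3)) / 3.0


def ga(signals, squared: bool = False):
    """Generalized anisotropy of a signal vector over >= 2 gradient directions.

    Model-free normalized signal variance; 0 for constant signals, 1 for a
    one-hot vector.  ``squared=True`` returns the rootless form.
    """
    s = np.asarray(signals, dtype=np.float64)
    n = s.shape[-1]
    if n < 2:
        raise ValueError("GA needs at least two gradient directions")
    total = (s**2).sum(axis=-1)
    var = ((s - s.mean(axis=-1, keepdims=True))**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g2 = (n / (n - 1.0)) * var / total
    g2 = np.where(total > 0, g2, 0.0)
    return g2[()] if squared else np.sqrt(g2)[()]
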