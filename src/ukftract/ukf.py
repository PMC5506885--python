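"""Unscented-Kalman-filter tractography.

The tracker estimates a multi-tensor diffusion model *while* propagating a
fiber: at each step the previous state (model parameters and their
covariance) is the prior, the trilinearly interpolated diffusion signal at
the current point is the measurement, and the unscented transform pushes
sigma points through the signal model to obtain the Kalman update

    x_s = x_{s|s-1} + K_s (y_s - y_{s|s-1}),      K_s = P_xy P_yy^{-1}.

The fiber then advances a fixed step along the principal direction of the
first tensor, sign-aligned with the previous step.

State vectors (eigenvalues carried in 1e-6 mm^2/s units):

* ``1T``     — (m, l1, l2): 5 components;
* ``1T+FW``  — + free-water fraction w: 6;
* ``2T``     — two tensors: 10 (the tissue split f is fixed at 0.5 and is
  not estimated — the state has no room for it);
* ``2T+FW``  — 11.

Process noise Q is diagonal: eigenvalue entries at rate ``q_l`` (the knob
that controls how fast diffusivities may change along a fiber, and thereby
the Kalman gain), direction entries at ``q_m``, free-water entry at ``q_w``.
Measurement noise is R = ``r_scale`` * I over the normalized signals.

Stopping rules: FA of tensor one (from the state's eigenvalues) below
``min_fa``; generalized anisotropy of the local measured signals below
``min_ga``; leaving the tracking mask / volume; exceeding ``max_angle_deg``
per step; or ``max_steps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fitting import SingularFitError, fit_single_tensor
from .io import DWIVolume, Fiber, TractSet
from .models import fa_cylindrical, ga

#: Internal eigenvalue scale: state lambda of 1100 means 1100e-6 mm^2/s.
LAMBDA_UNIT = 1e-6

_MODELS = ("1T", "2T", "1T+FW", "2T+FW")


@dataclass
class UKFConfig:
    """Tracking parameters; defaults follow the method's standard settings."""

    model: str = "2T"
    min_fa: float = 0.15          # stopping threshold on tensor-1 FA
    min_ga: float = 0.1           # stopping threshold on measured GA
    q_l: float = 50.0             # eigenvalue system-noise rate
    q_m: float = 0.001            # direction system-noise rate
    q_w: float = 0.0005           # free-water-fraction system-noise rate
    r_scale: float = 0.02         # measurement noise level (variance)
    step_mm: float | None = None  # default: 0.1 x smallest voxel dimension
    seeds_per_voxel: int = 1
    max_steps: int = 2000
    max_angle_deg: float = 45.0
    min_length_mm: float = 10.0
    rng_seed: int = 0
    kappa: float = 0.01           # sigma-point spread
    ga_squared: bool = False      # use the rootless GA form
    lambda_floor: float = 0.1     # in 1e-6 mm^2/s units
    omega_init: float = 0.05
    #: diagonal prior variances at the seed
    p0_direction: float = 0.01
    p0_lambda: float = 100.0
    p0_omega: float = 0.01
    #: multiplier on tensor 2's eigenvalue process noise and prior variance.
    #: Starting from two equal tensors, exchange-symmetric dynamics preserve
    #: tensor equality exactly on symmetric data; giving the second
    #: compartment a faster eigenvalue adaptation rate breaks that symmetry
    #: so the tensors can specialize — one keeps the tract orientation while
    #: the other rounds out to absorb isotropic (edema) signal.
    tensor2_q_scale: float = 4.0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.min_fa < 0 or self.min_ga < 0:
            raise ValueError("stopping thresholds must be >= 0")
        if self.step_mm is not None and self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.seeds_per_voxel < 1 or self.max_steps < 1:
            raise ValueError("seeds_per_voxel and max_steps must be >= 1")

    @property
    def n_tensors(self) -> int:
        return 2 if self.model.startswith("2T") else 1

    @property
    def has_free_water(self) -> bool:
        return self.model.endswith("+FW")

    @property
    def state_dim(self) -> int:
        return 5 * self.n_tensors + (1 if self.has_free_water else 0)


@dataclass
class UKFState:
    """Model-parameter mean and covariance carried along a fiber."""

    mean: np.ndarray
    cov: np.ndarray

    def copy(self) -> "UKFState":
        return UKFState(self.mean.copy(), self.cov.copy())


# --------------------------------------------------------------------------
# Signal interpolation
# --------------------------------------------------------------------------

class SignalInterpolator:
    """Trilinear interpolation of normalized signals at world-mm points."""

    def __init__(self, dwi: DWIVolume):
        self.norm = np.ascontiguousarray(dwi.normalized())
        self.spacing = dwi.spacing
        self.origin = dwi.origin
        self.shape = np.array(dwi.shape3)

    def __call__(self, point: np.ndarray) -> np.ndarray | None:
        """Signal vector at `point`, or None outside the volume bounds.

        The volume extends half a voxel beyond the outermost voxel centers;
        inside that border the edge value is used (clamped interpolation).
        """
        ci = (point - self.origin) / self.spacing
        if np.any(ci < -0.5) or np.any(ci > self.shape - 0.5):
            return None
        ci = np.clip(ci, 0.0, self.shape - 1.0)
        i0 = np.minimum(ci.astype(np.intp), self.shape - 2)
        f = ci - i0
        x, y, z = i0
        fx, fy, fz = f
        block = self.norm[x:x + 2, y:y + 2, z:z + 2]     # (2,2,2,G)
        wx = np.array([1 - fx, fx])
        wy = np.array([1 - fy, fy])
        wz = np.array([1 - fz, fz])
        w = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
        return np.einsum("xyz,xyzg->g", w, block)


def interpolate_signal(dwi: DWIVolume, point) -> np.ndarray:
    """Per-gradient trilinear interpolation of S_i/S0 at a world-mm point."""
    out = SignalInterpolator(dwi)(np.asarray(point, dtype=np.float64))
    if out is None:
        raise ValueError(f"point {point} outside volume bounds")
    return out


# --------------------------------------------------------------------------
# The filter
# --------------------------------------------------------------------------

class UKFFilter:
    """Prepared unscented filter for one (gradient scheme, b, config)."""

    def __init__(self, config: UKFConfig, gradients: np.ndarray, b: float):
        self.config = config
        self.gradients = np.asarray(gradients, dtype=np.float64)
        self.b = float(b)
        d = config.state_dim
        self.dim = d
        kappa = config.kappa
        self.scale = np.sqrt(d + kappa)
        self.weights = np.full(2 * d + 1, 1.0 / (2.0 * (d + kappa)))
        self.weights[0] = kappa / (d + kappa)
        q = np.empty(d)
        for t in range(config.n_tensors):
            scale = config.tensor2_q_scale if t == 1 else 1.0
            q[5 * t:5 * t + 3] = config.q_m
            q[5 * t + 3:5 * t + 5] = config.q_l * scale
        if config.has_free_water:
            q[-1] = config.q_w
        self.Q = np.diag(q)
        self.R = config.r_scale * np.eye(self.gradients.shape[0])

    # -- state block access ------------------------------------------------

    def directions(self, x: np.ndarray) -> list[np.ndarray]:
        return [x[5 * t:5 * t + 3] for t in range(self.config.n_tensors)]

    def eigenvalues(self, x: np.ndarray) -> list[tuple[float, float]]:
        return [(x[5 * t + 3], x[5 * t + 4])
                for t in range(self.config.n_tensors)]

    def omega(self, x: np.ndarray) -> float | None:
        return float(x[-1]) if self.config.has_free_water else None

    def fa1(self, x: np.ndarray) -> float:
        l1, l2 = self.eigenvalues(x)[0]
        return float(fa_cylindrical(l1 * LAMBDA_UNIT, l2 * LAMBDA_UNIT))

    def fa2(self, x: np.ndarray) -> float:
        if self.config.n_tensors < 2:
            return 0.0
        l1, l2 = self.eigenvalues(x)[1]
        return float(fa_cylindrical(l1 * LAMBDA_UNIT, l2 * LAMBDA_UNIT))

    # -- measurement model ---------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Normalized signals for each state row of X: (k, d) -> (k, G)."""
        X = np.atleast_2d(X)
        cfg = self.config
        floor = cfg.lambda_floor
        tissue = 0.0
        frac = 1.0 / cfg.n_tensors
        for t in range(cfg.n_tensors):
            m = X[:, 5 * t:5 * t + 3]
            norm = np.linalg.norm(m, axis=1, keepdims=True)
            m = m / np.where(norm < 1e-12, 1.0, norm)
            l1 = np.maximum(X[:, 5 * t + 3], floor) * LAMBDA_UNIT
            l2 = np.maximum(X[:, 5 * t + 4], floor) * LAMBDA_UNIT
            proj2 = (m @ self.gradients.T)**2               # (k, G)
            adc = l2[:, None] + (l1 - l2)[:, None] * proj2
            tissue = tissue + frac * np.exp(-self.b * adc)
        if not cfg.has_free_water:
            return tissue
        w = np.clip(X[:, -1], 0.0, 1.0)[:, None]
        from .models import D_FREE_WATER
        return (1.0 - w) * tissue + w * np.exp(-self.b * D_FREE_WATER)

    # -- constraint repair ---------------------------------------------------

    def repair(self, x: np.ndarray) -> np.ndarray:
        cfg = self.config
        x = x.copy()
        for t in range(cfg.n_tensors):
            m = x[5 * t:5 * t + 3]
            n = np.linalg.norm(m)
            x[5 * t:5 * t + 3] = m / n if n > 1e-12 else np.array([1.0, 0, 0])
            l1 = max(x[5 * t + 3], cfg.lambda_floor)
            l2 = max(x[5 * t + 4], cfg.lambda_floor)
            if l1 < l2:
                l1, l2 = l2, l1
            x[5 * t + 3], x[5 * t + 4] = l1, l2
        if cfg.has_free_water:
            x[-1] = np.clip(x[-1], 0.0, 1.0)
        return x

    @staticmethod
    def _psd(cov: np.ndarray) -> np.ndarray:
        cov = 0.5 * (cov + cov.T)
        evals, evecs = np.linalg.eigh(cov)
        if evals[0] < -1e-10:
            evals = np.maximum(evals, 0.0)
            cov = (evecs * evals) @ evecs.T
            cov = 0.5 * (cov + cov.T)
        return cov

    # -- the update ----------------------------------------------------------

    def update(self, state: UKFState, measurement: np.ndarray):
        """One unscented Kalman update.  Returns (new_state, gain)."""
        d = self.dim
        p_pred = self._psd(state.cov + self.Q)
        try:
            chol = np.linalg.cholesky(p_pred)
        except np.linalg.LinAlgError:
            chol = np.linalg.cholesky(p_pred + 1e-8 * np.eye(d))
        offsets = self.scale * chol
        X = np.empty((2 * d + 1, d))
        X[0] = state.mean
        X[1:d + 1] = state.mean + offsets.T
        X[d + 1:] = state.mean - offsets.T

        Y = self.predict(X)
        w = self.weights
        ybar = w @ Y
        xd = X - state.mean          # sigma set is symmetric: mean is exact
        yd = Y - ybar
        p_yy = (yd.T * w) @ yd + self.R
        p_xy = (xd.T * w) @ yd
        try:
            gain = np.linalg.solve(p_yy, p_xy.T).T
        except np.linalg.LinAlgError:
            gain = np.linalg.solve(
                p_yy + 1e-10 * np.eye(p_yy.shape[0]), p_xy.T).T
        mean = state.mean + gain @ (measurement - ybar)
        cov = self._psd(p_pred - gain @ p_yy @ gain.T)
        return UKFState(self.repair(mean), cov), gain

    # -- tensor bookkeeping ----------------------------------------------------

    #: alignment difference below which the two tensors are considered
    #: equally aligned with the tracked direction
    ALIGN_TIE = 0.01
    #: FA margin required before the tie-break swaps tensors (hysteresis, so
    #: near-identical compartments on healthy tissue do not thrash labels)
    FA_TIE_MARGIN = 0.05

    def align(self, state: UKFState, prev_dir: np.ndarray,
              prev_dir2: np.ndarray | None) -> UKFState:
        """Swap tensors so tensor 1 is the compartment being tracked.

        Tensor 1 is the tensor whose direction is closer (by absolute dot
        product) to the previous step.  When both are equally aligned — the
        degenerate case of a single-orientation field, where the compartments
        differ only in shape — the more anisotropic (tract-like) tensor is
        followed.
        """
        x = state.mean.copy()
        cov = state.cov
        if self.config.n_tensors == 2:
            d1, d2 = self.directions(x)
            a1, a2 = abs(d1 @ prev_dir), abs(d2 @ prev_dir)
            tied = abs(a1 - a2) <= self.ALIGN_TIE
            swap = (a2 > a1 + self.ALIGN_TIE) or \
                (tied and self.fa2(x) > self.fa1(x) + self.FA_TIE_MARGIN)
            if swap:
                perm = np.arange(self.dim)
                perm[0:5], perm[5:10] = np.arange(5, 10), np.arange(0, 5)
                x = x[perm]
                cov = cov[np.ix_(perm, perm)]
            if x[0:3] @ prev_dir < 0:
                x[0:3] *= -1
            ref2 = prev_dir2 if prev_dir2 is not None else prev_dir
            if x[5:8] @ ref2 < 0:
                x[5:8] *= -1
        else:
            if x[0:3] @ prev_dir < 0:
                x[0:3] *= -1
        return UKFState(x, cov)


def ukf_step(state: UKFState, measurement: np.ndarray, config: UKFConfig,
             gradients: np.ndarray, b: float) -> UKFState:
    """Single filter update (convenience wrapper around :class:`UKFFilter`)."""
    new, _ = UKFFilter(config, gradients, b).update(state, np.asarray(measurement))
    return new


def kalman_gain(state: UKFState, measurement: np.ndarray, config: UKFConfig,
                gradients: np.ndarray, b: float) -> np.ndarray:
    """Kalman gain of one update on fixed state and measurement."""
    _, gain = UKFFilter(config, gradients, b).update(state, np.asarray(measurement))
    return gain


# --------------------------------------------------------------------------
# Seeding and tracking
# --------------------------------------------------------------------------

def init_seed_state(dwi: DWIVolume, point, config: UKFConfig,
                    interp: SignalInterpolator | None = None) -> UKFState:
    """Seed state from an independent LS tensor fit at `point`.

    The fitted tensor is cylindricalized (l2 := mean of the two minor
    eigenvalues); for two-tensor models both tensors start equal (with a
    broader prior on tensor 2, see :class:`UKFConfig`).
    """
    interp = interp or SignalInterpolator(dwi)
    point = np.asarray(point, dtype=np.float64)
    signals = interp(point)
    if signals is None:
        raise ValueError(f"seed point {point} outside volume")
    tensor = fit_single_tensor(signals, dwi.weighted_gradients, dwi.b_weighted)
    evals, evecs = np.linalg.eigh(tensor)
    direction = evecs[:, 2]
    l1 = max(evals[2] / LAMBDA_UNIT, config.lambda_floor)
    l2 = max(0.5 * (evals[0] + evals[1]) / LAMBDA_UNIT, config.lambda_floor)
    if l1 < l2:
        l1, l2 = l2, l1

    d = config.state_dim
    mean = np.empty(d)
    p0 = np.empty(d)
    for t in range(config.n_tensors):
        mean[5 * t:5 * t + 3] = direction
        mean[5 * t + 3:5 * t + 5] = (l1, l2)
        p0[5 * t:5 * t + 3] = config.p0_direction
        scale = config.tensor2_q_scale if t == 1 else 1.0
        p0[5 * t + 3:5 * t + 5] = config.p0_lambda * scale
    if config.has_free_water:
        mean[-1] = config.omega_init
        p0[-1] = config.p0_omega
    return UKFState(mean, np.diag(p0))


def _resolve_step(config: UKFConfig, spacing: np.ndarray) -> float:
    """Default step: 0.1 x the smallest voxel dimension.

    The filter needs several updates per voxel to keep its running model
    estimate close to the local stationary fit; with coarser steps the
    estimate lags the data, which systematically depresses the tensor-1 FA
    while diffusivities are rising into edema.
    """
    return config.step_mm if config.step_mm is not None \
        else 0.1 * float(np.min(spacing))


def track_from_seed(dwi: DWIVolume, seed_point, config: UKFConfig,
                    mask: np.ndarray | None = None,
                    interp: SignalInterpolator | None = None,
                    filt: UKFFilter | None = None) -> Fiber | None:
    """Track bidirectionally from one seed.  Returns None for rejected seeds.

    A seed is rejected when it lies outside the mask/volume, its LS fit is
    singular, or the start thresholds (min FA on the fitted tensor, min GA on
    the local signals) are not met.
    """
    mask = np.ones(dwi.shape3, dtype=bool) if mask is None \
        else np.asarray(mask, bool)
    interp = interp or SignalInterpolator(dwi)
    filt = filt or UKFFilter(config, dwi.weighted_gradients, dwi.b_weighted)
    seed_point = np.asarray(seed_point, dtype=np.float64)
    step = _resolve_step(config, dwi.spacing)
    cos_limit = np.cos(np.deg2rad(config.max_angle_deg))

    vox = dwi.point_to_voxel(seed_point)
    if np.any(vox < 0) or np.any(vox >= dwi.shape3) or not mask[tuple(vox)]:
        return None
    signals0 = interp(seed_point)
    if signals0 is None:
        return None
    try:
        state0 = init_seed_state(dwi, seed_point, config, interp)
    except (SingularFitError, ValueError):
        return None
    ga0 = float(ga(signals0, squared=config.ga_squared))
    if filt.fa1(state0.mean) < config.min_fa or ga0 < config.min_ga:
        return None

    halves = []
    for direction_sign in (1.0, -1.0):
        pts, fa1s, fa2s, gas, omegas = [], [], [], [], []
        state = state0.copy()
        prev = direction_sign * filt.directions(state.mean)[0].copy()
        prev2 = None
        point = seed_point.copy()
        reason = "max-steps"
        for _ in range(config.max_steps):
            vox = dwi.point_to_voxel(point)
            if np.any(vox < 0) or np.any(vox >= dwi.shape3) \
                    or not mask[tuple(vox)]:
                reason = "left-mask"
                break
            y = interp(point)
            if y is None:
                reason = "left-mask"
                break
            state, _ = filt.update(state, y)
            state = filt.align(state, prev, prev2)
            new_dir = filt.directions(state.mean)[0]
            fa1 = filt.fa1(state.mean)
            ga_val = float(ga(y, squared=config.ga_squared))

            pts.append(point.copy())
            fa1s.append(fa1)
            fa2s.append(filt.fa2(state.mean))
            gas.append(ga_val)
            w = filt.omega(state.mean)
            omegas.append(w if w is not None else 0.0)

            if fa1 < config.min_fa:
                reason = "low-FA"
                break
            if ga_val < config.min_ga:
                reason = "low-GA"
                break
            if float(new_dir @ prev) < cos_limit:
                reason = "sharp-turn"
                break
            point = point + step * new_dir
            prev = new_dir.copy()
            if config.n_tensors == 2:
                prev2 = filt.directions(state.mean)[1].copy()
        halves.append((pts, fa1s, fa2s, gas, omegas, reason))

    fwd, bwd = halves
    def cat(i):
        back = list(reversed(bwd[i][1:]))     # drop duplicate seed record
        return np.asarray(back + fwd[i], dtype=np.float64)
    if len(fwd[0]) + max(len(bwd[0]) - 1, 0) < 2:
        return None
    return Fiber(points=cat(0), fa1=cat(1), fa2=cat(2), ga=cat(3),
                 omega=cat(4), reasons=(bwd[5], fwd[5]))


def track(dwi: DWIVolume, seed_mask: np.ndarray, config: UKFConfig,
          tracking_mask: np.ndarray | None = None) -> TractSet:
    """Track from every seed-mask voxel (``seeds_per_voxel`` jittered seeds).

    Fibers shorter than ``min_length_mm`` are discarded.  Deterministic under
    a fixed ``config.rng_seed``.
    """
    seed_mask = np.asarray(seed_mask, bool)
    tracking_mask = np.ones(dwi.shape3, dtype=bool) if tracking_mask is None \
        else np.asarray(tracking_mask, bool)
    rng = np.random.default_rng(config.rng_seed)
    interp = SignalInterpolator(dwi)
    filt = UKFFilter(config, dwi.weighted_gradients, dwi.b_weighted)
    step = _resolve_step(config, dwi.spacing)

    voxels = np.argwhere(seed_mask)
    fibers = []
    counts = {"seeds": 0, "rejected": 0, "short": 0}
    reasons: dict[str, int] = {}
    for vox in voxels:
        for _ in range(config.seeds_per_voxel):
            jitter = rng.uniform(-0.5, 0.5, size=3)
            point = dwi.index_to_world(vox + jitter)
            counts["seeds"] += 1
            fiber = track_from_seed(dwi, point, config, tracking_mask,
                                    interp=interp, filt=filt)
            if fiber is None:
                counts["rejected"] += 1
                continue
            if fiber.length_mm() < config.min_length_mm:
                counts["short"] += 1
                continue
            for r in fiber.reasons:
                reasons[r] = reasons.get(r, 0) + 1
            fibers.append(fiber)
    meta = {"config": {k: v for k, v in vars(config).items()},
            "counts": counts, "termination_reasons": reasons}
    return TractSet(fibers=fibers, spacing=dwi.spacing.copy(),
                    origin=dwi.origin.copy(), shape=dwi.shape3,
                    step_mm=step, meta=meta)
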