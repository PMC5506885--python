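"""Quantitative evaluation of fiber bundles.

* coverage — fraction of a target mask's voxels reached by at least one
  fiber point (C = V_fiber / V_target);
* traversal — fraction of fibers that pass through an edema mask and reach a
  far target beyond it;
* ROI selection and midline-crossing rejection;
* per-fiber and bundle length statistics.

Fiber points are mapped to voxels by rounding the continuous index to the
nearest voxel center; fibers are treated as point sequences (no segment
rasterization), which is adequate while the tracking step does not exceed
the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Fiber, TractSet


@dataclass
class CoverageReport:
    target: str
    v_target: int
    v_fiber: int

    @property
    def coverage(self) -> float:
        return self.v_fiber / self.v_target

    def as_dict(self) -> dict:
        return {"target": self.target, "v_target": self.v_target,
                "v_fiber": self.v_fiber, "coverage": self.coverage}


def _fiber_voxels(tracts: TractSet, fiber: Fiber) -> np.ndarray:
    """Voxel indices visited by a fiber, clipped mask-out when off-grid."""
    vox = tracts.point_to_voxel(fiber.points)
    shape = np.asarray(tracts.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    return vox[inside]


def _touches(tracts: TractSet, fiber: Fiber, mask: np.ndarray) -> bool:
    vox = _fiber_voxels(tracts, fiber)
    return bool(len(vox)) and bool(mask[vox[:, 0], vox[:, 1], vox[:, 2]].any())


def coverage(tracts: TractSet, target_mask: np.ndarray,
             name: str = "target") -> CoverageReport:
    """Fraction of target voxels containing at least one fiber point."""
    target_mask = np.asarray(target_mask, bool)
    v_target = int(target_mask.sum())
    if v_target == 0:
        raise ValueError("empty target mask")
    reached = np.zeros_like(target_mask)
    for fiber in tracts:
        vox = _fiber_voxels(tracts, fiber)
        reached[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    v_fiber = int((reached & target_mask).sum())
    return CoverageReport(target=name, v_target=v_target, v_fiber=v_fiber)


def traversal_fraction(tracts: TractSet, edema_mask: np.ndarray,
                       far_mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Fraction of fibers with points both inside the edema and in the far
    target beyond it; also returns the per-fiber boolean flags."""
    edema_mask = np.asarray(edema_mask, bool)
    far_mask = np.asarray(far_mask, bool)
    flags = np.array([_touches(tracts, f, edema_mask)
                      and _touches(tracts, f, far_mask) for f in tracts],
                     dtype=bool)
    frac = float(flags.mean()) if len(flags) else 0.0
    return frac, flags


def select_by_rois(tracts: TractSet, rois: list[np.ndarray],
                   mode: str = "all") -> TractSet:
    """Keep fibers intersecting all (or any) of the ROI masks, stable order."""
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    if not rois:
        kept = list(tracts.fibers)
    else:
        combine = all if mode == "all" else any
        kept = [f for f in tracts
                if combine(_touches(tracts, f, np.asarray(r, bool))
                           for r in rois)]
    return TractSet(fibers=kept, spacing=tracts.spacing.copy(),
                    origin=tracts.origin.copy(), shape=tracts.shape,
                    step_mm=tracts.step_mm,
                    meta={**tracts.meta, "selection": mode})


def reject_midline_crossers(tracts: TractSet, midline_coordinate: float,
                            axis: int, tolerance_mm: float = 0.0) -> TractSet:
    """Drop fibers with points on both sides of a midline plane.

    Excursions within ``tolerance_mm`` of the plane do not count as crossing.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    kept = []
    for fiber in tracts:
        coord = fiber.points[:, axis] - midline_coordinate
        crosses = (coord > tolerance_mm).any() and (coord < -tolerance_mm).any()
        if not crosses:
            kept.append(fiber)
    return TractSet(fibers=kept, spacing=tracts.spacing.copy(),
                    origin=tracts.origin.copy(), shape=tracts.shape,
                    step_mm=tracts.step_mm,
                    meta={**tracts.meta, "midline_rejected":
                          len(tracts) - len(kept)})


def length_stats(tracts: TractSet) -> dict:
    """Per-fiber lengths plus summary (count, total, mean, median), in mm."""
    lengths = np.array([f.length_mm() for f in tracts], dtype=float)
    if len(lengths) == 0:
        return {"count": 0, "total_mm": 0.0, "mean_mm": 0.0,
                "median_mm": 0.0, "lengths_mm": lengths}
    return {"count": int(len(lengths)),
            "total_mm": float(lengths.sum()),
            "mean_mm": float(lengths.mean()),
            "median_mm": float(np.median(lengths)),
            "lengths_mm": lengths}
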