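"""Diffusion-MRI container and file formats.

The central container is :class:`DWIVolume`: a 4D signal array (three spatial
axes plus one volume axis) with per-volume gradient directions and b-values,
on an axis-aligned grid (world mm = origin + index * spacing, 0-based voxel
indices at voxel centers).

Formats:

* NRRD (primary) with the DWMRI key/value convention used by 3D Slicer:
  ``DWMRI_b-value`` and one ``DWMRI_gradient_NNNN`` entry per volume
  (zero vector marks a baseline).  Only the subset of NRRD needed for these
  volumes is implemented: raw little-endian encoding, per-axis ``spacings``
  and ``axis mins``.
* NIfTI plus FSL-style ``.bval``/``.bvec`` text pair (secondary), via nibabel.
* TrackVis TRK for fiber bundles (via nibabel.streamlines) with per-point
  scalars, and legacy ASCII VTK polydata as an alternative export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from nibabel.streamlines import Tractogram
from nibabel.streamlines.trk import TrkFile


class FormatError(ValueError):
    """A file does not carry the metadata required to interpret it."""


# --------------------------------------------------------------------------
# DWI container
# --------------------------------------------------------------------------

@dataclass
class DWIVolume:
    """4D diffusion-weighted volume with gradient table and grid geometry.

    Parameters
    ----------
    data : (X, Y, Z, V) array
        Signal values; the last axis enumerates acquired volumes.
    gradients : (V, 3) array
        Unit gradient direction per volume; all-zero rows mark baselines.
    bvalues : (V,) array
        b-value per volume in s/mm^2 (0 for baselines).
    spacing, origin : (3,) arrays, mm.
    """

    data: np.ndarray
    gradients: np.ndarray
    bvalues: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.gradients = np.asarray(self.gradients, dtype=np.float64)
        self.bvalues = np.atleast_1d(np.asarray(self.bvalues, dtype=np.float64))
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.data.ndim != 4:
            raise FormatError("DWI data must be 4D (x, y, z, volume)")
        nvol = self.data.shape[3]
        if self.bvalues.size == 1:
            b = np.full(nvol, float(self.bvalues))
            b[np.linalg.norm(self.gradients, axis=1) == 0] = 0.0
            self.bvalues = b
        if self.gradients.shape != (nvol, 3):
            raise FormatError(
                f"gradient count {self.gradients.shape} does not match "
                f"{nvol} volumes")
        if np.any(self.spacing <= 0):
            raise FormatError("voxel spacing must be positive")
        norms = np.linalg.norm(self.gradients, axis=1)
        weighted = norms > 0
        if np.any(np.abs(norms[weighted] - 1.0) > 1e-6):
            raise FormatError("diffusion gradient directions must be unit vectors")
        if not np.any(weighted):
            raise FormatError("no diffusion-weighted volumes present")

    # -- bookkeeping -------------------------------------------------------

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def baseline_mask(self) -> np.ndarray:
        return np.linalg.norm(self.gradients, axis=1) == 0

    @property
    def weighted_gradients(self) -> np.ndarray:
        return self.gradients[~self.baseline_mask]

    @property
    def b_weighted(self) -> float:
        b = np.unique(self.bvalues[~self.baseline_mask])
        if b.size != 1:
            raise FormatError("multi-shell data not supported")
        return float(b[0])

    def s0(self) -> np.ndarray:
        """Mean baseline volume, floored at a tiny positive value."""
        base = self.data[..., self.baseline_mask]
        if base.shape[-1] == 0:
            return np.ones(self.shape3)
        return np.maximum(base.mean(axis=-1), 1e-12)

    def normalized(self) -> np.ndarray:
        """(X, Y, Z, G) array of S_i / S_0 over the weighted volumes."""
        return self.data[..., ~self.baseline_mask] / self.s0()[..., None]

    # -- geometry ----------------------------------------------------------

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - self.origin) / self.spacing

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=np.float64) * self.spacing

    def point_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel (round-half-up on the continuous index)."""
        return np.floor(self.world_to_index(points) + 0.5).astype(np.intp)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True where a point lies within the voxel extent of the grid."""
        ci = self.world_to_index(points)
        hi = np.array(self.shape3) - 0.5
        return np.all((ci >= -0.5) & (ci <= hi), axis=-1)


# --------------------------------------------------------------------------
# Fibers
# --------------------------------------------------------------------------

@dataclass
class Fiber:
    """One streamline: ordered world-mm points with per-point model scalars."""

    points: np.ndarray                     # (M, 3)
    fa1: np.ndarray | None = None
    fa2: np.ndarray | None = None
    ga: np.ndarray | None = None
    omega: np.ndarray | None = None
    reasons: tuple[str, str] = ("", "")    # termination of the two half-tracks

    def __len__(self) -> int:
        return len(self.points)

    def length_mm(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class TractSet:
    """A named bundle of fibers plus the grid it was traced on."""

    fibers: list[Fiber] = field(default_factory=list)
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    shape: tuple[int, int, int] = (1, 1, 1)
    step_mm: float = 0.0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fibers)

    def __iter__(self):
        return iter(self.fibers)

    def point_to_voxel(self, points: np.ndarray) -> np.ndarray:
        ci = (np.asarray(points, dtype=np.float64) - self.origin) / self.spacing
        return np.floor(ci + 0.5).astype(np.intp)


# --------------------------------------------------------------------------
# NRRD
# --------------------------------------------------------------------------

_NRRD_TYPES = {
    "double": np.float64, "float": np.float32,
    "unsigned char": np.uint8, "uchar": np.uint8,
    "short": np.int16, "int": np.int32, "unsigned int": np.uint32,
}
_NP_TO_NRRD = {
    np.dtype(np.float64): "double", np.dtype(np.float32): "float",
    np.dtype(np.uint8): "unsigned char", np.dtype(np.int16): "short",
    np.dtype(np.int32): "int", np.dtype(np.uint32): "unsigned int",
}


def write_nrrd(path, array: np.ndarray, spacing, origin, keyvalues: dict | None = None) -> None:
    """Write a 3D scalar or 4D (spatial-first) array as raw little-endian NRRD."""
    array = np.asarray(array)
    if array.dtype not in _NP_TO_NRRD:
        array = array.astype(np.float64)
    ndim = array.ndim
    if ndim not in (3, 4):
        raise FormatError("only 3D/4D arrays supported")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    kinds = ["space"] * 3 + (["list"] if ndim == 4 else [])
    spac = [f"{s:.17g}" for s in spacing] + (["nan"] if ndim == 4 else [])
    mins = [f"{o:.17g}" for o in origin] + (["nan"] if ndim == 4 else [])
    lines = [
        "NRRD0005",
        f"type: {_NP_TO_NRRD[array.dtype]}",
        f"dimension: {ndim}",
        "sizes: " + " ".join(str(s) for s in array.shape),
        "kinds: " + " ".join(kinds),
        "endian: little",
        "encoding: raw",
        "spacings: " + " ".join(spac),
        "axis mins: " + " ".join(mins),
    ]
    for key, val in (keyvalues or {}).items():
        lines.append(f"{key}:={val}")
    with open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n\n").encode("ascii"))
        # NRRD orders data with the first listed axis varying fastest
        fh.write(np.ascontiguousarray(array.ravel(order="F")).astype(
            array.dtype.newbyteorder("<")).tobytes())


def read_nrrd(path):
    """Read an NRRD written by this package (raw encoding). Returns (array, header)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    end = raw.find(b"\n\n")
    if end < 0:
        raise FormatError(f"{path}: no NRRD header terminator")
    header_text = raw[:end].decode("ascii", errors="replace")
    lines = header_text.splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise FormatError(f"{path}: not an NRRD file")
    fields: dict[str, str] = {}
    keyvalues: dict[str, str] = {}
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        if ":=" in line:
            key, val = line.split(":=", 1)
            keyvalues[key.strip()] = val.strip()
        elif ": " in line or line.endswith(":"):
            key, _, val = line.partition(":")
            fields[key.strip().lower()] = val.strip()
    try:
        sizes = [int(s) for s in fields["sizes"].split()]
        dtype = _NRRD_TYPES[fields["type"]]
    except KeyError as exc:
        raise FormatError(f"{path}: missing NRRD field {exc}") from exc
    if fields.get("encoding", "raw") != "raw":
        raise FormatError(f"{path}: only raw encoding supported")
    if np.dtype(dtype).itemsize > 1 and fields.get("endian", "little") != "little":
        raise FormatError(f"{path}: only little-endian supported")
    count = int(np.prod(sizes))
    data = np.frombuffer(raw[end + 2:], dtype=np.dtype(dtype).newbyteorder("<"),
                         count=count)
    array = data.reshape(sizes, order="F")
    header = {"fields": fields, "keyvalues": keyvalues}
    return array, header


def _grid_from_header(header, ndim_spatial=3):
    fields = header["fields"]
    def parse(name, default):
        if name not in fields:
            return np.full(ndim_spatial, default, dtype=float)
        vals = [float(v) for v in fields[name].split()[:ndim_spatial]]
        return np.asarray(vals, dtype=float)
    spacing = parse("spacings", 1.0)
    origin = parse("axis mins", 0.0)
    return spacing, origin


def write_dwi_nrrd(vol: DWIVolume, path) -> None:
    kv = {"modality": "DWMRI",
          "DWMRI_b-value": f"{vol.b_weighted:.17g}"}
    for i, g in enumerate(vol.gradients):
        kv[f"DWMRI_gradient_{i:04d}"] = f"{g[0]:.17g} {g[1]:.17g} {g[2]:.17g}"
    write_nrrd(path, vol.data, vol.spacing, vol.origin, kv)


def read_dwi_nrrd(path) -> DWIVolume:
    array, header = read_nrrd(path)
    kv = header["keyvalues"]
    if array.ndim != 4:
        raise FormatError(f"{path}: DWI NRRD must be 4D")
    if "DWMRI_b-value" not in kv:
        raise FormatError(f"{path}: missing key 'DWMRI_b-value'")
    nvol = array.shape[3]
    gradients = np.zeros((nvol, 3))
    for i in range(nvol):
        key = f"DWMRI_gradient_{i:04d}"
        if key not in kv:
            raise FormatError(f"{path}: missing key '{key}'")
        gradients[i] = [float(v) for v in kv[key].split()]
    b = float(kv["DWMRI_b-value"])
    bvalues = np.where(np.linalg.norm(gradients, axis=1) > 0, b, 0.0)
    spacing, origin = _grid_from_header(header)
    return DWIVolume(array, gradients, bvalues, spacing, origin)


def write_mask_nrrd(mask: np.ndarray, spacing, origin, path) -> None:
    write_nrrd(path, mask.astype(np.uint8), spacing, origin)


def read_mask_nrrd(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    array, header = read_nrrd(path)
    spacing, origin = _grid_from_header(header)
    return array.astype(bool), spacing, origin


def read_map_nrrd(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    array, header = read_nrrd(path)
    spacing, origin = _grid_from_header(header)
    return np.asarray(array, dtype=np.float64), spacing, origin


# --------------------------------------------------------------------------
# NIfTI + bval/bvec
# --------------------------------------------------------------------------

def write_dwi_nifti(vol: DWIVolume, path) -> None:
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.data, affine), str(path))
    stem = str(path).removesuffix(".gz").removesuffix(".nii")
    np.savetxt(stem + ".bval", vol.bvalues[None], fmt="%.17g")
    np.savetxt(stem + ".bvec", vol.gradients.T, fmt="%.17g")


def read_dwi_nifti(path) -> DWIVolume:
    path = Path(path)
    img = nib.load(str(path))
    stem = str(path).removesuffix(".gz").removesuffix(".nii")
    try:
        bvalues = np.loadtxt(stem + ".bval").ravel()
        gradients = np.loadtxt(stem + ".bvec").T
    except OSError as exc:
        raise FormatError(f"{path}: missing bval/bvec pair") from exc
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    origin = affine[:3, 3]
    return DWIVolume(np.asarray(img.dataobj, dtype=np.float64),
                     gradients, bvalues, spacing, origin)


def read_dwi(path) -> DWIVolume:
    name = str(path)
    if name.endswith(".nrrd") or name.endswith(".nhdr"):
        return read_dwi_nrrd(path)
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return read_dwi_nifti(path)
    raise FormatError(f"unknown DWI format: {path}")


def write_dwi(vol: DWIVolume, path) -> None:
    name = str(path)
    if name.endswith(".nrrd"):
        write_dwi_nrrd(vol, path)
    elif name.endswith(".nii") or name.endswith(".nii.gz"):
        write_dwi_nifti(vol, path)
    else:
        raise FormatError(f"unknown DWI format: {path}")


# --------------------------------------------------------------------------
# Tract I/O
# --------------------------------------------------------------------------

_SCALARS = ("fa1", "fa2", "ga", "omega")


def write_tracts(tracts: TractSet, path, format: str | None = None) -> None:
    name = str(path)
    fmt = format or ("trk" if name.endswith(".trk")
                     else "vtk" if name.endswith(".vtk") else None)
    if fmt == "trk":
        _write_trk(tracts, path)
    elif fmt == "vtk":
        _write_vtk(tracts, path)
    else:
        raise FormatError(f"unknown tract format: {path}")


def _write_trk(tracts: TractSet, path) -> None:
    streams = [f.points.astype(np.float32) for f in tracts.fibers]
    dpp = {}
    for key in _SCALARS:
        vals = [getattr(f, key) for f in tracts.fibers]
        if all(v is not None for v in vals) and len(vals) > 0:
            dpp[key] = [np.asarray(v, dtype=np.float32)[:, None] for v in vals]
    tg = Tractogram(streams, data_per_point=dpp or None,
                    affine_to_rasmm=np.eye(4))
    affine = np.diag(list(tracts.spacing) + [1.0])
    affine[:3, 3] = tracts.origin
    header = {
        "voxel_sizes": np.asarray(tracts.spacing, dtype=np.float32),
        "dimensions": np.asarray(tracts.shape, dtype=np.int16),
        "voxel_to_rasmm": affine.astype(np.float32),
        "voxel_order": "RAS",
    }
    TrkFile(tg, header=header).save(str(path))


def read_tracts(path) -> TractSet:
    name = str(path)
    if not name.endswith(".trk"):
        raise FormatError(f"only TRK reading supported: {path}")
    trk = TrkFile.load(str(path))
    header = trk.header
    spacing = np.asarray(header["voxel_sizes"], dtype=float)
    affine = np.asarray(header["voxel_to_rasmm"], dtype=float)
    origin = affine[:3, 3]
    shape = tuple(int(s) for s in header["dimensions"])
    fibers = []
    tg = trk.tractogram
    for i, pts in enumerate(tg.streamlines):
        kw = {}
        for key in _SCALARS:
            if key in tg.data_per_point:
                kw[key] = np.asarray(tg.data_per_point[key][i]).ravel().astype(float)
        fibers.append(Fiber(points=np.asarray(pts, dtype=np.float64), **kw))
    return TractSet(fibers=fibers, spacing=spacing, origin=origin, shape=shape)


def _write_vtk(tracts: TractSet, path) -> None:
    """Legacy ASCII VTK polydata: one polyline per fiber + point scalars."""
    npts = sum(len(f) for f in tracts.fibers)
    lines = ["# vtk DataFile Version 3.0", "ukftract fibers", "ASCII",
             "DATASET POLYDATA", f"POINTS {npts} float"]
    for f in tracts.fibers:
        for p in f.points:
            lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    nlines = len(tracts.fibers)
    lines.append(f"LINES {nlines} {nlines + npts}")
    offset = 0
    for f in tracts.fibers:
        lines.append(str(len(f)) + " " + " ".join(
            str(offset + j) for j in range(len(f))))
        offset += len(f)
    scalar_arrays = {key: np.concatenate([getattr(f, key) for f in tracts.fibers])
                     for key in _SCALARS
                     if tracts.fibers and all(getattr(f, key) is not None
                                              for f in tracts.fibers)}
    if scalar_arrays and npts:
        lines.append(f"POINT_DATA {npts}")
        for key, vals in scalar_arrays.items():
            lines.append(f"SCALARS {key} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.6f}" for v in vals)
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

def write_report(report: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(report, indent=2, default=_jsonable) + "\n")
    elif path.suffix == ".csv":
        keys = list(report)
        path.write_text(",".join(keys) + "\n" +
                        ",".join(str(_jsonable(report[k])) for k in keys) + "\n")
    else:
        raise FormatError(f"unknown report format: {path}")


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v
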