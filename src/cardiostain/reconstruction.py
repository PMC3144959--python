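"""Rigid alignment of segmented slices and 3D volume reconstruction.

Consecutive binary stain masks are registered (translation + rotation
maximizing Dice overlap, exhaustive integer grid search via FFT
cross-correlation plus a local sub-pixel/sub-degree refinement), composed
into the first slice's frame, replicated along z to simulate section
thickness, and exported as a MetaImage (.mhd/.raw) volume with
maximum-intensity orthogonal projections.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.signal import fftconvolve

from .errors import FormatError, InvalidParameterError
from .transforms import RigidTransform, apply_rigid

__all__ = [
    "RegistrationResult",
    "StainVolume",
    "select_slices",
    "register_pair",
    "align_series",
    "stack_volume",
    "write_metaimage",
    "read_metaimage",
    "export_orthogonal_views",
]

log = logging.getLogger(__name__)

DEFAULT_REPLICATION = 7


def _as_mask(m) -> np.ndarray:
    arr = np.asarray(getattr(m, "mask", m))
    if arr.ndim != 2:
        raise FormatError("expected a 2D binary mask")
    return arr.astype(bool)


def select_slices(series: list, subset: list) -> list:
    """Order-preserving subsequence of the slice series."""
    n = len(series)
    prev = -1
    out = []
    for idx in subset:
        if not isinstance(idx, (int, np.integer)):
            raise InvalidParameterError("subset indices must be integers")
        if idx < 0 or idx >= n:
            raise InvalidParameterError(f"slice index {idx} out of range [0, {n})")
        if idx <= prev:
            raise InvalidParameterError("subset indices must be strictly increasing")
        prev = idx
        out.append(series[idx])
    return out


@dataclass
class RegistrationResult:
    """Outcome of a pairwise mask registration."""

    transform: RigidTransform
    dice: float
    flagged_empty: bool = False


def _overlap_map(fixed: np.ndarray, moved: np.ndarray) -> np.ndarray:
    """Cross-correlation of two binary masks: entry (dy, dx) (offset by
    H-1, W-1 in the returned 'full' array) is the overlap count when
    ``moved`` is shifted by (dy, dx)."""
    return fftconvolve(fixed.astype(np.float32), moved[::-1, ::-1].astype(np.float32), mode="full")


def _best_shift(ov: np.ndarray, h: int, w: int, bound: int) -> tuple[int, int, float]:
    """Best integer (dy, dx) within +/-bound; ties to smallest |dy|+|dx|."""
    cy, cx = h - 1, w - 1
    win = ov[cy - bound: cy + bound + 1, cx - bound: cx + bound + 1]
    counts = np.rint(win).astype(np.int64)
    best = counts.max()
    ties = np.argwhere(counts == best)
    offs = ties - bound
    costs = np.abs(offs).sum(axis=1)
    pick = offs[np.lexsort((offs[:, 1], offs[:, 0], costs))[0]]
    return int(pick[0]), int(pick[1]), float(best)


def register_pair(
    moving,
    fixed,
    translation_bound: int = 15,
    rotation_bound_deg: float = 10.0,
    rotation_step_deg: float = 1.0,
    refine: bool = True,
) -> RegistrationResult:
    """Find the rigid transform maximizing Dice overlap of ``moving``
    (after transformation) with ``fixed``.

    Exhaustive search on a 1 px / ``rotation_step_deg`` grid (translations
    scanned densely via FFT cross-correlation per rotation candidate),
    then, when ``refine`` is set, a 0.1-degree local rotation sweep and a
    parabolic sub-pixel interpolation of the translation peak.
    Deterministic; exact ties break toward the smallest |tx|+|ty|+|theta|.
    Empty inputs yield a flagged identity.
    """
    mov = _as_mask(moving)
    fix = _as_mask(fixed)
    if mov.shape != fix.shape:
        raise InvalidParameterError("moving and fixed masks must share dimensions")
    n_fix = int(fix.sum())
    n_mov = int(mov.sum())
    if n_fix == 0 or n_mov == 0:
        log.warning("register_pair: empty mask; returning identity (flagged)")
        return RegistrationResult(RigidTransform.identity(), dice=0.0, flagged_empty=True)
    h, w = fix.shape

    def _eval_theta(theta_deg: float):
        rot = apply_rigid(mov, RigidTransform(theta=math.radians(theta_deg)), order=0)
        ov = _overlap_map(fix, rot)
        dy, dx, best = _best_shift(ov, h, w, translation_bound)
        dice = 2.0 * best / (n_fix + int(rot.sum()))
        return dice, dy, dx, ov

    n_steps = int(round(rotation_bound_deg / rotation_step_deg))
    thetas = [i * rotation_step_deg for i in range(-n_steps, n_steps + 1)]
    results = {}
    best_key = None
    for th in thetas:
        dice, dy, dx, ov = _eval_theta(th)
        results[th] = (dice, dy, dx, ov)
        key = (-dice, abs(dx) + abs(dy) + abs(th), abs(th), th)
        if best_key is None or key < best_key:
            best_key, best_theta = key, th
    dice, dy, dx, ov = results[best_theta]

    if refine:
        fine = [best_theta + 0.1 * i for i in range(-9, 10)]
        for th in fine:
            if th in results or abs(th) > rotation_bound_deg:
                continue
            d, y_, x_, o_ = _eval_theta(th)
            results[th] = (d, y_, x_, o_)
            key = (-d, abs(x_) + abs(y_) + abs(th), abs(th), th)
            if key < best_key:
                best_key, best_theta = key, th
        dice, dy, dx, ov = results[best_theta]
        dy_f = dy + _parabolic_offset(ov, h - 1 + dy, w - 1 + dx, axis=0)
        dx_f = dx + _parabolic_offset(ov, h - 1 + dy, w - 1 + dx, axis=1)
    else:
        dy_f, dx_f = float(dy), float(dx)

    t = RigidTransform(tx=dx_f, ty=dy_f, theta=math.radians(best_theta))
    return RegistrationResult(transform=t, dice=float(dice))


def _parabolic_offset(ov: np.ndarray, iy: int, ix: int, axis: int) -> float:
    """Sub-pixel peak offset from a 3-point parabola along one axis."""
    if axis == 0:
        if iy <= 0 or iy >= ov.shape[0] - 1:
            return 0.0
        f0, f1, f2 = ov[iy - 1, ix], ov[iy, ix], ov[iy + 1, ix]
    else:
        if ix <= 0 or ix >= ov.shape[1] - 1:
            return 0.0
        f0, f1, f2 = ov[iy, ix - 1], ov[iy, ix], ov[iy, ix + 1]
    # overlaps are integer counts; round away FFT noise so exact symmetry
    # yields an exactly-zero offset
    f0, f1, f2 = (float(np.rint(v)) for v in (f0, f1, f2))
    denom = f0 - 2.0 * f1 + f2
    if denom >= -1e-9:  # flat or non-concave: keep the integer peak
        return 0.0
    off = 0.5 * (f0 - f2) / denom
    return float(np.clip(off, -0.5, 0.5))


def align_series(masks: list, **kwargs) -> tuple[list, list]:
    """Register each slice to its predecessor and compose the transforms
    into the first slice's frame.

    Returns ``(aligned_masks, transforms)`` where ``transforms[k]`` maps
    slice k into slice 0's frame (``transforms[0]`` is the identity).
    """
    arrs = [_as_mask(m) for m in masks]
    if not arrs:
        raise InvalidParameterError("align_series requires at least one mask")
    transforms = [RigidTransform.identity()]
    for k in range(1, len(arrs)):
        res = register_pair(arrs[k], arrs[k - 1], **kwargs)
        # slice k -> slice k-1, then slice k-1 -> frame 0
        transforms.append(res.transform.then(transforms[k - 1]))
    aligned = [arrs[0]] + [
        apply_rigid(arrs[k], transforms[k], order=0) for k in range(1, len(arrs))
    ]
    return aligned, transforms


@dataclass
class StainVolume:
    """Stacked binary stain volume with z-replication provenance."""

    voxels: np.ndarray  # (Z, H, W) bool
    replication_factor: int
    slice_ids: list
    spacing: tuple = (1.0, 1.0, 1.0)  # (z, y, x)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise FormatError("StainVolume.voxels must be 3D (Z, H, W)")

    @property
    def n_slices(self) -> int:
        return len(self.slice_ids)

    @property
    def true_voxel_count(self) -> int:
        return int(np.count_nonzero(self.voxels))

    def to_dict(self) -> dict:
        return {
            "shape_zyx": list(self.voxels.shape),
            "replication_factor": self.replication_factor,
            "slice_ids": list(self.slice_ids),
            "spacing_zyx": list(self.spacing),
            "true_voxel_count": self.true_voxel_count,
        }


def stack_volume(
    aligned: list,
    replication_factor: int = DEFAULT_REPLICATION,
    section_thickness_um: float = 20.0,
    in_plane_spacing: float = 1.0,
    slice_ids: list | None = None,
) -> StainVolume:
    """Stack aligned masks into a 3D volume, replicating each mask
    ``replication_factor`` times along z to simulate section thickness.

    z-spacing is ``section_thickness_um / replication_factor`` so the
    replicated layers of one mask span one physical section.
    """
    if replication_factor < 1:
        raise InvalidParameterError("replication_factor must be >= 1")
    arrs = [_as_mask(m) for m in aligned]
    if not arrs:
        raise InvalidParameterError("stack_volume requires at least one mask")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise InvalidParameterError("all masks must share dimensions")
    stacked = np.stack(arrs, axis=0)
    voxels = np.repeat(stacked, replication_factor, axis=0)
    if slice_ids is None:
        slice_ids = list(range(len(arrs)))
    return StainVolume(
        voxels=voxels,
        replication_factor=replication_factor,
        slice_ids=list(slice_ids),
        spacing=(section_thickness_um / replication_factor, in_plane_spacing, in_plane_spacing),
    )


def write_metaimage(volume: StainVolume, path) -> tuple[Path, Path]:
    """Write a MetaImage pair: text ``.mhd`` header + ``.raw`` voxel data
    (MET_UCHAR, true voxels stored as 255).  Returns (header, raw) paths."""
    path = Path(path)
    if path.suffix != ".mhd":
        path = path.with_suffix(".mhd")
    raw_path = path.with_suffix(".raw")
    z, h, w = volume.voxels.shape
    sz, sy, sx = volume.spacing
    header = "\n".join([
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = 1 0 0 0 1 0 0 0 1",
        "Offset = 0 0 0",
        f"DimSize = {w} {h} {z}",
        f"ElementSpacing = {sx:g} {sy:g} {sz:g}",
        "ElementType = MET_UCHAR",
        f"ElementDataFile = {raw_path.name}",
    ]) + "\n"
    path.write_text(header)
    raw_path.write_bytes((volume.voxels.astype(np.uint8) * 255).tobytes())
    return path, raw_path


def read_metaimage(path) -> StainVolume:
    """Read back a MetaImage volume written by :func:`write_metaimage`."""
    path = Path(path)
    fields = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip()] = v.strip()
    if fields.get("ObjectType") != "Image" or fields.get("NDims") != "3":
        raise FormatError("unsupported MetaImage header")
    if fields.get("ElementType") != "MET_UCHAR":
        raise FormatError("only MET_UCHAR volumes are supported")
    w, h, z = (int(v) for v in fields["DimSize"].split())
    sx, sy, sz = (float(v) for v in fields["ElementSpacing"].split())
    raw = (path.parent / fields["ElementDataFile"]).read_bytes()
    arr = np.frombuffer(raw, dtype=np.uint8)
    if arr.size != w * h * z:
        raise FormatError("raw data size does not match DimSize")
    voxels = arr.reshape(z, h, w) > 0
    return StainVolume(voxels=voxels, replication_factor=1,
                       slice_ids=list(range(z)), spacing=(sz, sy, sx))


def export_orthogonal_views(volume: StainVolume, outdir=None) -> dict:
    """Maximum-intensity projections along each axis (axial = along z,
    coronal = along y, sagittal = along x).  Returns the projection arrays;
    writes them as PNGs when ``outdir`` is given."""
    views = {
        "axial": volume.voxels.max(axis=0),
        "coronal": volume.voxels.max(axis=1),
        "sagittal": volume.voxels.max(axis=2),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, arr in views.items():
            iio.imwrite(outdir / f"projection_{name}.png", arr.astype(np.uint8) * 255)
    return views
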