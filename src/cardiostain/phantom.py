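"""Synthetic serial-section phantom generator.

Produces stacks of heart-like RGB "histology sections" — pink tissue
silhouette on a white background with blue stain patches concentrated on
one side of a recorded apex-to-base separation line — together with exact
ground truth: binary stain masks, per-slice rigid perturbations, and
per-side pixel counts.  Every downstream stage (segmentation,
quantification, registration, reconstruction) can therefore be tested
without any external data.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import GeometryError, InvalidParameterError
from .quantification import PartitionLine
from .slices import ColorSlice
from .transforms import RigidTransform, apply_rigid

__all__ = ["PhantomParams", "PhantomTruth", "generate_stack", "write_stack", "load_stack"]

# Defaults: deep blue chromogen on an eosin-pink counterstain, white background.
DEFAULT_STAIN_COLOR = (40, 40, 160)
DEFAULT_TISSUE_COLOR = (232, 150, 170)
DEFAULT_BACKGROUND_COLOR = (245, 245, 245)


@dataclass(frozen=True)
class PhantomParams:
    """Parameters for one synthetic serial-section stack."""

    n_slices: int = 5
    frame_height: int = 970
    frame_width: int = 690
    left_fraction: float = 0.9
    stain_color: tuple = DEFAULT_STAIN_COLOR
    tissue_color: tuple = DEFAULT_TISSUE_COLOR
    background_color: tuple = DEFAULT_BACKGROUND_COLOR
    noise_sd: float = 4.0
    jitter_translation_max: float = 0.0
    jitter_rotation_max: float = 0.0  # degrees
    n_stain_patches: int = 20
    patch_radius_range: tuple = (6.0, 8.0)
    section_thickness_um: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_slices < 1:
            raise InvalidParameterError("n_slices must be >= 1")
        if self.frame_height <= 0 or self.frame_width <= 0:
            raise InvalidParameterError("frame dimensions must be positive")
        if not 0.0 <= self.left_fraction <= 1.0:
            raise InvalidParameterError("left_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.n_stain_patches < 0:
            raise InvalidParameterError("n_stain_patches must be >= 0")
        if self.jitter_translation_max < 0 or self.jitter_rotation_max < 0:
            raise InvalidParameterError("jitter bounds must be >= 0")
        for name in ("stain_color", "tissue_color", "background_color"):
            col = getattr(self, name)
            if len(col) != 3 or any(not (0 <= v <= 255) for v in col):
                raise InvalidParameterError(f"{name} must be an RGB triple in [0, 255]")
        r0, r1 = self.patch_radius_range
        if not (0 < r0 <= r1):
            raise InvalidParameterError("patch_radius_range must satisfy 0 < lo <= hi")

    def to_dict(self) -> dict:
        return {
            "n_slices": self.n_slices,
            "frame_height": self.frame_height,
            "frame_width": self.frame_width,
            "left_fraction": self.left_fraction,
            "stain_color": list(self.stain_color),
            "tissue_color": list(self.tissue_color),
            "background_color": list(self.background_color),
            "noise_sd": self.noise_sd,
            "jitter_translation_max": self.jitter_translation_max,
            "jitter_rotation_max": self.jitter_rotation_max,
            "n_stain_patches": self.n_stain_patches,
            "patch_radius_range": list(self.patch_radius_range),
            "section_thickness_um": self.section_thickness_um,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomParams":
        d = dict(d)
        for key in ("stain_color", "tissue_color", "background_color", "patch_radius_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Exact ground truth recorded alongside a generated stack."""

    masks: list  # per-slice binary stain masks (H, W) bool
    transforms: list  # per-slice RigidTransform relative to slice 0's frame
    lines: list  # per-slice PartitionLine (transformed with the slice)
    left_counts: list
    right_counts: list
    params: PhantomParams

    @property
    def true_left_fraction(self) -> float:
        """Pooled left share of stain pixels across the stack."""
        left = sum(self.left_counts)
        total = left + sum(self.right_counts)
        return float("nan") if total == 0 else left / total

    def pairwise_transform(self, k: int) -> RigidTransform:
        """Transform aligning slice ``k`` onto slice ``k-1`` (the truth a
        pairwise registration should recover)."""
        if k < 1:
            raise InvalidParameterError("pairwise transform defined for k >= 1")
        return self.transforms[k].inverse().then(self.transforms[k - 1])


def _heart_silhouette(h: int, w: int) -> np.ndarray:
    """Two overlapping ellipses with a V-notch at the bottom (the apex)."""
    yy, xx = np.mgrid[0:h, 0:w]
    cx = (w - 1) / 2.0
    lobes = np.zeros((h, w), dtype=bool)
    for dx in (-0.10 * w, +0.10 * w):
        cy, ey, ex = 0.45 * h, 0.38 * h, 0.24 * w
        lobes |= ((yy - cy) / ey) ** 2 + ((xx - (cx + dx)) / ex) ** 2 <= 1.0
    # apex notch: upward wedge cut between the two bottom lobes
    notch_tip_y, notch_bottom_y = 0.70 * h, 0.90 * h
    half_width = 0.04 * w * (yy - notch_tip_y) / max(notch_bottom_y - notch_tip_y, 1e-9)
    notch = (yy >= notch_tip_y) & (np.abs(xx - cx) <= half_width)
    return lobes & ~notch


def _base_separation_line(tissue: np.ndarray) -> PartitionLine:
    """Straight apex-to-base line: from the lowest midline tissue pixel up
    to the top edge, offset slightly rightward (toward the 'aorta')."""
    h, w = tissue.shape
    cx = (w - 1) / 2.0
    col = tissue[:, int(round(cx))]
    rows = np.nonzero(col)[0]
    apex_y = float(rows.max()) if rows.size else float(h - 1)
    return PartitionLine(points=[(cx, apex_y), (cx + 0.04 * w, 0.0)])


def _place_patches(
    tissue: np.ndarray,
    line: PartitionLine,
    n_left: int,
    n_right: int,
    radius_range: tuple,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> np.ndarray:
    """Place non-overlapping stain disks fully inside tissue and strictly on
    their assigned side of the line.  Returns the boolean union mask."""
    h, w = tissue.shape
    dist_in = ndimage.distance_transform_edt(tissue)
    ys = np.arange(h)
    line_x = line.x_at(ys)
    mask = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []  # (y, x, r)
    sides = ["L"] * n_left + ["R"] * n_right
    for side in sides:
        r = float(rng.uniform(*radius_range))
        ok = False
        for _ in range(max_tries):
            y = rng.uniform(0, h - 1)
            x = rng.uniform(0, w - 1)
            iy, ix = int(round(y)), int(round(x))
            if dist_in[iy, ix] <= r + 1.5:
                continue
            margin = x - float(np.interp(y, ys, line_x))
            if side == "L" and margin > -(r + 1.5):
                continue
            if side == "R" and margin < (r + 1.5):
                continue
            if any((y - py) ** 2 + (x - px) ** 2 <= (r + pr + 2.0) ** 2 for py, px, pr in placed):
                continue
            ok = True
            break
        if not ok:
            raise GeometryError(
                f"could not place a {side}-side stain patch (r={r:.1f}) after "
                f"{max_tries} tries; frame too small or too many patches"
            )
        placed.append((y, x, r))
        yy, xx = np.ogrid[0:h, 0:w]
        mask |= (yy - y) ** 2 + (xx - x) ** 2 <= r**2
    return mask


def _split_sides(n: int, left_fraction: float, rng: np.random.Generator) -> tuple[int, int]:
    """Stochastically rounded quota so E[n_left] = left_fraction * n."""
    exact = left_fraction * n
    n_left = int(math.floor(exact))
    if rng.random() < exact - n_left:
        n_left += 1
    n_left = min(n_left, n)
    return n_left, n - n_left


def generate_stack(params: PhantomParams) -> tuple[list[ColorSlice], PhantomTruth]:
    """Generate an ordered (ventral-to-dorsal) stack of phantom sections.

    All slices share one base stain layout (serial sections of one block);
    slice ``k > 0`` is rigidly perturbed by a jitter transform recorded in
    the returned :class:`PhantomTruth`.  Deterministic given ``params``.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.frame_height, params.frame_width
    tissue = _heart_silhouette(h, w)
    line = _base_separation_line(tissue)
    n_left, n_right = _split_sides(params.n_stain_patches, params.left_fraction, rng)
    base_mask = (
        _place_patches(tissue, line, n_left, n_right, params.patch_radius_range, rng)
        if params.n_stain_patches > 0
        else np.zeros((h, w), dtype=bool)
    )
    base_img = np.empty((h, w, 3), dtype=np.uint8)
    base_img[:] = np.array(params.background_color, dtype=np.uint8)
    base_img[tissue] = np.array(params.tissue_color, dtype=np.uint8)
    base_img[base_mask] = np.array(params.stain_color, dtype=np.uint8)

    slices: list[ColorSlice] = []
    masks, transforms, lines, lefts, rights = [], [], [], [], []
    ys = np.arange(h)
    for k in range(params.n_slices):
        if k == 0 or (params.jitter_translation_max == 0 and params.jitter_rotation_max == 0):
            t = RigidTransform.identity()
        else:
            t = RigidTransform(
                tx=float(rng.uniform(-params.jitter_translation_max, params.jitter_translation_max)),
                ty=float(rng.uniform(-params.jitter_translation_max, params.jitter_translation_max)),
                theta=math.radians(
                    float(rng.uniform(-params.jitter_rotation_max, params.jitter_rotation_max))
                ),
            )
        img = apply_rigid(base_img, t, order=0, cval=tuple(params.background_color))
        mask = apply_rigid(base_mask, t, order=0, cval=0)
        pts_yx = np.array([(p[1], p[0]) for p in line.points])
        moved = t.apply_points(pts_yx, h, w)
        slice_line = PartitionLine(
            points=[(float(x), float(y)) for y, x in moved],
            side_convention=line.side_convention,
        )
        if params.noise_sd > 0:
            noisy = img.astype(np.float64) + rng.normal(0.0, params.noise_sd, img.shape)
            img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
        pos_y, pos_x = np.nonzero(mask)
        line_x = np.interp(pos_y.astype(float), ys, slice_line.x_at(ys))
        left = int(np.count_nonzero(pos_x < line_x))
        right = int(pos_x.size - left)
        slices.append(
            ColorSlice(pixels=img, order_index=k, section_thickness_um=params.section_thickness_um)
        )
        masks.append(mask)
        transforms.append(t)
        lines.append(slice_line)
        lefts.append(left)
        rights.append(right)
    truth = PhantomTruth(
        masks=masks, transforms=transforms, lines=lines,
        left_counts=lefts, right_counts=rights, params=params,
    )
    return slices, truth


def write_stack(outdir, slices: Sequence[ColorSlice], truth: PhantomTruth) -> dict:
    """Write slices as ``slice_###.png``, truth masks as ``truth_###.png``
    (0/255), a JSON sidecar with params/transforms/lines, and a counts CSV.
    Returns a manifest of written files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {"slices": [], "truth_masks": []}
    for k, sl in enumerate(slices):
        p = outdir / f"slice_{k:03d}.png"
        iio.imwrite(p, sl.pixels)
        files["slices"].append(str(p))
    for k, m in enumerate(truth.masks):
        p = outdir / f"truth_{k:03d}.png"
        iio.imwrite(p, (m.astype(np.uint8) * 255))
        files["truth_masks"].append(str(p))
    sidecar = {
        "params": truth.params.to_dict(),
        "transforms": [t.to_dict() for t in truth.transforms],
        "lines": [ln.to_dict() for ln in truth.lines],
        "true_left_fraction": truth.true_left_fraction,
    }
    sidecar_path = outdir / "phantom_truth.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    files["sidecar"] = str(sidecar_path)
    counts_path = outdir / "truth_counts.csv"
    with open(counts_path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["slice", "left_count", "right_count"])
        for k, (l, r) in enumerate(zip(truth.left_counts, truth.right_counts)):
            wr.writerow([k, l, r])
    files["counts"] = str(counts_path)
    return files


def load_stack(indir) -> tuple[list[ColorSlice], PhantomTruth]:
    """Inverse of :func:`write_stack`."""
    indir = Path(indir)
    sidecar = json.loads((indir / "phantom_truth.json").read_text())
    params = PhantomParams.from_dict(sidecar["params"])
    slices, masks = [], []
    for k in range(params.n_slices):
        img = np.asarray(iio.imread(indir / f"slice_{k:03d}.png"))
        slices.append(
            ColorSlice(pixels=img, order_index=k, section_thickness_um=params.section_thickness_um)
        )
        masks.append(np.asarray(iio.imread(indir / f"truth_{k:03d}.png")) > 0)
    transforms = [RigidTransform.from_dict(d) for d in sidecar["transforms"]]
    lines = [PartitionLine.from_dict(d) for d in sidecar["lines"]]
    lefts, rights = [], []
    with open(indir / "truth_counts.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            lefts.append(int(row["left_count"]))
            rights.append(int(row["right_count"]))
    truth = PhantomTruth(
        masks=masks, transforms=transforms, lines=lines,
        left_counts=lefts, right_counts=rights, params=params,
    )
    return slices, truth
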