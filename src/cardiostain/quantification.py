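"""Left/right morphometric quantification of stain-positive pixels.

Each section image is standardized to a fixed 690x970 analysis frame
(669300 pixels), stain-positive pixels are split by an apex-to-base
separation polyline, counts are aggregated per heart as mean +/- SEM and
per-slice percentages, and sides are compared with a two-sample t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from skimage.transform import resize

from .errors import FormatError, InvalidParameterError, InvalidPartitionError
from .slices import ColorSlice

__all__ = [
    "FRAME_WIDTH",
    "FRAME_HEIGHT",
    "FRAME_PIXELS",
    "PartitionLine",
    "SliceQuant",
    "HeartSummary",
    "SideComparison",
    "standardize_frame",
    "standardize_mask",
    "split_by_partition",
    "summarize_heart",
    "summarize_group",
    "compare_sides",
]

log = logging.getLogger(__name__)

FRAME_WIDTH = 690
FRAME_HEIGHT = 970
FRAME_PIXELS = FRAME_WIDTH * FRAME_HEIGHT  # 669300


@dataclass
class PartitionLine:
    """y-monotone polyline from the apex toward the base, in standardized
    image pixel coordinates.

    ``points`` is an ordered list of ``(x, y)`` pairs (>= 2).  Pixels whose
    center lies strictly left of the line at their row count as the
    ``side_convention`` "left" side; pixels exactly on the line go right.
    """

    points: list
    side_convention: str = "image_left"  # or "image_right"

    def __post_init__(self):
        pts = [(float(x), float(y)) for x, y in self.points]
        if len(pts) < 2:
            raise InvalidPartitionError("partition line needs at least 2 points")
        ys = [p[1] for p in pts]
        dys = np.diff(ys)
        if np.any(dys == 0) or not (np.all(dys > 0) or np.all(dys < 0)):
            raise InvalidPartitionError("partition polyline must be strictly y-monotone")
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            if x0 == x1 and y0 == y1:
                raise InvalidPartitionError("consecutive points must be distinct")
        if self.side_convention not in ("image_left", "image_right"):
            raise InvalidPartitionError("side_convention must be 'image_left' or 'image_right'")
        self.points = pts

    def x_at(self, y) -> np.ndarray:
        """x-coordinate of the line at row(s) ``y``; end segments are
        extended linearly beyond the polyline's vertical extent."""
        pts = self.points if self.points[0][1] < self.points[-1][1] else self.points[::-1]
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        y = np.asarray(y, dtype=float)
        out = np.interp(y, ys, xs)
        lo = y < ys[0]
        if np.any(lo):
            slope = (xs[1] - xs[0]) / (ys[1] - ys[0])
            out = np.where(lo, xs[0] + slope * (y - ys[0]), out)
        hi = y > ys[-1]
        if np.any(hi):
            slope = (xs[-1] - xs[-2]) / (ys[-1] - ys[-2])
            out = np.where(hi, xs[-1] + slope * (y - ys[-1]), out)
        return out

    def to_dict(self) -> dict:
        return {"points": [list(p) for p in self.points], "side_convention": self.side_convention}

    @classmethod
    def from_dict(cls, d: dict) -> "PartitionLine":
        return cls(points=[tuple(p) for p in d["points"]], side_convention=d["side_convention"])


@dataclass
class SliceQuant:
    """Per-slice left/right stain-positive pixel counts."""

    slice_id: int
    left_count: int
    right_count: int
    total_frame_pixels: int = FRAME_PIXELS

    def __post_init__(self):
        if self.left_count < 0 or self.right_count < 0:
            raise InvalidParameterError("counts must be >= 0")

    @property
    def total_positive(self) -> int:
        return self.left_count + self.right_count


@dataclass
class HeartSummary:
    """Per-heart aggregation of slice-level left/right counts."""

    heart_id: str
    n_slices: int
    mean_left: float
    mean_right: float
    sem_left: float
    sem_right: float
    pct_left: float  # mean over slices of per-slice left percentage
    pct_right: float
    n_slices_with_signal: int = 0
    flagged_no_signal: bool = False

    def to_dict(self) -> dict:
        return {
            "heart_id": self.heart_id,
            "n_slices": self.n_slices,
            "mean_left": self.mean_left,
            "mean_right": self.mean_right,
            "sem_left": self.sem_left,
            "sem_right": self.sem_right,
            "pct_left": self.pct_left,
            "pct_right": self.pct_right,
            "n_slices_with_signal": self.n_slices_with_signal,
            "flagged_no_signal": self.flagged_no_signal,
        }


@dataclass
class SideComparison:
    """Two-sample comparison of left vs right per-heart means."""

    mean_left: float
    mean_right: float
    sem_left: float
    sem_right: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    variant: str
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "mean_left": self.mean_left,
            "mean_right": self.mean_right,
            "sem_left": self.sem_left,
            "sem_right": self.sem_right,
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "variant": self.variant,
            "alpha": self.alpha,
            "significant": self.significant,
        }


def standardize_frame(slice_: ColorSlice) -> ColorSlice:
    """Resample a section image to exactly 690x970 (669300 pixels).

    Bilinear interpolation with anti-aliasing when shrinking; aspect
    distortion is permitted (only the total pixel count is normalized).
    Images already at the target size are returned unchanged.
    """
    img = slice_.pixels
    if img.shape[:2] == (FRAME_HEIGHT, FRAME_WIDTH):
        return slice_
    shrinking = img.shape[0] > FRAME_HEIGHT or img.shape[1] > FRAME_WIDTH
    out = resize(
        img.astype(np.float64),
        (FRAME_HEIGHT, FRAME_WIDTH),
        order=1,
        anti_aliasing=shrinking,
        preserve_range=True,
    )
    return ColorSlice(
        pixels=np.clip(np.rint(out), 0, 255).astype(np.uint8),
        order_index=slice_.order_index,
        section_thickness_um=slice_.section_thickness_um,
    )


def standardize_mask(mask: np.ndarray) -> np.ndarray:
    """Nearest-neighbor resample of a binary mask to the analysis frame."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise FormatError("mask must be 2D")
    if m.shape == (FRAME_HEIGHT, FRAME_WIDTH):
        return m.astype(bool)
    out = resize(m.astype(np.float64), (FRAME_HEIGHT, FRAME_WIDTH), order=0,
                 anti_aliasing=False, preserve_range=True)
    return out > 0.5


def split_by_partition(mask, line: PartitionLine) -> tuple[int, int]:
    """Count stain-positive pixels on each side of the partition line.

    A positive pixel at (row y, col x) is "left" iff ``x < line.x_at(y)``
    (half-open: pixels exactly on the line go right), then mapped through
    ``line.side_convention``.  Returns ``(left_count, right_count)``.
    """
    m = np.asarray(getattr(mask, "mask", mask))
    if m.ndim != 2:
        raise FormatError("mask must be 2D")
    pos_y, pos_x = np.nonzero(m)
    if pos_y.size == 0:
        return 0, 0
    line_x = line.x_at(pos_y.astype(float))
    img_left = int(np.count_nonzero(pos_x < line_x))
    img_right = int(pos_x.size - img_left)
    if line.side_convention == "image_left":
        return img_left, img_right
    return img_right, img_left


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    n = len(values)
    mean = float(np.mean(values))
    sem = 0.0 if n < 2 else float(np.std(values, ddof=1) / math.sqrt(n))
    return mean, sem


def summarize_heart(quants: Sequence[SliceQuant], heart_id: str = "heart") -> HeartSummary:
    """Aggregate per-slice counts for one heart.

    Percentages are the mean over slices of each slice's left (right) share
    of its positive pixels; slices with zero positives are excluded from
    the percentage mean (and logged).
    """
    if not quants:
        raise InvalidParameterError("summarize_heart requires at least one SliceQuant")
    lefts = np.array([q.left_count for q in quants], dtype=float)
    rights = np.array([q.right_count for q in quants], dtype=float)
    mean_left, sem_left = _mean_sem(lefts)
    mean_right, sem_right = _mean_sem(rights)
    totals = lefts + rights
    with_signal = totals > 0
    n_signal = int(np.count_nonzero(with_signal))
    if n_signal < len(quants):
        log.info("heart %s: %d/%d slices had zero positive pixels; excluded from "
                 "percentage mean", heart_id, len(quants) - n_signal, len(quants))
    if n_signal == 0:
        pct_left = pct_right = float("nan")
    else:
        pct_left = float(np.mean(lefts[with_signal] / totals[with_signal]) * 100.0)
        pct_right = float(np.mean(rights[with_signal] / totals[with_signal]) * 100.0)
    return HeartSummary(
        heart_id=heart_id,
        n_slices=len(quants),
        mean_left=mean_left,
        mean_right=mean_right,
        sem_left=sem_left,
        sem_right=sem_right,
        pct_left=pct_left,
        pct_right=pct_right,
        n_slices_with_signal=n_signal,
        flagged_no_signal=n_signal == 0,
    )


def summarize_group(values: Iterable[float]) -> tuple[float, float]:
    """Mean and SEM (n-1 sample SD over sqrt(n)) of per-heart values —
    the study-level aggregation row."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InvalidParameterError("summarize_group requires at least one value")
    return _mean_sem(arr)


def compare_sides(
    left_means: Sequence[float],
    right_means: Sequence[float],
    variant: str = "pooled",
) -> SideComparison:
    """Two-tailed Student's t-test of left vs right per-heart means.

    ``variant`` is one of ``"pooled"`` (classic equal-variance two-sample
    test, the reported default), ``"welch"``, or ``"paired"``.
    """
    left = np.asarray(left_means, dtype=float)
    right = np.asarray(right_means, dtype=float)
    if left.size < 2 or right.size < 2:
        raise InvalidParameterError("compare_sides requires >= 2 values per group")
    if variant == "pooled":
        res = stats.ttest_ind(left, right, equal_var=True)
        df = float(left.size + right.size - 2)
    elif variant == "welch":
        res = stats.ttest_ind(left, right, equal_var=False)
        df = float(res.df)
    elif variant == "paired":
        if left.size != right.size:
            raise InvalidParameterError("paired comparison requires equal group sizes")
        res = stats.ttest_rel(left, right)
        df = float(left.size - 1)
    else:
        raise InvalidParameterError(f"unknown t-test variant: {variant!r}")
    ml, sl = _mean_sem(left)
    mr, sr = _mean_sem(right)
    return SideComparison(
        mean_left=ml, mean_right=mr, sem_left=sl, sem_right=sr,
        t_statistic=float(res.statistic), degrees_of_freedom=df,
        p_value=float(res.pvalue), variant=variant,
    )
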