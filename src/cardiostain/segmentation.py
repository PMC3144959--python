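"""Stain segmentation by k-means clustering in CIE L*a*b* color space.

A section image is converted to L*a*b* (sRGB, D65 white), its pixels are
clustered with squared-Euclidean k-means (K initialized at 6), and the
stain mask is the cluster whose centroid lies closest to a configured
stain reference color, guarded by a blue-chromaticity test (centroid
b* < 0).  An automatic, deterministic K tuner stands in for interactive
adjustment of the cluster count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab
from sklearn.cluster import KMeans

from .errors import DegenerateInputError, FormatError, InvalidParameterError
from .phantom import DEFAULT_STAIN_COLOR
from .slices import ColorSlice

__all__ = [
    "LabSlice",
    "ClusterModel",
    "StainMask",
    "DEFAULT_K",
    "default_stain_reference",
    "rgb_to_lab",
    "cluster_colors",
    "select_stain_cluster",
    "segment_slice",
    "tune_k",
    "jaccard",
]

log = logging.getLogger(__name__)

DEFAULT_K = 6


@dataclass
class LabSlice:
    """(L*, a*, b*) pixel array with provenance to its source slice."""

    pixels: np.ndarray  # (H, W, 3) float
    order_index: int = 0

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError("LabSlice.pixels must be (H, W, 3)")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]

    def flat(self) -> np.ndarray:
        return self.pixels.reshape(-1, 3)


@dataclass
class ClusterModel:
    """Fitted k-means model over the L*a*b* pixels of one slice."""

    K: int
    centroids: np.ndarray  # (K, 3)
    labels: np.ndarray  # (H, W) int
    inertia: float
    seed: int

    def mask_for(self, cluster: int) -> np.ndarray:
        return self.labels == cluster


@dataclass
class StainMask:
    """Binary stain-positive map plus the clustering evidence behind it."""

    mask: np.ndarray  # (H, W) bool
    selected_cluster: int | None
    model: ClusterModel | None
    flagged_no_stain: bool = False
    trace: list = field(default_factory=list)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def positive_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def shape(self) -> tuple:
        return self.mask.shape


def default_stain_reference(stain_rgb=DEFAULT_STAIN_COLOR) -> np.ndarray:
    """L*a*b* coordinates of the nominal stain color."""
    rgb = np.array(stain_rgb, dtype=np.uint8).reshape(1, 1, 3)
    return rgb2lab(rgb).reshape(3).astype(float)


def rgb_to_lab(slice_: ColorSlice) -> LabSlice:
    """sRGB (8-bit) to CIE L*a*b* under the D65 reference white."""
    px = slice_.pixels
    if px.ndim != 3 or px.shape[2] != 3:
        raise FormatError("expected an (H, W, 3) RGB image")
    return LabSlice(pixels=rgb2lab(px), order_index=slice_.order_index)


def cluster_colors(
    lab: LabSlice,
    K: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = 10,
    sample_size: int | None = None,
) -> ClusterModel:
    """Lloyd's k-means (squared Euclidean distance) on the L*a*b* pixels.

    Best of ``n_restarts`` k-means++ initializations by inertia;
    deterministic given ``seed``.  With ``sample_size`` set, centroids are
    fitted on a seeded pixel subsample and all pixels are then assigned to
    their nearest centroid (inertia is recomputed over all pixels).
    """
    if K < 2:
        raise InvalidParameterError("K must be >= 2")
    X = lab.flat()
    distinct = np.unique(X, axis=0)
    if distinct.shape[0] < K:
        raise DegenerateInputError(
            f"image has {distinct.shape[0]} distinct colors, fewer than K={K}"
        )
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    if sample_size is not None and X.shape[0] > sample_size:
        idx = np.random.default_rng(seed).choice(X.shape[0], size=sample_size, replace=False)
        km.fit(X[idx])
        labels = km.predict(X)
        d2 = np.sum((X - km.cluster_centers_[labels]) ** 2, axis=1)
        inertia = float(d2.sum())
    else:
        labels = km.fit_predict(X)
        inertia = float(km.inertia_)
    return ClusterModel(
        K=K,
        centroids=km.cluster_centers_.copy(),
        labels=labels.reshape(lab.shape),
        inertia=inertia,
        seed=seed,
    )


def select_stain_cluster(model: ClusterModel, stain_reference) -> StainMask:
    """Pick the cluster closest (squared Euclidean) to the stain reference.

    Only blue-shifted clusters (centroid b* < 0) are eligible.  If no
    cluster passes the guard the slide is treated as stain-free: an
    all-false mask flagged ``flagged_no_stain`` is returned, not an error.
    """
    ref = np.asarray(stain_reference, dtype=float).reshape(3)
    d2 = np.sum((model.centroids - ref) ** 2, axis=1)
    eligible = model.centroids[:, 2] < 0.0
    if not np.any(eligible):
        log.info("no cluster passed the blue-chromaticity guard (all centroid b* >= 0)")
        return StainMask(
            mask=np.zeros_like(model.labels, dtype=bool),
            selected_cluster=None,
            model=model,
            flagged_no_stain=True,
        )
    d2 = np.where(eligible, d2, np.inf)
    best = int(np.argmin(d2))
    return StainMask(mask=model.mask_for(best), selected_cluster=best, model=model)


def segment_slice(
    slice_: ColorSlice,
    K: int = DEFAULT_K,
    stain_reference=None,
    seed: int = 0,
    n_restarts: int = 10,
    sample_size: int | None = None,
) -> StainMask:
    """Convenience: rgb_to_lab -> cluster_colors -> select_stain_cluster."""
    if stain_reference is None:
        stain_reference = default_stain_reference()
    lab = rgb_to_lab(slice_)
    model = cluster_colors(lab, K=K, seed=seed, n_restarts=n_restarts, sample_size=sample_size)
    return select_stain_cluster(model, stain_reference)


def _symdiff_rate(a: np.ndarray, b: np.ndarray) -> float:
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a ^ b)) / union


def tune_k(
    lab: LabSlice,
    stain_reference=None,
    k_min: int = 2,
    k_max: int = 8,
    seed: int = 0,
    n_restarts: int = 10,
    stability_weight: float = 0.5,
    sample_size: int | None = None,
) -> StainMask:
    """Deterministic stand-in for interactive K adjustment.

    Fits models for every K in ``[k_min, k_max]`` and scores each candidate
    stain mask by the mean L*a*b* distance of its pixels to the stain
    reference (scaled by 1/100) plus ``stability_weight`` times the
    symmetric-difference rate between the masks at K and its neighbor K+1
    (K-1 at the top of the range).  The lowest score wins; ties go to the
    K nearest 6.  The candidate trace is attached to the result and logged.
    """
    if not (2 <= k_min <= DEFAULT_K <= k_max):
        raise InvalidParameterError("require 2 <= k_min <= 6 <= k_max")
    if stain_reference is None:
        stain_reference = default_stain_reference()
    ref = np.asarray(stain_reference, dtype=float).reshape(3)
    ks = list(range(k_min, k_max + 1))
    candidates: dict[int, StainMask] = {}
    for k in ks:
        model = cluster_colors(lab, K=k, seed=seed, n_restarts=n_restarts,
                               sample_size=sample_size)
        candidates[k] = select_stain_cluster(model, ref)
    X = lab.flat()
    trace = []
    scored = []
    for k in ks:
        cand = candidates[k]
        if cand.flagged_no_stain or cand.positive_count == 0:
            trace.append({"K": k, "score": None, "flagged": True})
            continue
        mean_dist = float(
            np.mean(np.linalg.norm(X[cand.mask.ravel()] - ref, axis=1))
        )
        neighbor = k + 1 if k + 1 in candidates else k - 1
        penalty = _symdiff_rate(cand.mask, candidates[neighbor].mask)
        score = mean_dist / 100.0 + stability_weight * penalty
        trace.append({"K": k, "mean_dist": mean_dist, "stability_penalty": penalty,
                      "score": score, "flagged": False})
        scored.append((score, abs(k - DEFAULT_K), k))
    if not scored:
        log.info("tune_k: stain absent at every K in [%d, %d]", k_min, k_max)
        empty = candidates[DEFAULT_K]
        empty.trace = trace
        empty.flagged_no_stain = True
        return empty
    best_score = min(s for s, _, _ in scored)
    # tie region: scores within 1e-9 of the best; break toward K = 6
    in_tie = [(d6, k) for s, d6, k in scored if s - best_score <= 1e-9]
    _, best_k = min(in_tie)
    log.info("tune_k: selected K=%d (score=%.6f); trace=%s", best_k, best_score, trace)
    chosen = candidates[best_k]
    chosen.trace = trace
    return chosen


def jaccard(a, b) -> float:
    """Jaccard overlap of two binary masks (1.0 when both are empty)."""
    a = np.asarray(getattr(a, "mask", a), dtype=bool)
    b = np.asarray(getattr(b, "mask", b), dtype=bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b) / union)
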