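"""In-plane rigid transforms (translation + rotation about the image center).

Conventions
-----------
Array coordinates are ``(row, col)`` = ``(y, x)`` with y increasing downward.
A :class:`RigidTransform` maps a point ``p`` of the *moving* image to

    q = R(theta) @ (p - c) + c + (ty, tx)

where ``c`` is the image center ``((H-1)/2, (W-1)/2)`` and ``R`` is the
rotation matrix ``[[cos, -sin], [sin, cos]]`` acting on ``(y, x)`` vectors.
``apply_rigid`` resamples the image so that ``out[q] = in[p]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError

__all__ = ["RigidTransform", "apply_rigid"]


@dataclass(frozen=True)
class RigidTransform:
    """Translation (``tx`` right, ``ty`` down, pixels) plus rotation
    ``theta`` (radians, about the image center)."""

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.tx, self.ty, self.theta)):
            raise InvalidParameterError("rigid transform parameters must be finite")

    @property
    def is_identity(self) -> bool:
        return self.tx == 0.0 and self.ty == 0.0 and self.theta == 0.0

    def rotation_matrix(self) -> np.ndarray:
        """2x2 rotation acting on (y, x) vectors."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def then(self, other: "RigidTransform") -> "RigidTransform":
        """Composition: apply ``self`` first, then ``other``."""
        r2 = other.rotation_matrix()
        t1 = np.array([self.ty, self.tx])
        t2 = np.array([other.ty, other.tx])
        t = r2 @ t1 + t2
        return RigidTransform(tx=float(t[1]), ty=float(t[0]), theta=self.theta + other.theta)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation_matrix().T
        t = -rt @ np.array([self.ty, self.tx])
        return RigidTransform(tx=float(t[1]), ty=float(t[0]), theta=-self.theta)

    def apply_points(self, points: np.ndarray, height: int, width: int) -> np.ndarray:
        """Map an ``(N, 2)`` array of ``(y, x)`` points forward."""
        pts = np.asarray(points, dtype=float)
        c = np.array([(height - 1) / 2.0, (width - 1) / 2.0])
        return (pts - c) @ self.rotation_matrix().T + c + np.array([self.ty, self.tx])

    def to_dict(self) -> dict:
        return {"tx": self.tx, "ty": self.ty, "theta": self.theta}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(tx=float(d["tx"]), ty=float(d["ty"]), theta=float(d["theta"]))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(0.0, 0.0, 0.0)


def apply_rigid(
    image: np.ndarray,
    transform: RigidTransform,
    *,
    order: int = 0,
    cval: float | tuple = 0,
) -> np.ndarray:
    """Resample ``image`` under ``transform`` (output size = input size).

    ``order=0`` (nearest-neighbor) is the default so binary masks stay
    binary.  ``cval`` may be a tuple for multi-channel images (one fill
    value per channel).
    """
    img = np.asarray(image)
    if img.ndim not in (2, 3):
        raise InvalidParameterError("expected a 2D or HxWxC image array")
    if img.dtype == bool:
        return apply_rigid(
            img.astype(np.uint8), transform, order=order, cval=cval
        ).astype(bool)
    h, w = img.shape[:2]
    if transform.is_identity:
        return img.copy()
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    t = np.array([transform.ty, transform.tx])
    rt = transform.rotation_matrix().T  # inverse rotation
    offset = c - rt @ (c + t)

    def _one(channel: np.ndarray, fill) -> np.ndarray:
        return ndimage.affine_transform(
            channel, rt, offset=offset, order=order, mode="constant", cval=fill,
            output=channel.dtype,
        )

    if img.ndim == 2:
        return _one(img, cval if np.isscalar(cval) else cval[0])
    cvals = cval if not np.isscalar(cval) else (cval,) * img.shape[2]
    out = np.empty_like(img)
    for k in range(img.shape[2]):
        out[..., k] = _one(img[..., k], cvals[k])
    return out
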