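"""In-plane rigid transforms for serial-section alignment.

A :class:`RigidTransform2D` maps a point ``p = (x, y)`` (pixel units,
x = column, y = row, origin at the top-left pixel *center*) to

    p' = R(theta) @ (p - c) + c + t

where ``c`` is the rotation center (by default the image center),
``t = (tx, ty)`` is a translation in pixels and ``theta`` is the rotation
angle in degrees, counter-clockwise. Because rotation is always taken about
the same center, composition and inversion have center-free closed forms:
only the translation picks up a rotation factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class RigidTransform2D:
    """Rigid in-plane motion: translation (px) plus rotation (degrees CCW)."""

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0

    def rotation_matrix(self) -> np.ndarray:
        """2x2 rotation matrix acting on (x, y) column vectors."""
        a = math.radians(self.theta)
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, -s], [s, c]])

    def apply_to_points(self, points, center=(0.0, 0.0)) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(center, dtype=float)
        t = np.array([self.tx, self.ty])
        return (pts - c) @ self.rotation_matrix().T + c + t

    def inverse(self) -> "RigidTransform2D":
        """Exact inverse: ``compose(T, T.inverse())`` is the identity."""
        a = math.radians(self.theta)
        c, s = math.cos(a), math.sin(a)
        # -R(-theta) @ t
        tx = -(c * self.tx + s * self.ty)
        ty = -(-s * self.tx + c * self.ty)
        return RigidTransform2D(tx, ty, -self.theta)

    def is_identity(self, tol: float = 0.0) -> bool:
        return (
            abs(self.tx) <= tol and abs(self.ty) <= tol and abs(self.theta) <= tol
        )

    def as_dict(self) -> dict:
        return {"tx": self.tx, "ty": self.ty, "theta": self.theta}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform2D":
        return cls(float(d["tx"]), float(d["ty"]), float(d["theta"]))


def identity() -> RigidTransform2D:
    return RigidTransform2D(0.0, 0.0, 0.0)


def compose(a: RigidTransform2D, b: RigidTransform2D) -> RigidTransform2D:
    """Transform mapping p -> a(b(p)).

    theta adds; the inner translation is rotated by the outer rotation:
    ``t = R(theta_a) @ t_b + t_a``.
    """
    tb = a.rotation_matrix() @ np.array([b.tx, b.ty])
    return RigidTransform2D(
        float(tb[0] + a.tx), float(tb[1] + a.ty), a.theta + b.theta
    )


def _image_center(shape) -> tuple[float, float]:
    h, w = shape[-2], shape[-1]
    return ((w - 1) / 2.0, (h - 1) / 2.0)


def warp_image(
    image: np.ndarray,
    transform: RigidTransform2D,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``image`` under ``transform``: output(p) = image(T^-1(p)).

    Rotation is about the image center; interpolation is bilinear by default
    with out-of-bounds pixels filled with ``cval``. Accepts a single 2-D
    plane or a (C, Y, X) channel stack (each channel warped identically).
    Output is float64 regardless of input dtype; quantization is the
    caller's responsibility so that resampling is only ever applied once.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        return np.stack(
            [warp_image(ch, transform, order=order, cval=cval) for ch in img]
        )
    if img.ndim != 2:
        raise ValueError(f"expected 2-D or (C, Y, X) image, got shape {img.shape}")
    if transform.is_identity():
        return img.astype(float)
    cx, cy = _image_center(img.shape)
    a = math.radians(transform.theta)
    c, s = math.cos(a), math.sin(a)
    # Inverse map in (row, col) = (y, x) index order for affine_transform:
    # (x_in, y_in) = R(-theta) @ (x - cx - tx, y - cy - ty) + (cx, cy)
    matrix = np.array([[c, -s], [s, c]])  # rows: y_in, x_in; cols: y, x
    ox = cx + transform.tx
    oy = cy + transform.ty
    offset = np.array(
        [cy - (-s) * ox - c * oy, cx - c * ox - s * oy]
    )
    return ndimage.affine_transform(
        img.astype(float), matrix, offset=offset, order=order, cval=cval,
        mode="constant",
    )
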