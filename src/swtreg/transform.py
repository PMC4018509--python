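"""2D rigid transforms (dx, dy, theta) and image resampling under them.

Conventions (fixed package-wide): ``x`` runs along columns, ``y`` along
rows; ``theta`` is in **degrees**, counter-clockwise in the (x, y) plane;
rotation is about the image center ``((M-1)/2, (N-1)/2)`` unless a center
is given.  Translations are in pixels internally; callers working in mm
convert through the image spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import Image2D

__all__ = ["RigidTransform", "apply_rigid", "compose", "invert"]


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion: translate by (dx, dy) after rotating by theta about ``center``.

    A point ``p = (x, y)`` maps to ``R(theta) (p - c) + c + (dx, dy)``.
    """

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0  # degrees, CCW
    center: tuple[float, float] | None = None  # (row, col); None = image center

    def matrix(self, shape: tuple[int, int]) -> np.ndarray:
        """Homogeneous 3x3 matrix acting on (x, y, 1) column vectors."""
        cy, cx = self._center(shape)
        a = np.deg2rad(self.theta)
        c, s = np.cos(a), np.sin(a)
        R = np.array([[c, -s], [s, c]])
        t = np.array([self.dx, self.dy]) + np.array([cx, cy]) - R @ np.array([cx, cy])
        out = np.eye(3)
        out[:2, :2] = R
        out[:2, 2] = t
        return out

    def _center(self, shape: tuple[int, int]) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.theta)

    def to_json(self) -> dict:
        return {"dx": self.dx, "dy": self.dy, "theta_deg": self.theta}


def _wrap_angle(theta: float) -> float:
    return (theta + 180.0) % 360.0 - 180.0


def compose(t1: RigidTransform, t2: RigidTransform, shape=None) -> RigidTransform:
    """The transform applying ``t2`` first, then ``t1`` (same center)."""
    if t1.center != t2.center:
        raise ValueError("can only compose transforms sharing a rotation center")
    shape = shape or (1, 1)
    m = t1.matrix(shape) @ t2.matrix(shape)
    return _from_matrix(m, t1._center(shape), t1.center)


def invert(t: RigidTransform, shape=None) -> RigidTransform:
    """Parameters of the inverse motion (about the same center)."""
    shape = shape or (1, 1)
    m = np.linalg.inv(t.matrix(shape))
    return _from_matrix(m, t._center(shape), t.center)


def _from_matrix(m: np.ndarray, center_rc, center_field) -> RigidTransform:
    theta = np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
    cy, cx = center_rc
    cvec = np.array([cx, cy])
    t = m[:2, 2] - cvec + m[:2, :2] @ cvec
    return RigidTransform(float(t[0]), float(t[1]), _wrap_angle(float(theta)), center_field)


def apply_rigid(
    img,
    t: RigidTransform,
    interpolation: str = "bilinear",
    pad_value: float | None = None,
):
    """Resample an image under a rigid transform (pull-back).

    The output grid equals the input grid; each output pixel is sampled
    from the input at the inverse-mapped position, so exactly one
    interpolation happens per pixel.  Out-of-bounds samples take
    ``pad_value`` (default: the input minimum, an air-like background).
    Passing ``pad_value=nan`` marks invalid samples for masking.
    """
    arr = img.pixels if isinstance(img, Image2D) else np.asarray(img, dtype=np.float64)
    if interpolation not in ("nearest", "bilinear"):
        raise ValueError(f"interpolation must be 'nearest' or 'bilinear', got {interpolation!r}")
    if pad_value is None:
        pad_value = float(arr.min())
    m_inv = np.linalg.inv(t.matrix(arr.shape))
    # ndimage indexes (row, col) = (y, x): permute the (x, y) matrix.
    A = np.array([[m_inv[1, 1], m_inv[1, 0]], [m_inv[0, 1], m_inv[0, 0]]])
    b = np.array([m_inv[1, 2], m_inv[0, 2]])
    # Snap float residue: ndimage treats a coordinate even 1e-16 past the
    # last index as out-of-bounds, which would corrupt border pixels for
    # exact identities, full turns and integer shifts.
    A[np.abs(A) < 1e-12] = 0.0
    A[np.abs(A - 1.0) < 1e-12] = 1.0
    b[np.abs(b - np.rint(b)) < 1e-9] = np.rint(b[np.abs(b - np.rint(b)) < 1e-9])
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.affine_transform(
        arr, A, offset=b, order=order, mode="constant", cval=pad_value
    )
    # Image2D forbids NaN; with pad_value=nan the caller wants the raw array.
    if isinstance(img, Image2D) and np.all(np.isfinite(out)):
        return img.with_pixels(out)
    return out
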