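"""Nematic orientation fields from the intensity gradient of a 2D image.

The membrane layers in an electron micrograph appear as elongated
high-contrast structures; their local direction is perpendicular to the image
intensity gradient.  Orientations are *directors*: angles in ``[0, pi)``,
invariant under a 180-degree rotation.  The gradient magnitude is kept as a
per-pixel weight so that downstream tensor sums automatically discount flat
regions; a zero-magnitude pixel has no defined orientation and carries a NaN
sentinel that every weighted sum ignores.

Conventions
-----------
Arrays are indexed ``[row (y), column (x)]`` with y increasing downward.
``theta`` is measured counter-clockwise from the +x (column) axis applied to
this frame; the director of a gradient ``(gx, gy)`` is the angle of
``(gy, -gx)`` folded into ``[0, pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import correlate

from ..kernels import DERIVATIVE_KERNEL_X, GRADIENT_SUPPORT_RADIUS

#: default TEM sampling: 287.5 pixels per micrometre at 5000x magnification
DEFAULT_PIXEL_SIZE_UM = 1.0 / 287.5


@dataclass
class GrayImage2D:
    """A single-channel 2D image with physical pixel size in micrometres."""

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"expected a single-channel 2D image, got shape {self.pixels.shape}; "
                "multi-channel inputs are rejected, not converted"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class GradientField:
    """Per-pixel derivative responses along x (columns) and y (rows).

    ``valid`` flags pixels whose full 5x5 kernel support lies inside the
    image; no padding is assumed, responses outside ``valid`` are zeroed.
    """

    gx: np.ndarray
    gy: np.ndarray
    valid: np.ndarray


@dataclass
class OrientationField:
    """Director angles ``theta`` in ``[0, pi)`` with magnitude weights ``m``.

    Where ``m == 0`` the director is undefined and ``theta`` is NaN; such
    pixels contribute zero weight to every tensor sum.
    """

    theta: np.ndarray
    m: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=np.float64)
        self.m = np.asarray(self.m, dtype=np.float64)
        if self.theta.shape != self.m.shape:
            raise ValueError("theta and m must have the same shape")
        if np.any(self.m < 0):
            raise ValueError("magnitude weights must be non-negative")
        if self.valid is None:
            self.valid = np.ones(self.theta.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta.shape


def compute_gradient(img: GrayImage2D) -> GradientField:
    """Apply the optimized 5x5 derivative kernels to ``img``.

    Raises ``ValueError`` if the image is smaller than the kernel support.
    """
    r = GRADIENT_SUPPORT_RADIUS
    h, w = img.shape
    if h < 2 * r + 1 or w < 2 * r + 1:
        raise ValueError(
            f"image {h}x{w} smaller than the {2 * r + 1}x{2 * r + 1} kernel support"
        )
    # apply the antisymmetric kernel as (positive half) - (mirrored half):
    # both correlations see identical tap values on constant inputs, so the
    # response to a constant image is exactly zero in floating point
    pos_x = np.where(DERIVATIVE_KERNEL_X > 0, DERIVATIVE_KERNEL_X, 0.0)
    gx = correlate(img.pixels, pos_x, mode="constant") - correlate(
        img.pixels, pos_x[:, ::-1], mode="constant"
    )
    transposed = np.ascontiguousarray(img.pixels.T)
    gy = (
        correlate(transposed, pos_x, mode="constant")
        - correlate(transposed, pos_x[:, ::-1], mode="constant")
    ).T
    valid = np.zeros((h, w), dtype=bool)
    valid[r : h - r, r : w - r] = True
    gx[~valid] = 0.0
    gy[~valid] = 0.0
    return GradientField(gx=gx, gy=gy, valid=valid)


def gradient_to_orientation(grad: GradientField) -> OrientationField:
    """Fold the gradient into a director field perpendicular to it.

    ``m = sqrt(gx**2 + gy**2)``; ``theta`` is the angle of ``(gy, -gx)``
    folded into ``[0, pi)``.  Antipodal gradients map to the same director.
    """
    m = np.hypot(grad.gx, grad.gy)
    theta = np.where(m > 0, np.arctan2(-grad.gx, grad.gy) % np.pi, np.nan)
    return OrientationField(theta=theta, m=m, valid=grad.valid.copy())


def _check_factor(factor: int) -> int:
    if not isinstance(factor, (int, np.integer)) or isinstance(factor, bool):
        raise ValueError(f"downsampling factor must be a positive integer, got {factor!r}")
    if factor < 1:
        raise ValueError(f"downsampling factor must be >= 1, got {factor}")
    return int(factor)


def _blocks(a: np.ndarray, f: int) -> np.ndarray:
    """View ``a`` as (nby, nbx, f, f) blocks, cropping any remainder."""
    h, w = a.shape
    nby, nbx = h // f, w // f
    return a[: nby * f, : nbx * f].reshape(nby, f, nbx, f).swapaxes(1, 2)


def downsample_gray(img: GrayImage2D, factor: int) -> GrayImage2D:
    """Block-mean reduction of the grayscale image; factor 1 is the identity."""
    f = _check_factor(factor)
    if f == 1:
        return replace(img, pixels=img.pixels.copy())
    if min(img.shape) < f:
        raise ValueError(f"image {img.shape} smaller than block factor {f}")
    pixels = _blocks(img.pixels, f).mean(axis=(2, 3))
    return GrayImage2D(pixels=pixels, pixel_size=img.pixel_size * f)


def downsample_orientation(field: OrientationField, factor: int) -> OrientationField:
    """Aggregate ``factor x factor`` super-pixels through their Q-tensor.

    Each super-pixel's director is the dominant angle of the summed tensor;
    its weight is the tensor magnitude ``2*sqrt(qxx**2 + qxy**2)``, i.e. the
    coherency times the summed member weight.  Perfectly cancelling members
    produce ``m = 0`` and an undefined (NaN) director.
    """
    f = _check_factor(factor)
    if f == 1:
        return OrientationField(
            theta=field.theta.copy(), m=field.m.copy(), valid=field.valid.copy()
        )
    if min(field.shape) < f:
        raise ValueError(f"field {field.shape} smaller than block factor {f}")
    defined = field.m > 0
    c2 = np.where(defined, np.cos(2 * np.where(defined, field.theta, 0.0)), 0.0)
    s2 = np.where(defined, np.sin(2 * np.where(defined, field.theta, 0.0)), 0.0)
    qxx = _blocks(0.5 * field.m * c2, f).sum(axis=(2, 3))
    qxy = _blocks(0.5 * field.m * s2, f).sum(axis=(2, 3))
    msum = _blocks(field.m, f).sum(axis=(2, 3))
    m = 2.0 * np.hypot(qxx, qxy)
    # perfect cancellation leaves only rounding noise: treat as undirected
    defined_out = m > 1e-12 * msum
    theta = np.where(defined_out, 0.5 * np.arctan2(qxy, qxx) % np.pi, np.nan)
    valid = _blocks(field.valid, f).any(axis=(2, 3))
    return OrientationField(theta=theta, m=m, valid=valid)
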