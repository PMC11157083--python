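"""Background subtraction and intensity normalization of 3D stacks.

Pipeline order is fixed: top-hat first, then per-stack max normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import grey_opening

#: normalization target: the per-stack maximum is mapped to this value
NORMALIZATION_MAX = 4096.0


@dataclass
class ImageStack3D:
    """A 3D intensity grid (z, y, x) with anisotropic voxel size in micrometres."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D stack, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack contains non-finite values")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive numbers (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def tophat_background(stack: ImageStack3D, radius: int = 3) -> ImageStack3D:
    """White top-hat with a box structuring element of half-width ``radius``.

    Output is ``input - opening(input)``: smooth background is removed while
    structures smaller than the ``(2*radius+1)^3`` box are preserved.  The
    result is pointwise within ``[0, input]``.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    size = 2 * radius + 1
    if min(stack.shape) < size:
        raise ValueError(
            f"stack {stack.shape} smaller than the {size}^3 structuring element"
        )
    opened = grey_opening(stack.voxels, size=(size, size, size), mode="nearest")
    return replace(stack, voxels=np.maximum(stack.voxels - opened, 0.0))


def normalize_max(stack: ImageStack3D) -> ImageStack3D:
    """Scale the stack so its maximum is exactly ``NORMALIZATION_MAX``."""
    peak = float(stack.voxels.max())
    if peak <= 0:
        raise ValueError("cannot normalize a non-positive stack")
    return replace(stack, voxels=stack.voxels * (NORMALIZATION_MAX / peak))


def preprocess(stack: ImageStack3D, radius: int = 3) -> ImageStack3D:
    """Standard pipeline: top-hat background subtraction, then normalization."""
    return normalize_max(tophat_background(stack, radius=radius))
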