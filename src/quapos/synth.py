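"""Synthetic imagery with ground truth for both analysis tracks.

Two generators: layered sinusoidal "membrane" textures for the orientation/
coherency pipeline (with controllable angular disorder: smooth jitter,
patchwork of mutually rotated patches, vesicle clutter) and 3D volumes of
elongated ellipsoidal objects over noisy background for the segmentation
pipeline.  Both are fully deterministic given their seed and return the
generating ground truth alongside the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from .lm.classifier import BACKGROUND, SIGNAL, SparseAnnotation
from .lm.preprocess import ImageStack3D
from .tem.orientation import DEFAULT_PIXEL_SIZE_UM, GrayImage2D


# --------------------------------------------------------------------------
# membrane-like 2D textures


@dataclass
class MembranePatternSpec:
    """Recipe for a striped 2D texture with known per-pixel director.

    ``patch_grid``/``patch_directors_deg`` switch to a patchwork of
    internally aligned patches ("partly stacked"); ``n_vesicles`` adds
    isotropic ring clutter ("chaotic").  ``jitter_deg`` is the standard
    deviation of a smooth random angle field added to the director.
    """

    size: int = 128
    director_deg: float = 0.0
    wavelength: float = 12.0
    amplitude: float = 1.0
    jitter_deg: float = 0.0
    patch_grid: tuple[int, int] | None = None
    patch_directors_deg: tuple[float, ...] | None = None
    n_vesicles: int = 0
    vesicle_amplitude: float = 1.0
    noise_sd: float = 0.0
    offset: float = 0.0
    seed: int = 0
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.wavelength < 4:
            raise ValueError("wavelength must be >= 4 px (band-limited stripes)")
        if self.size < 8:
            raise ValueError("size too small")
        if (self.patch_grid is None) != (self.patch_directors_deg is None):
            raise ValueError("patch_grid and patch_directors_deg go together")
        if self.patch_grid is not None:
            pr, pc = self.patch_grid
            if len(self.patch_directors_deg) != pr * pc:  # type: ignore[arg-type]
                raise ValueError("need one director per patch")


def _stripes(shape, director_deg, wavelength, phase0=0.0):
    """cos grating whose measured director equals ``director_deg``."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    a = np.radians(director_deg)
    k = 2 * np.pi / wavelength
    return np.cos(k * (xx * np.sin(a) - yy * np.cos(a)) + phase0)


def make_membrane_image(spec: MembranePatternSpec) -> tuple[GrayImage2D, np.ndarray]:
    """Render the texture and its ground-truth director map (degrees).

    The truth map is exact for jitter-free and patchwork patterns; under
    smooth jitter it is the generating angle field (the rendered local
    orientation tracks it up to terms of order ``|grad jitter| * radius``).
    Pixels with no defined director (pure vesicle clutter) are NaN.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    img = np.full((n, n), float(spec.offset))
    truth = np.full((n, n), np.nan)

    if spec.patch_grid is not None:
        pr, pc = spec.patch_grid
        dirs = np.asarray(spec.patch_directors_deg, dtype=float).reshape(pr, pc)
        ys = np.linspace(0, n, pr + 1).astype(int)
        xs = np.linspace(0, n, pc + 1).astype(int)
        for i in range(pr):
            for j in range(pc):
                block = (slice(ys[i], ys[i + 1]), slice(xs[j], xs[j + 1]))
                phase0 = rng.uniform(0, 2 * np.pi)
                img[block] += spec.amplitude * _stripes(
                    (ys[i + 1] - ys[i], xs[j + 1] - xs[j]), dirs[i, j], spec.wavelength, phase0
                )
                truth[block] = dirs[i, j] % 180.0
    elif spec.amplitude != 0:
        angle_field = np.full((n, n), float(spec.director_deg))
        if spec.jitter_deg > 0:
            noise = gaussian_filter(rng.standard_normal((n, n)), sigma=spec.wavelength)
            sd = noise.std()
            if sd > 0:
                angle_field = angle_field + noise * (spec.jitter_deg / sd)
        yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
        a = np.radians(angle_field)
        k = 2 * np.pi / spec.wavelength
        img += spec.amplitude * np.cos(k * (xx * np.sin(a) - yy * np.cos(a)))
        truth = angle_field % 180.0

    if spec.n_vesicles > 0:
        yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
        for _ in range(spec.n_vesicles):
            cy, cx = rng.uniform(0, n, size=2)
            radius = rng.uniform(0.5 * spec.wavelength, 1.5 * spec.wavelength)
            width = spec.wavelength / 5.0
            r = np.hypot(yy - cy, xx - cx)
            img += spec.vesicle_amplitude * np.exp(-((r - radius) ** 2) / (2 * width**2))

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    return GrayImage2D(pixels=img, pixel_size=spec.pixel_size), truth


# --------------------------------------------------------------------------
# 3D phantoms of elongated objects


@dataclass
class PosPhantomSpec:
    """Recipe for a 3D volume of disjoint bright ellipsoids over background.

    Semi-axes are in micrometres, elongated along y by construction of the
    defaults.  ``volume_sigma`` scales each object log-normally.  Objects are
    placed by rejection sampling so that their bounding boxes stay at least
    ``min_separation_vox`` voxels apart; an infeasible request raises.
    """

    shape: tuple[int, int, int] = (20, 96, 96)
    voxel_size: tuple[float, float, float] = (1.0, 0.323, 0.323)
    n_objects: int = 10
    semi_axes_um: tuple[float, float, float] = (1.0, 2.4, 1.0)
    volume_sigma: float = 0.0
    intensity: tuple[float, float] = (900.0, 1100.0)
    background: float = 40.0
    background_gradient: float = 0.0
    gaussian_noise_sd: float = 10.0
    poisson_noise: bool = False
    min_separation_vox: int = 2
    seed: int = 0
    max_tries: int = 20000


def make_pos_phantom(
    spec: PosPhantomSpec,
) -> tuple[ImageStack3D, np.ndarray, pd.DataFrame]:
    """Render the phantom, its ground-truth mask, and a per-object table.

    The truth table columns: ``object_id, volume_vox, volume_um3,
    bbox_height_um, centroid_z/y/x (voxels), intensity``.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    vz, vy, vx = spec.voxel_size
    voxel_volume = vz * vy * vx

    # per-object semi-axes in voxel units
    objects = []
    for _ in range(spec.n_objects):
        scale = float(np.exp(rng.normal(0.0, spec.volume_sigma))) ** (1 / 3) if spec.volume_sigma > 0 else 1.0
        az, ay, ax = (
            spec.semi_axes_um[0] * scale / vz,
            spec.semi_axes_um[1] * scale / vy,
            spec.semi_axes_um[2] * scale / vx,
        )
        objects.append((az, ay, ax, rng.uniform(*spec.intensity)))

    placed: list[tuple[float, float, float, float, float, float]] = []
    centers = []
    margin = spec.min_separation_vox
    for az, ay, ax, _ in objects:
        ok = False
        for _ in range(spec.max_tries):
            cz = rng.uniform(az + 1, nz - az - 1)
            cy = rng.uniform(ay + 1, ny - ay - 1)
            cx = rng.uniform(ax + 1, nx - ax - 1)
            clash = False
            for (pz, py, px, bz, by, bx) in placed:
                if (
                    abs(cz - pz) < az + bz + margin
                    and abs(cy - py) < ay + by + margin
                    and abs(cx - px) < ax + bx + margin
                ):
                    clash = True
                    break
            if not clash:
                placed.append((cz, cy, cx, az, ay, ax))
                centers.append((cz, cy, cx))
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place {spec.n_objects} disjoint objects in {spec.shape}"
            )

    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(np.float64)
    volume = np.full(spec.shape, float(spec.background))
    if spec.background_gradient:
        volume += spec.background_gradient * (yy / max(ny - 1, 1))
    mask = np.zeros(spec.shape, dtype=bool)
    rows = []
    for oid, ((cz, cy, cx, az, ay, ax), (_, _, _, amp)) in enumerate(
        zip(placed, objects), start=1
    ):
        inside = (
            ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        ) <= 1.0
        volume[inside] += amp
        mask |= inside
        n_vox = int(inside.sum())
        ys = np.nonzero(inside.any(axis=(0, 2)))[0]
        rows.append(
            {
                "object_id": oid,
                "volume_vox": n_vox,
                "volume_um3": n_vox * voxel_volume,
                "bbox_height_um": (ys[-1] - ys[0] + 1) * vy if len(ys) else 0.0,
                "centroid_z": cz,
                "centroid_y": cy,
                "centroid_x": cx,
                "intensity": amp,
            }
        )

    if spec.poisson_noise:
        volume = rng.poisson(np.clip(volume, 0, None)).astype(np.float64)
    if spec.gaussian_noise_sd > 0:
        volume = volume + rng.normal(0.0, spec.gaussian_noise_sd, size=spec.shape)
    volume = np.clip(volume, 0.0, None)

    stack = ImageStack3D(voxels=volume, voxel_size=spec.voxel_size, channel="synthetic")
    return stack, mask, pd.DataFrame(rows)


def sample_annotations(
    mask: np.ndarray, n_per_class: int = 100, seed: int = 0, image_id: str = ""
) -> SparseAnnotation:
    """Draw a sparse two-class annotation from a ground-truth mask.

    Mimics guided manual annotation: half of the background picks come from
    the shell just outside the objects (where class boundaries live), the
    other half from anywhere in the background.
    """
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool)
    sig = np.argwhere(mask)
    if len(sig) < n_per_class or int((~mask).sum()) < n_per_class:
        raise ValueError("mask too small for the requested annotation count")
    shell = binary_dilation(mask, iterations=2) & ~mask
    bg_all = np.argwhere(~mask & ~shell)
    bg_shell = np.argwhere(shell)
    n_shell = min(n_per_class // 2, len(bg_shell))
    bg_coords = np.concatenate(
        [
            bg_shell[rng.choice(len(bg_shell), size=n_shell, replace=False)]
            if n_shell
            else np.empty((0, 3), dtype=np.intp),
            bg_all[rng.choice(len(bg_all), size=n_per_class - n_shell, replace=False)],
        ]
    )
    coords = np.concatenate(
        [sig[rng.choice(len(sig), size=n_per_class, replace=False)], bg_coords]
    )
    labels = np.concatenate(
        [np.full(n_per_class, SIGNAL), np.full(n_per_class, BACKGROUND)]
    )
    return SparseAnnotation(coords=coords, labels=labels, image_id=image_id)
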