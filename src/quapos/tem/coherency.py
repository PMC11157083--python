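"""Q-tensors, local/global coherency, per-ROI summaries, replicate alignment.

A weighted set of directors ``{(theta_i, m_i)}`` is summarized by the 2x2
symmetric traceless tensor

    Q = sum_i m_i * [[cos^2 t_i - 1/2, cos t_i sin t_i],
                     [cos t_i sin t_i, sin^2 t_i - 1/2]]

fully described by ``(qxx, qxy)``.  Twice its larger eigenvalue,
``2*sqrt(qxx^2 + qxy^2)``, normalized by the total weight, is the scalar
nematic order parameter ("coherency"): 1 for perfectly aligned directors,
0 for balanced perpendicular sets.  It equals ``|sum_i m_i e^{2i t_i}| /
sum_i m_i``.  The dominant direction is the larger-eigenvalue eigenvector,
``atan2(qxy, qxx) / 2`` folded into ``[0, 180)`` degrees.

Local coherency evaluates Q over a sliding ``(2*box_radius+1)^2`` box
(default 25x25); global coherency evaluates one Q over all ROI pixels whose
5x5 gradient support lies inside the ROI.  A query pixel of the local map is
valid only when its box and all underlying gradient supports fit in the ROI,
i.e. when it survives erosion of the ROI by ``box_radius + 2`` pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy.ndimage import binary_erosion, uniform_filter

from ..kernels import GRADIENT_SUPPORT_RADIUS
from .orientation import (
    GrayImage2D,
    OrientationField,
    compute_gradient,
    downsample_gray,
    downsample_orientation,
    gradient_to_orientation,
)

DEFAULT_BOX_RADIUS = 12


@dataclass(frozen=True)
class QTensor:
    """Symmetric traceless 2x2 tensor ``(qxx, qxy)`` with its total weight."""

    qxx: float
    qxy: float
    weight_sum: float

    def __post_init__(self) -> None:
        if self.weight_sum < 0:
            raise ValueError("weight_sum must be non-negative")


class GlobalCoherency(NamedTuple):
    coherency: float
    angle_deg: float
    n_pixels: int


@dataclass
class CoherencyMap:
    """Per-query-pixel local coherency and director over a ROI.

    Values are defined (non-NaN) only on ``valid_mask``; a ROI too small to
    contain any valid query pixel yields an empty (all-False) mask rather
    than an error.
    """

    local_coherency: np.ndarray
    local_angle_deg: np.ndarray
    valid_mask: np.ndarray
    box_radius: int = DEFAULT_BOX_RADIUS

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_valid == 0

    def valid_coherencies(self) -> np.ndarray:
        return self.local_coherency[self.valid_mask]

    def valid_angles_deg(self) -> np.ndarray:
        return self.local_angle_deg[self.valid_mask]


@dataclass
class RoiCoherencySummary:
    roi_id: str
    mean_local_coherency: float
    global_coherency: float
    global_angle_deg: float
    ratio_global_to_local: float
    n_valid_local: int
    n_valid_global: int


@dataclass
class ReplicateAlignment:
    """Coherency of per-ROI global angles within one biological replicate."""

    alignment: float
    dominant_angle_deg: float
    n_rois: int


@dataclass
class RoiDistributions:
    coherency_bin_edges: np.ndarray
    coherency_density: np.ndarray
    angle_bin_edges_deg: np.ndarray
    angle_counts: np.ndarray
    mean_local_coherency: float
    global_coherency: float


def _tensor_terms(theta: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-member (qxx, qxy) summands; zero wherever ``m == 0``."""
    defined = m > 0
    safe_theta = np.where(defined, theta, 0.0)
    if np.any(defined & ~np.isfinite(safe_theta)):
        raise ValueError("finite theta required wherever m > 0")
    qxx = np.where(defined, 0.5 * m * np.cos(2 * safe_theta), 0.0)
    qxy = np.where(defined, 0.5 * m * np.sin(2 * safe_theta), 0.0)
    return qxx, qxy


def q_tensor(theta: np.ndarray, m: np.ndarray) -> QTensor:
    """Sum the Q-tensor over a set of directors with weights ``m``.

    ``theta`` in radians; members with ``m == 0`` contribute nothing (their
    ``theta`` may be NaN).  Raises on an empty member set.
    """
    theta = np.asarray(theta, dtype=np.float64)
    m = np.asarray(m, dtype=np.float64)
    if theta.size == 0:
        raise ValueError("empty neighborhood")
    if np.any(m < 0):
        raise ValueError("weights must be non-negative")
    qxx, qxy = _tensor_terms(theta, m)
    return QTensor(qxx=float(qxx.sum()), qxy=float(qxy.sum()), weight_sum=float(m.sum()))


def coherency(q: QTensor) -> float:
    """Weight-normalized scalar nematic order parameter in ``[0, 1]``."""
    if q.weight_sum <= 0:
        return 0.0
    return min(1.0, 2.0 * float(np.hypot(q.qxx, q.qxy)) / q.weight_sum)


def dominant_angle_deg(q: QTensor) -> float:
    """Director of the larger eigenvector, in degrees ``[0, 180)``.

    Returns NaN for the zero tensor (no defined direction).
    """
    mag = np.hypot(q.qxx, q.qxy)
    # rounding noise from perfect cancellation carries no direction
    if mag == 0.0 or (q.weight_sum > 0 and 2.0 * mag / q.weight_sum < 1e-12):
        return float("nan")
    return float(np.degrees(0.5 * np.arctan2(q.qxy, q.qxx)) % 180.0)


def _erode(mask: np.ndarray, radius: int) -> np.ndarray:
    """Square erosion by ``radius`` pixels; outside the image counts as background."""
    if radius == 0:
        return mask.copy()
    structure = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    return binary_erosion(mask, structure=structure, border_value=0)


def local_coherency_map(
    orientations: OrientationField,
    roi_mask: np.ndarray,
    box_radius: int = DEFAULT_BOX_RADIUS,
) -> CoherencyMap:
    """Sliding-box coherency over every valid query pixel of a ROI.

    The box spans ``(2*box_radius + 1)`` pixels per axis.  Validity requires
    the box plus the 5x5 gradient support of each member to lie inside the
    ROI, i.e. erosion of the ROI by ``box_radius + 2``.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != orientations.shape:
        raise ValueError("roi_mask shape must match the orientation field")
    if box_radius < 1:
        raise ValueError("box_radius must be >= 1")
    size = 2 * box_radius + 1
    qxx_px, qxy_px = _tensor_terms(orientations.theta, orientations.m)
    n_box = float(size * size)
    s_qxx = uniform_filter(qxx_px, size=size, mode="constant") * n_box
    s_qxy = uniform_filter(qxy_px, size=size, mode="constant") * n_box
    s_m = uniform_filter(orientations.m, size=size, mode="constant") * n_box
    mag = 2.0 * np.hypot(s_qxx, s_qxy)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(s_m > 0, np.minimum(1.0, mag / s_m), 0.0)
    angle = np.where(mag > 0, np.degrees(0.5 * np.arctan2(s_qxy, s_qxx)) % 180.0, np.nan)
    valid = _erode(roi_mask, box_radius + GRADIENT_SUPPORT_RADIUS)
    coh = np.where(valid, coh, np.nan)
    angle = np.where(valid, angle, np.nan)
    return CoherencyMap(
        local_coherency=coh, local_angle_deg=angle, valid_mask=valid, box_radius=box_radius
    )


def global_coherency(
    orientations: OrientationField, roi_mask: np.ndarray
) -> GlobalCoherency:
    """One Q-tensor over all ROI pixels with fully contained gradient support."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != orientations.shape:
        raise ValueError("roi_mask shape must match the orientation field")
    region = _erode(roi_mask, GRADIENT_SUPPORT_RADIUS)
    n = int(region.sum())
    if n == 0:
        raise ValueError("ROI empty after erosion by the gradient support radius")
    q = q_tensor(orientations.theta[region], orientations.m[region])
    return GlobalCoherency(coherency=coherency(q), angle_deg=dominant_angle_deg(q), n_pixels=n)


def summarize_roi(
    roi_id: str, cmap: CoherencyMap, glob: GlobalCoherency
) -> RoiCoherencySummary:
    """Combine the local map and the global tensor of one ROI.

    ``mean_local_coherency`` is the unweighted mean over valid query pixels;
    the ratio ``global / mean local`` is NaN when no valid local pixel exists
    or the mean local coherency is zero.
    """
    if cmap.is_empty:
        mean_local = float("nan")
    else:
        mean_local = float(cmap.valid_coherencies().mean())
    if mean_local > 0:
        ratio = glob.coherency / mean_local
    else:
        ratio = float("nan")
    return RoiCoherencySummary(
        roi_id=roi_id,
        mean_local_coherency=mean_local,
        global_coherency=glob.coherency,
        global_angle_deg=glob.angle_deg,
        ratio_global_to_local=ratio,
        n_valid_local=cmap.n_valid,
        n_valid_global=glob.n_pixels,
    )


def replicate_alignment(global_angles_deg: Sequence[float]) -> ReplicateAlignment:
    """Unit-weight Q-tensor over a replicate's per-ROI global angles.

    Respects the 180-degree periodicity of directors: alignment is 1 iff all
    angles coincide mod 180.
    """
    angles = np.asarray(global_angles_deg, dtype=np.float64)
    if angles.size == 0:
        raise ValueError("at least one angle is required")
    q = q_tensor(np.radians(angles), np.ones_like(angles))
    return ReplicateAlignment(
        alignment=coherency(q),
        dominant_angle_deg=dominant_angle_deg(q),
        n_rois=int(angles.size),
    )


def roi_distributions(
    cmap: CoherencyMap,
    glob: GlobalCoherency,
    coherency_bins: int = 25,
    angle_bins: int = 18,
) -> RoiDistributions:
    """Histogram the local coherencies and directors of one ROI.

    The angle histogram covers ``[0, 180)`` degrees (counts per bin); its
    duplication to ``[180, 360)`` is a rendering concern only.
    """
    if cmap.is_empty:
        raise ValueError("empty coherency map")
    coh = cmap.valid_coherencies()
    density, coh_edges = np.histogram(coh, bins=coherency_bins, range=(0.0, 1.0), density=True)
    angles = cmap.valid_angles_deg()
    counts, ang_edges = np.histogram(angles[np.isfinite(angles)], bins=angle_bins, range=(0.0, 180.0))
    return RoiDistributions(
        coherency_bin_edges=coh_edges,
        coherency_density=density,
        angle_bin_edges_deg=ang_edges,
        angle_counts=counts,
        mean_local_coherency=float(coh.mean()),
        global_coherency=glob.coherency,
    )


def analyze_image(
    img: GrayImage2D,
    roi_masks: Mapping[str, np.ndarray],
    box_radius: int = DEFAULT_BOX_RADIUS,
    downsample_gray_factor: int = 1,
    downsample_orientation_factor: int = 1,
) -> tuple[list[RoiCoherencySummary], dict[str, CoherencyMap]]:
    """Run the full orientation/coherency pipeline for every ROI of an image.

    ROIs are passed as boolean masks at the resolution of ``img``; when
    downsampling is requested the masks are reduced conservatively (a
    super-pixel belongs to the ROI only if all members do).
    """
    work = downsample_gray(img, downsample_gray_factor)
    field = gradient_to_orientation(compute_gradient(work))
    field = downsample_orientation(field, downsample_orientation_factor)
    f = downsample_gray_factor * downsample_orientation_factor

    summaries: list[RoiCoherencySummary] = []
    maps: dict[str, CoherencyMap] = {}
    for roi_id, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError(f"ROI {roi_id!r} mask shape {mask.shape} != image {img.shape}")
        if f > 1:
            h, w = mask.shape
            nby, nbx = h // f, w // f
            mask = (
                mask[: nby * f, : nbx * f].reshape(nby, f, nbx, f).all(axis=(1, 3))
            )
            mask = mask[: field.shape[0], : field.shape[1]]
        cmap = local_coherency_map(field, mask, box_radius=box_radius)
        glob = global_coherency(field, mask)
        summaries.append(summarize_roi(roi_id, cmap, glob))
        maps[roi_id] = cmap
    return summaries, maps
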