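"""Sphere-based ROI definition on statistic maps.

Four-step procedure: (1) find group-level peaks of the thresholded
training-difference map and surround each with a 15 mm sphere; (2) find
each subject's own peak inside that sphere; (3) grow a 10 mm sphere
around the subject peak; (4) intersect with the brain mask (on the
synthetic common grid the native-space back-mapping step is the
identity, but the operation boundary is kept).  Distances are Euclidean
in world millimetres via the image affine; sphere membership uses
``distance <= radius`` inclusively; peak ties are broken by the smallest
linear (C-order) voxel index for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["RoiSpec", "group_peaks", "subject_peak", "sphere_roi"]

FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)

GROUP_RADIUS_MM = 15.0
SUBJECT_RADIUS_MM = 10.0


def voxel_to_mm(index: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """World coordinates of voxel indices ((..., 3) -> (..., 3) mm)."""
    idx = np.asarray(index, dtype=float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


@dataclass
class RoiSpec:
    """One subject's sphere ROI with its provenance."""

    subject: str
    group_center: tuple[int, int, int]
    group_radius_mm: float
    subject_center: tuple[int, int, int]
    subject_radius_mm: float
    member_voxels: np.ndarray  # (n, 3) int indices, sorted by linear index

    @property
    def size(self) -> int:
        return self.member_voxels.shape[0]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[tuple(self.member_voxels.T)] = True
        return out


def _masked_argmax(values: np.ndarray, admissible: np.ndarray) -> tuple[int, ...]:
    """Index of the maximum over ``admissible``; ties -> lowest linear index."""
    flat = np.where(admissible.ravel(), values.ravel(), -np.inf)
    return tuple(int(i) for i in np.unravel_index(int(np.argmax(flat)), values.shape))


def group_peaks(
    stat_map: np.ndarray,
    mask: np.ndarray,
    stat_threshold: float,
    k_min: int = 10,
    two_sided: bool = True,
) -> list[tuple[int, int, int]]:
    """Peak voxel of every surviving cluster of a thresholded map.

    Voxels with ``|t| > stat_threshold`` (or ``t >`` if one-sided) inside
    the mask are clustered by face connectivity; clusters smaller than
    ``k_min`` are dropped; each cluster contributes its max-``|t|`` voxel.
    Peaks are returned sorted by descending cluster size.  Raises when no
    cluster survives.
    """
    score = np.abs(stat_map) if two_sided else stat_map
    supra = (score > stat_threshold) & mask
    labels, n = ndimage.label(supra, structure=FACE_CONNECTIVITY)
    peaks: list[tuple[int, tuple[int, int, int]]] = []
    for lab in range(1, n + 1):
        in_cluster = labels == lab
        size = int(in_cluster.sum())
        if size < k_min:
            continue
        peaks.append((size, _masked_argmax(score, in_cluster)))
    if not peaks:
        raise ValueError("no cluster survives the threshold rules")
    peaks.sort(key=lambda x: -x[0])
    return [p for _, p in peaks]


def _sphere_indices(
    center: tuple[int, int, int],
    radius_mm: float,
    shape: tuple[int, int, int],
    affine: np.ndarray,
) -> np.ndarray:
    """All voxel indices within ``radius_mm`` of the center (mm distance)."""
    c_mm = voxel_to_mm(np.asarray(center), affine)
    # bounding box in voxel units from the affine's column norms
    steps = np.linalg.norm(affine[:3, :3], axis=0)
    lo = np.maximum(0, np.floor(np.asarray(center) - radius_mm / steps)).astype(int)
    hi = np.minimum(
        np.asarray(shape) - 1, np.ceil(np.asarray(center) + radius_mm / steps)
    ).astype(int)
    grids = np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)], indexing="ij")
    cand = np.stack([g.ravel() for g in grids], axis=1)
    dist = np.linalg.norm(voxel_to_mm(cand, affine) - c_mm, axis=1)
    inside = cand[dist <= radius_mm + 1e-9]
    linear = np.ravel_multi_index(tuple(inside.T), shape)
    return inside[np.argsort(linear)]


def subject_peak(
    subject_map: np.ndarray,
    group_center: tuple[int, int, int],
    affine: np.ndarray,
    mask: np.ndarray | None = None,
    radius_mm: float = GROUP_RADIUS_MM,
    two_sided: bool = True,
) -> tuple[int, int, int]:
    """The subject's strongest voxel inside the group sphere (and mask)."""
    if mask is None:
        mask = np.ones(subject_map.shape, dtype=bool)
    sphere = np.zeros(subject_map.shape, dtype=bool)
    idx = _sphere_indices(group_center, radius_mm, subject_map.shape, affine)
    sphere[tuple(idx.T)] = True
    admissible = sphere & mask
    if not admissible.any():
        raise ValueError("group sphere does not intersect the mask")
    score = np.abs(subject_map) if two_sided else subject_map
    return _masked_argmax(score, admissible)


def sphere_roi(
    center: tuple[int, int, int],
    affine: np.ndarray,
    mask: np.ndarray,
    radius_mm: float = SUBJECT_RADIUS_MM,
    subject: str = "",
    group_center: tuple[int, int, int] | None = None,
) -> RoiSpec:
    """10 mm (by default) sphere around a subject peak, clipped to the mask."""
    if not mask[tuple(center)]:
        raise ValueError("sphere center lies outside the brain mask")
    members = _sphere_indices(center, radius_mm, mask.shape, affine)
    keep = mask[tuple(members.T)]
    return RoiSpec(
        subject=subject,
        group_center=tuple(group_center) if group_center else tuple(center),
        group_radius_mm=GROUP_RADIUS_MM,
        subject_center=tuple(center),
        subject_radius_mm=radius_mm,
        member_voxels=members[keep],
    )
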