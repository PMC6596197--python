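"""Fixed-cardinality searchlight mapping of the average LDC.

Instead of fixed-radius spheres, every searchlight contains exactly
``k`` voxels (default 160): for each in-mask center voxel the k nearest
in-mask voxels by world-mm distance are selected (distance ties broken
by linear voxel index) and the realized radius is recorded.  The
four-sequence average crossnobis dissimilarity is computed within each
searchlight — with the noise covariance restricted to the member voxels
— and assigned to the center voxel.  Maps may be smoothed with a 3-D
Gaussian kernel (4 mm FWHM by convention) before group statistics.

A global summary mirrors the whole-cortex view: per subject, a mask of
voxels where any condition's LDC is above zero, and per condition the
mean LDC within that mask plus the above-zero area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .mvpa import NoiseModel, _fold_products, _pair_indices
from .roi import voxel_to_mm

__all__ = [
    "Neighborhood",
    "NeighborhoodSet",
    "LdcMap",
    "build_neighborhoods",
    "searchlight_ldc",
    "smooth_in_mask",
    "global_summary",
]

DEFAULT_K = 160
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Neighborhood:
    center: tuple[int, int, int]
    members: np.ndarray  # indices into the mask voxel list
    radius_mm: float


@dataclass
class NeighborhoodSet:
    """All searchlight neighborhoods over one mask (shared arrays)."""

    voxels: np.ndarray  # (P, 3) in-mask voxel indices, C-order
    members: np.ndarray  # (P, k) indices into ``voxels``
    radii_mm: np.ndarray  # (P,) realized radius per searchlight
    mask_shape: tuple[int, int, int]
    affine: np.ndarray

    def __len__(self) -> int:
        return self.voxels.shape[0]

    def __getitem__(self, i: int) -> Neighborhood:
        return Neighborhood(
            center=tuple(int(v) for v in self.voxels[i]),
            members=self.members[i],
            radius_mm=float(self.radii_mm[i]),
        )

    @property
    def k(self) -> int:
        return self.members.shape[1]

    @property
    def mean_radius_mm(self) -> float:
        return float(self.radii_mm.mean())


def build_neighborhoods(
    mask: np.ndarray, affine: np.ndarray, k: int = DEFAULT_K, chunk: int = 256
) -> NeighborhoodSet:
    """Exact-k nearest-neighbour searchlights for every in-mask voxel.

    Distances are center-to-center world mm; ties are resolved by the
    smaller linear voxel index, making memberships fully deterministic.
    """
    voxels = np.argwhere(mask)  # C-order == ascending linear index
    P = voxels.shape[0]
    if P < k:
        raise ValueError(f"mask has {P} voxels, fewer than k={k}")
    if k < 1:
        raise ValueError("k must be >= 1")
    pos = voxel_to_mm(voxels, affine)
    members = np.empty((P, k), dtype=np.int64)
    radii = np.empty(P)
    idx = np.arange(P)
    for start in range(0, P, chunk):
        stop = min(start + chunk, P)
        d = np.linalg.norm(pos[start:stop, None, :] - pos[None, :, :], axis=-1)
        # lexicographic (distance, index) order makes ties deterministic
        for row, drow in enumerate(d):
            order = np.lexsort((idx, drow))[:k]
            members[start + row] = np.sort(order)
            radii[start + row] = drow[order].max()
    return NeighborhoodSet(
        voxels=voxels,
        members=members,
        radii_mm=radii,
        mask_shape=mask.shape,
        affine=np.asarray(affine, dtype=float),
    )


@dataclass
class LdcMap:
    """Searchlight LDC values assigned to center voxels of one mask."""

    values: np.ndarray  # (P,) aligned with neighborhoods.voxels
    neighborhoods: NeighborhoodSet
    session: str = ""
    condition: str = ""
    fwhm_mm: float = 0.0

    def volume(self, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.neighborhoods.mask_shape, fill)
        out[tuple(self.neighborhoods.voxels.T)] = self.values
        return out


def _batched_whitener(sigmas: np.ndarray) -> np.ndarray:
    """Inverse symmetric square roots of a stack of covariance blocks."""
    vals, vecs = np.linalg.eigh(sigmas)
    if vals.min() <= 0:
        raise np.linalg.LinAlgError("restricted noise block not positive definite")
    return np.einsum("nij,nj,nkj->nik", vecs, 1.0 / np.sqrt(vals), vecs)


def searchlight_ldc(
    patterns: np.ndarray,
    noise: NoiseModel | None,
    neighborhoods: NeighborhoodSet,
    fwhm_mm: float = 0.0,
    session: str = "",
    condition: str = "",
    chunk: int = 128,
) -> LdcMap:
    """Average-LDC map over all searchlights.

    ``patterns``: (4 sequences, R runs, P mask voxels) activation
    estimates in the neighborhood set's voxel order.  The noise model
    (over the same P voxels) is restricted to each searchlight's members
    before prewhitening.  ``fwhm_mm > 0`` smooths the resulting map
    within the mask.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 3 or patterns.shape[0] != 4:
        raise ValueError("expected (4, runs, voxels) patterns")
    P = patterns.shape[2]
    if P != len(neighborhoods):
        raise ValueError("patterns and neighborhoods are on different grids")
    if noise is not None and noise.n_voxels != P:
        raise ValueError("noise model voxel count mismatch")
    pairs = _pair_indices(4)
    k = neighborhoods.k
    values = np.empty(P)
    for start in range(0, P, chunk):
        stop = min(start + chunk, P)
        m = neighborhoods.members[start:stop]  # (n, k)
        local = patterns[:, :, m]  # (4, R, n, k)
        if noise is not None:
            blocks = noise.sigma[m[:, :, None], m[:, None, :]]  # (n, k, k)
            W = _batched_whitener(blocks)
            local = np.einsum("srnk,nkl->srnl", local, W)
        diffs = np.stack([local[j] - local[kk] for j, kk in pairs])  # (6, R, n, k)
        diffs = np.moveaxis(diffs, 2, 1)  # (6, n, R, k)
        folds = _fold_products(diffs)  # (6, n, R)
        values[start:stop] = folds.mean(axis=(0, 2))
    out = LdcMap(values, neighborhoods, session, condition, fwhm_mm=0.0)
    if fwhm_mm > 0:
        mask = np.zeros(neighborhoods.mask_shape, dtype=bool)
        mask[tuple(neighborhoods.voxels.T)] = True
        vol = smooth_in_mask(out.volume(), mask, neighborhoods.affine, fwhm_mm)
        out = LdcMap(
            vol[tuple(neighborhoods.voxels.T)], neighborhoods, session, condition,
            fwhm_mm=fwhm_mm,
        )
    return out


def smooth_in_mask(
    volume: np.ndarray, mask: np.ndarray, affine: np.ndarray, fwhm_mm: float
) -> np.ndarray:
    """Isotropic Gaussian smoothing renormalized inside the mask.

    Values outside the mask are treated as missing (not zero): both the
    masked volume and the mask indicator are smoothed and their ratio
    taken, so edge voxels are not diluted toward zero.
    """
    voxel_sizes = np.linalg.norm(affine[:3, :3], axis=0)
    sigma = (fwhm_mm * FWHM_TO_SIGMA) / voxel_sizes
    num = ndimage.gaussian_filter(np.where(mask, volume, 0.0), sigma)
    den = ndimage.gaussian_filter(mask.astype(float), sigma)
    out = np.zeros_like(num)
    inside = den > 1e-12
    out[inside] = num[inside] / den[inside]
    return np.where(mask, out, 0.0)


def global_summary(maps: dict[str, LdcMap]) -> pd.DataFrame:
    """Per-condition mean LDC and above-zero area over the union mask.

    ``maps`` holds one subject's four condition maps (pre/post x
    trained/untrained).  The union mask collects voxels where *any*
    condition's LDC is above zero; per condition the mean LDC within
    that mask and the area of that condition's own above-zero voxels
    (count x in-plane voxel area, in cm^2) are reported.
    """
    if not maps:
        raise ValueError("no maps supplied")
    stacked = {name: m.values for name, m in maps.items()}
    first = next(iter(maps.values()))
    for m in maps.values():
        if m.values.shape != first.values.shape:
            raise ValueError("maps must share one grid")
    union = np.zeros_like(first.values, dtype=bool)
    for v in stacked.values():
        union |= v > 0
    if not union.any():
        raise ValueError("no voxel is above zero in any condition")
    affine = first.neighborhoods.affine
    voxel_sizes = np.linalg.norm(affine[:3, :3], axis=0)
    area_cm2 = float(voxel_sizes[0] * voxel_sizes[1]) / 100.0  # in-plane mm^2 -> cm^2
    rows = []
    for name, v in stacked.items():
        rows.append(
            {
                "condition": name,
                "mean_ldc": float(v[union].mean()),
                "area_cm2": float((v > 0).sum() * area_cm2),
                "n_above_zero": int((v > 0).sum()),
            }
        )
    return pd.DataFrame(rows)
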