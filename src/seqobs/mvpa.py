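"""Crossnobis engine: noise normalization and cross-validated Mahalanobis
(linear discriminant contrast, LDC) dissimilarities.

The LDC between two conditions is the mean difference of their activity
patterns measured along a noise-normalized linear discriminant estimated
on independent data.  Leave-one-run-out cross-validation makes the
estimator unbiased: under the null of identical patterns its expectation
is exactly zero, so negative values occur and zero is meaningful.

For two sequences with per-run prewhitened pattern difference
``d_r`` (r = 1..R, each of length P), fold ``m`` contributes

    ldc_m = mean_{r != m}(d_r) . d_m / P

and the pair's LDC is the mean over the R folds.  Division by the voxel
count P makes values comparable across ROI / searchlight sizes.  With
four sequences per condition the six pairwise LDCs are averaged into a
single dissimilarity estimate per (condition, session).

Noise normalization uses the voxel-space residual covariance from the
first-level GLM, pooled over runs and shrunk toward its diagonal with an
analytically chosen weight (Ledoit-Wolf-style optimal shrinkage with a
diagonal target), which guarantees a well-conditioned, positive-definite
matrix even when P exceeds the residual degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseModel",
    "BetaPatternSet",
    "DissimilarityEstimate",
    "estimate_noise_cov",
    "whitening_matrix",
    "crossnobis_pair",
    "average_dissimilarity",
    "random_subspace_ldc",
]

logger = logging.getLogger(__name__)

N_PAIRS = 6  # unordered pairs of 4 sequences
SUBSET_SIZE = 160  # voxels per random subspace / searchlight
N_SUBSETS = 1000


@dataclass
class NoiseModel:
    """Shrinkage-regularized voxel covariance used for prewhitening."""

    sigma: np.ndarray  # P x P
    shrinkage_weight: float
    source: str = "pooled run-wise GLM residuals"
    _whitener: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        s = self.sigma
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("sigma must be square")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")

    @property
    def n_voxels(self) -> int:
        return self.sigma.shape[0]

    def whitener(self) -> np.ndarray:
        """Inverse matrix square root ``sigma^(-1/2)`` (symmetric)."""
        if self._whitener is None:
            self._whitener = whitening_matrix(self.sigma)
        return self._whitener

    def restrict(self, voxel_idx: np.ndarray) -> "NoiseModel":
        """Noise model over a voxel subset (sub-block of sigma)."""
        sub = self.sigma[np.ix_(voxel_idx, voxel_idx)]
        return NoiseModel(sub, self.shrinkage_weight, self.source)


def whitening_matrix(sigma: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition."""
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() <= 0:
        raise np.linalg.LinAlgError("noise covariance is not positive definite")
    return (vecs / np.sqrt(vals)) @ vecs.T


def _diagonal_shrinkage_weight(residuals: np.ndarray) -> float:
    """Analytic optimal shrinkage intensity toward the diagonal target.

    Standard large-covariance estimator: lambda* minimizes the expected
    Frobenius loss of ``lam * diag(S) + (1 - lam) * S`` and equals the
    summed sampling variance of the off-diagonal entries of S over their
    summed squared magnitude, clipped to [0, 1].
    """
    T = residuals.shape[0]
    Xc = residuals - residuals.mean(axis=0)
    S = (Xc.T @ Xc) / T
    # sampling variance of each S_ij from the per-sample outer products
    # w_tij = x_ti x_tj:  sum_t (w_tij - S_ij)^2 = sum_t w_tij^2 - T S_ij^2
    sq = Xc**2
    varS = (sq.T @ sq - T * S**2) / (T * (T - 1))
    off = ~np.eye(S.shape[0], dtype=bool)
    denom = float((S[off] ** 2).sum())
    if denom == 0:
        return 1.0
    return float(np.clip(varS[off].sum() / denom, 0.0, 1.0))


def estimate_noise_cov(
    residuals_per_run: list[np.ndarray], shrinkage_weight: float | None = None
) -> NoiseModel:
    """Pool run-wise residual covariances and shrink toward the diagonal.

    Parameters
    ----------
    residuals_per_run
        One T_r x P residual matrix per functional run.
    shrinkage_weight
        Fixed shrinkage intensity in [0, 1]; if None the analytic
        optimal weight is computed from the pooled residuals
        (1 = fully diagonal, 0 = raw sample covariance).
    """
    if not residuals_per_run:
        raise ValueError("no residuals supplied")
    P = residuals_per_run[0].shape[1]
    if P == 0:
        raise ValueError("residuals have zero voxels")
    pooled = np.vstack(residuals_per_run)
    if not np.any(pooled):
        raise ValueError("residuals are identically zero")
    covs = []
    for r in residuals_per_run:
        if r.shape[0] < 2 or r.shape[1] != P:
            raise ValueError("each run needs T > 1 residual rows and equal P")
        rc = r - r.mean(axis=0)
        covs.append((rc.T @ rc) / (r.shape[0] - 1))
    S = np.mean(covs, axis=0)
    lam = (
        _diagonal_shrinkage_weight(pooled)
        if shrinkage_weight is None
        else float(shrinkage_weight)
    )
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage weight must lie in [0, 1]")
    sigma = lam * np.diag(np.diag(S)) + (1.0 - lam) * S
    # guard against degenerate zero-variance voxels
    eps = 1e-10 * max(np.trace(sigma) / P, 1.0)
    sigma[np.diag_indices(P)] += eps
    return NoiseModel(sigma=sigma, shrinkage_weight=lam)


def _fold_products(diffs: np.ndarray) -> np.ndarray:
    """Leave-one-run-out fold values from per-run difference vectors.

    ``diffs``: (..., R, P) whitened per-run differences.  Returns
    (..., R) fold values ``mean_{r != m}(d_r) . d_m / P``.
    """
    R, P = diffs.shape[-2], diffs.shape[-1]
    if R < 2:
        raise ValueError("crossnobis needs at least 2 runs")
    total = diffs.sum(axis=-2, keepdims=True)  # (..., 1, P)
    train_mean = (total - diffs) / (R - 1)  # (..., R, P)
    return np.einsum("...rp,...rp->...r", train_mean, diffs) / P


@dataclass
class DissimilarityEstimate:
    """Pairwise and averaged LDC with fold-level detail."""

    pairwise: np.ndarray  # (6,) pair LDCs, pairs in lexicographic order
    fold_values: np.ndarray  # (6, R)
    pairs: list[tuple[int, int]]
    average: float

    def __post_init__(self) -> None:
        if not np.isclose(self.average, self.pairwise.mean()):
            raise ValueError("average must equal the mean of pairwise LDCs")


def crossnobis_pair(
    patterns_j: np.ndarray,
    patterns_k: np.ndarray,
    noise: NoiseModel | None = None,
    prewhitened: bool = False,
) -> tuple[float, np.ndarray]:
    """Leave-one-run-out crossnobis distance between two sequences.

    Parameters
    ----------
    patterns_j, patterns_k
        R x P per-run activation patterns for the two sequences (same
        runs, same voxels).
    noise
        Noise model whose inverse square root prewhitens the patterns;
        may be omitted when ``prewhitened`` data are passed (equivalent
        to identity noise).

    Returns
    -------
    (ldc, fold_values)
        The fold-averaged LDC (can be negative) and the R per-fold values.
    """
    pj = np.asarray(patterns_j, dtype=float)
    pk = np.asarray(patterns_k, dtype=float)
    if pj.shape != pk.shape:
        raise ValueError("pattern sets must share (runs, voxels) shape")
    diffs = pj - pk
    if not prewhitened and noise is not None:
        if noise.n_voxels != diffs.shape[1]:
            raise ValueError("noise model voxel count mismatch")
        diffs = diffs @ noise.whitener()
    folds = _fold_products(diffs)
    return float(folds.mean()), folds


def _pair_indices(n: int = 4) -> list[tuple[int, int]]:
    return [(j, k) for j in range(n) for k in range(j + 1, n)]


def average_dissimilarity(
    patterns: np.ndarray, noise: NoiseModel | None = None
) -> DissimilarityEstimate:
    """Average LDC between the four sequences of one condition.

    ``patterns``: array (4, R, P) of per-run activation estimates.  The
    six unordered pairwise crossnobis distances are computed and averaged.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 3 or patterns.shape[0] != 4:
        raise ValueError("expected a (4, runs, voxels) pattern array")
    if patterns.shape[2] < 2:
        raise ValueError("need at least 2 voxels")
    if noise is not None:
        if noise.n_voxels != patterns.shape[2]:
            raise ValueError("noise model voxel count mismatch")
        patterns = patterns @ noise.whitener()
    pairs = _pair_indices(4)
    diffs = np.stack([patterns[j] - patterns[k] for j, k in pairs])  # (6, R, P)
    folds = _fold_products(diffs)  # (6, R)
    pairwise = folds.mean(axis=1)
    return DissimilarityEstimate(
        pairwise=pairwise,
        fold_values=folds,
        pairs=pairs,
        average=float(pairwise.mean()),
    )


def random_subspace_ldc(
    roi_patterns: np.ndarray,
    noise: NoiseModel | None,
    n_subsets: int = N_SUBSETS,
    subset_size: int = SUBSET_SIZE,
    seed: int | np.random.Generator = 0,
) -> float:
    """Random-subspace ROI estimator: average LDC over random voxel subsets.

    ``subset_size`` voxels are sampled without replacement ``n_subsets``
    times; the four-sequence average LDC is computed on each subset (with
    the noise model restricted to the subset's voxels) and the subset
    values are averaged.  An ROI smaller than ``subset_size`` falls back
    to the whole-ROI LDC with a logged warning; an ROI of exactly
    ``subset_size`` voxels reduces to the whole-ROI LDC.
    """
    roi_patterns = np.asarray(roi_patterns, dtype=float)
    P = roi_patterns.shape[2]
    if P < subset_size:
        logger.warning(
            "ROI has %d voxels < subset size %d; using whole-ROI LDC", P, subset_size
        )
        return average_dissimilarity(roi_patterns, noise).average
    if P == subset_size:
        return average_dissimilarity(roi_patterns, noise).average
    rng = np.random.default_rng(seed)
    values = np.empty(n_subsets)
    for i in range(n_subsets):
        idx = rng.choice(P, size=subset_size, replace=False)
        sub_noise = noise.restrict(idx) if noise is not None else None
        values[i] = average_dissimilarity(roi_patterns[:, :, idx], sub_noise).average
    return float(values.mean())
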