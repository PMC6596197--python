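"""Inferential layer: intercept-based training effects, one-sample tests,
within-subject confidence intervals, repeated-measures ANOVA, and
permutation-based cluster inference on statistic maps.

The training-effect statistic regresses each subject's post-training
trained-minus-untrained difference (outcome) on the pre-training
difference (predictor); the regression intercept B0 estimates the
post-training difference expected at zero pre-training difference, so
idiosyncratic baseline differences between the condition assignments are
corrected rather than propagated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "TrainingEffect",
    "StatResult",
    "intercept_effect",
    "one_sample_t",
    "ci_multiplier",
    "within_subject_ci",
    "rm_anova",
    "cluster_inference",
    "cohens_dz",
]

logger = logging.getLogger(__name__)

FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


def cohens_dz(values: np.ndarray) -> float:
    """Paired effect size: mean of the differences over their SD."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    return float(values.mean() / sd) if sd > 0 else np.inf * np.sign(values.mean())


@dataclass
class TrainingEffect:
    """Regression-intercept estimate of a pre/post training effect."""

    b0: float
    slope: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    d_z: float
    df: int
    level: str = "across-subjects"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.b0 <= self.ci_high):
            raise ValueError("confidence interval must bracket B0")


def intercept_effect(
    pre_diffs: np.ndarray, post_diffs: np.ndarray, level: str = "across-subjects"
) -> TrainingEffect:
    """OLS of post differences on pre differences; the intercept is the effect.

    Returns B0 with its standard error, t statistic (df = n - 2),
    two-sided p, 95% CI, and d_z computed from the post-training
    difference distribution.  A zero-variance predictor degenerates to
    the plain mean of the outcome (with a logged note, df = n - 1).
    """
    pre = np.asarray(pre_diffs, dtype=float)
    post = np.asarray(post_diffs, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post difference vectors must match")
    n = pre.size
    if n < 3:
        raise ValueError("need at least 3 paired differences")
    d_z = cohens_dz(post)
    if np.ptp(pre) == 0:
        logger.info("zero-variance predictor: intercept falls back to mean(post)")
        b0 = float(post.mean())
        se = float(post.std(ddof=1) / np.sqrt(n))
        df = n - 1
        slope = 0.0
    else:
        res = sps.linregress(pre, post)
        b0, slope = float(res.intercept), float(res.slope)
        se = float(res.intercept_stderr)
        df = n - 2
    crit = sps.t.ppf(0.975, df)
    tval = b0 / se if se > 0 else np.inf * np.sign(b0)
    p = 2.0 * sps.t.sf(abs(tval), df)
    return TrainingEffect(
        b0=b0,
        slope=slope,
        se=se,
        ci_low=b0 - crit * se,
        ci_high=b0 + crit * se,
        t=float(tval),
        p=float(p),
        d_z=d_z,
        df=df,
        level=level,
    )


@dataclass
class StatResult:
    statistic: float
    df: tuple[float, ...]
    p: float
    effect_size: float
    effect_size_label: str = "d_z"
    correction: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def one_sample_t(
    values: np.ndarray, tail: str = "two", m_corrections: int = 1
) -> StatResult:
    """One-sample t test of the mean against zero.

    ``tail="one"`` tests mean > 0.  Bonferroni correction over
    ``m_corrections`` comparisons caps the adjusted p at 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if values.std(ddof=1) == 0:
        raise ValueError("zero variance")
    alternative = {"one": "greater", "two": "two-sided"}[tail]
    res = sps.ttest_1samp(values, 0.0, alternative=alternative)
    p = min(1.0, float(res.pvalue) * m_corrections)
    return StatResult(
        statistic=float(res.statistic),
        df=(float(values.size - 1),),
        p=p,
        effect_size=cohens_dz(values),
        correction="bonferroni" if m_corrections > 1 else "none",
    )


def ci_multiplier(df: int, tails: int = 2) -> float:
    """Critical t value for a 95% confidence interval, rounded to 2 dp.

    Two-tailed df=15 gives 2.13; the one-tailed df=15 quantile is 1.75
    (t_{0.95,15} = 1.7531 — note some reports round this down to 1.74).
    The normal limit for large df is 1.96 two-tailed.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    q = 0.975 if tails == 2 else 0.95
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    return float(np.round(sps.t.ppf(q, df), 2))


def within_subject_ci(data: np.ndarray, tails: int = 2) -> pd.DataFrame:
    """Per-condition within-subject 95% CIs for a subject x condition matrix.

    Between-subject offsets are removed by centering each subject's row
    on the grand mean (Cousineau), and the per-condition variances are
    multiplied by the C/(C-1) bias correction (Morey) before forming
    ``mean +- multiplier * SE``.  With a single condition this reduces to
    the ordinary CI of the mean.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a subject x condition matrix")
    if np.isnan(X).any():
        raise ValueError("missing cells are not allowed")
    n, C = X.shape
    if C > 1:
        centered = X - X.mean(axis=1, keepdims=True) + X.mean()
        sd = centered.std(axis=0, ddof=1) * np.sqrt(C / (C - 1))
    else:  # single condition: ordinary CI of the mean
        sd = X.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    half = ci_multiplier(n - 1, tails) * se
    means = X.mean(axis=0)
    return pd.DataFrame(
        {"mean": means, "ci_low": means - half, "ci_high": means + half}
    )


def rm_anova(data: pd.DataFrame, dv: str, within: list[str], subject: str = "subject") -> pd.DataFrame:
    """Fully-crossed repeated-measures ANOVA with partial eta squared.

    ``data`` is long-format with one row per subject x cell.  Returns a
    table of F, dfs, p and partial eta squared
    (``F * df1 / (F * df1 + df2)``) for every main effect and
    interaction.  Incomplete designs raise.
    """
    cells = data.groupby([subject, *within], observed=True).size()
    if cells.min() < 1 or cells.nunique() != 1:
        raise ValueError("design must be complete and balanced")
    fit = AnovaRM(data, depvar=dv, subject=subject, within=within).fit()
    tab = fit.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df1", "Den DF": "df2", "Pr > F": "p"}
    )
    tab["eta_p2"] = tab["F"] * tab["df1"] / (tab["F"] * tab["df1"] + tab["df2"])
    tab.index.name = "effect"
    return tab.reset_index()


def _t_map(data: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t over subjects (axis 0)."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _max_cluster_size(
    t: np.ndarray, thresh: float, mask: np.ndarray, two_sided: bool
) -> int:
    supra = (np.abs(t) if two_sided else t) > thresh
    supra &= mask
    labels, n = ndimage.label(supra, structure=FACE_CONNECTIVITY)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(np.ones_like(t), labels, range(1, n + 1))))


@dataclass
class Cluster:
    label: int
    size: int
    peak_index: tuple[int, int, int]
    peak_t: float
    p_fwe: float


def cluster_inference(
    stat_maps: np.ndarray,
    mask: np.ndarray | None = None,
    voxel_p: float = 0.001,
    k_min: int = 10,
    fwe_p: float = 0.05,
    n_perm: int = 1000,
    two_sided: bool = True,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, list[Cluster]]:
    """Cluster-extent FWE inference by sign-flip permutation.

    Parameters
    ----------
    stat_maps
        Subject x X x Y x Z array of first-level contrast (or LDC) maps.
    mask
        Boolean analysis mask; default all voxels.
    voxel_p, k_min
        Cluster-forming threshold: voxels with one-sample ``|t|`` (or t,
        if one-sided) exceeding the parametric ``p < voxel_p`` critical
        value, clusters by face connectivity, discarding clusters smaller
        than ``k_min`` voxels.
    fwe_p, n_perm
        Observed cluster extents are referred to the permutation null of
        the maximum cluster size under random sign flips of whole-subject
        maps; clusters with permutation ``p <= fwe_p`` survive.

    Returns the thresholded t map (zero outside surviving clusters) and
    the cluster table.
    """
    maps = np.asarray(stat_maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("stat_maps must be subjects x X x Y x Z")
    n_subj = maps.shape[0]
    if n_subj < 8:
        raise ValueError("need at least 8 subjects")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if mask is None:
        mask = np.ones(maps.shape[1:], dtype=bool)
    rng = np.random.default_rng(seed)

    t_crit = sps.t.ppf(1.0 - (voxel_p / 2 if two_sided else voxel_p), n_subj - 1)
    t_obs = _t_map(maps)
    supra = (np.abs(t_obs) if two_sided else t_obs) > t_crit
    supra &= mask
    labels, n_clusters = ndimage.label(supra, structure=FACE_CONNECTIVITY)
    sizes = (
        ndimage.sum_labels(np.ones_like(t_obs), labels, range(1, n_clusters + 1))
        if n_clusters
        else np.array([])
    )

    keep = [i for i, s in enumerate(sizes, start=1) if s >= k_min]
    if not keep:
        return np.zeros_like(t_obs), []

    null_max = np.empty(n_perm)
    flat = maps.reshape(n_subj, -1)
    for b in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        t_b = _t_map((flat * signs[:, None]).reshape(maps.shape))
        null_max[b] = _max_cluster_size(t_b, t_crit, mask, two_sided)

    clusters: list[Cluster] = []
    out = np.zeros_like(t_obs)
    for lab in keep:
        size = int(sizes[lab - 1])
        p = float((1 + np.sum(null_max >= size)) / (1 + n_perm))
        in_cluster = labels == lab
        peak_flat = np.argmax(np.where(in_cluster, np.abs(t_obs), -np.inf))
        peak_idx = np.unravel_index(peak_flat, t_obs.shape)
        if p <= fwe_p:
            out[in_cluster] = t_obs[in_cluster]
            clusters.append(
                Cluster(lab, size, tuple(int(i) for i in peak_idx),
                        float(t_obs[peak_idx]), p)
            )
    clusters.sort(key=lambda c: -c.size)
    return out, clusters
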