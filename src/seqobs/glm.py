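"""First-level GLM: design matrices, high-pass filtering, OLS / AR(1) fits.

The design matrix is built per functional run from the session schedule.
Two modes are supported:

``univariate6``
    six task regressors — trained videos, untrained videos, the error
    video, question/response events, trained cues, untrained cues — with
    rest as the unmodeled (implicit) baseline.

``mvpa8``
    one regressor per sequence per run covering both 13 s occurrences of
    that sequence's video, plus nuisance regressors (error video,
    questions, cues); used to obtain the per-run, per-sequence activation
    patterns that the crossnobis analysis consumes.

Events are modeled as boxcars convolved with a canonical double-gamma
hemodynamic response (peak 6 s, undershoot 16 s).  Low-frequency drift
is removed by projecting onto the complement of a discrete-cosine basis
with cutoff 1/52 Hz.  Temporal autocorrelation can be handled by AR(1)
prewhitening (GLS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .design import TrialEvent

__all__ = [
    "DesignMatrix",
    "GlmFit",
    "canonical_hrf",
    "build_design",
    "dct_basis",
    "highpass",
    "fit",
    "contrast",
]

UNIVARIATE6_LABELS = [
    "trained_video",
    "untrained_video",
    "error_video",
    "question",
    "trained_cue",
    "untrained_cue",
]

OVERSAMPLING = 16


def canonical_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds.

    ``h(t) = g(t; 6, 1) - g(t; 16, 1) / 6`` with gamma-pdf kernels, the
    standard positive-peak-at-~5-6 s / undershoot-at-~16 s shape,
    normalized to unit peak.
    """
    t = np.arange(0.0, duration, dt)
    # gamma pdf with shape a, scale 1: t^(a-1) e^-t / Gamma(a)
    def gpdf(tt: np.ndarray, a: float) -> np.ndarray:
        out = np.zeros_like(tt)
        pos = tt > 0
        out[pos] = np.exp((a - 1) * np.log(tt[pos]) - tt[pos] - special.gammaln(a))
        return out

    h = gpdf(t, 6.0) - gpdf(t, 16.0) / 6.0
    return h / h.max()


@dataclass
class DesignMatrix:
    """Convolved design for one run plus the pre-convolution boxcars."""

    X: np.ndarray  # T x Q, HRF-convolved
    boxcars: np.ndarray  # T x Q, raw boxcars sampled on the volume grid
    labels: list[str]
    tr: float
    filter_cutoff: float = 1.0 / 52.0

    def __post_init__(self) -> None:
        if np.any(np.all(self.X == 0, axis=0)):
            raise ValueError("design matrix contains an all-zero column")

    @property
    def n_volumes(self) -> int:
        return self.X.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.X[:, self.labels.index(label)]


def _event_columns(
    events: list[TrialEvent], mode: str, trained_ids: set[int]
) -> dict[str, list[tuple[float, float]]]:
    """Map regressor label -> list of (onset, duration) windows."""
    cols: dict[str, list[tuple[float, float]]] = {}

    def add(label: str, e: TrialEvent) -> None:
        cols.setdefault(label, []).append((e.onset, e.duration))

    for e in events:
        if e.label == "rest":
            continue  # implicit baseline
        if mode == "univariate6":
            if e.label == "video":
                add(
                    "trained_video"
                    if e.sequence_id in trained_ids
                    else "untrained_video",
                    e,
                )
            elif e.label == "error_video":
                add("error_video", e)
            elif e.label == "question":
                add("question", e)
            elif e.label == "cue":
                add(
                    "trained_cue" if e.sequence_id in trained_ids else "untrained_cue",
                    e,
                )
        elif mode == "mvpa8":
            if e.label == "video":
                add(f"seq_{e.sequence_id}", e)
            elif e.label == "error_video":
                add("error_video", e)
            elif e.label == "question":
                add("question", e)
            elif e.label == "cue":
                add("cue", e)
        else:
            raise ValueError(f"unknown design mode {mode!r}")
    return cols


def build_design(
    events: list[TrialEvent],
    mode: str,
    tr: float,
    n_volumes: int,
    hrf: np.ndarray | None = None,
    trained_ids: set[int] = frozenset(range(4)),
    include_nuisance: bool = True,
) -> DesignMatrix:
    """Boxcar-convolved design matrix for one run.

    Volume ``j`` samples the continuous predictor at acquisition time
    ``j * tr``.  The pre-convolution boxcar on the volume grid is kept
    alongside the convolved design (a 13 s window covers exactly
    ``13 / tr`` volume samples when ``tr`` divides 13).

    In ``mvpa8`` mode the two occurrences of a sequence's video share a
    single column, so its beta averages brain activity across both
    occurrences.  ``include_nuisance=False`` drops the error-video /
    question / cue columns (mvpa8 only).
    """
    if not events:
        raise ValueError("empty event list")
    run_end = n_volumes * tr
    for e in events:
        if e.onset + e.duration > run_end + 1e-9:
            raise ValueError(
                f"event at {e.onset:.1f}s (+{e.duration:.1f}s) exceeds run end {run_end:.1f}s"
            )

    cols = _event_columns(events, mode, set(trained_ids))
    if mode == "mvpa8":
        seq_labels = sorted(
            (l for l in cols if l.startswith("seq_")), key=lambda s: int(s[4:])
        )
        nuis = [l for l in ("error_video", "question", "cue") if l in cols]
        labels = seq_labels + (nuis if include_nuisance else [])
    else:
        labels = [l for l in UNIVARIATE6_LABELS if l in cols]

    dt = tr / OVERSAMPLING
    n_hi = n_volumes * OVERSAMPLING
    t_hi = np.arange(n_hi) * dt
    h = canonical_hrf(dt) if hrf is None else hrf

    X = np.empty((n_volumes, len(labels)))
    boxcars = np.empty((n_volumes, len(labels)))
    vol_idx = np.arange(n_volumes) * OVERSAMPLING
    t_vol = np.arange(n_volumes) * tr
    for q, label in enumerate(labels):
        box_hi = np.zeros(n_hi)
        box_lo = np.zeros(n_volumes)
        for onset, duration in cols[label]:
            box_hi[(t_hi >= onset) & (t_hi < onset + duration)] = 1.0
            box_lo[(t_vol >= onset) & (t_vol < onset + duration)] = 1.0
        conv = np.convolve(box_hi, h)[:n_hi]
        X[:, q] = conv[vol_idx]
        boxcars[:, q] = box_lo
    return DesignMatrix(X=X, boxcars=boxcars, labels=labels, tr=tr)


def dct_basis(n_volumes: int, tr: float, cutoff: float = 1.0 / 52.0) -> np.ndarray:
    """Discrete-cosine drift basis: all components with frequency < cutoff.

    Component ``k`` has frequency ``k / (2 * T * tr)``; ``k = 0`` is the
    DC term.  Columns are orthonormal.
    """
    nyquist = 1.0 / (2.0 * tr)
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyquist} Hz")
    n_comp = int(np.ceil(2.0 * n_volumes * tr * cutoff))
    n_comp = max(n_comp, 1)
    t = np.arange(n_volumes)
    basis = np.empty((n_volumes, n_comp))
    basis[:, 0] = 1.0 / np.sqrt(n_volumes)
    for k in range(1, n_comp):
        basis[:, k] = np.sqrt(2.0 / n_volumes) * np.cos(
            np.pi * k * (2 * t + 1) / (2 * n_volumes)
        )
    return basis


def highpass(ts: np.ndarray, tr: float, cutoff: float = 1.0 / 52.0) -> np.ndarray:
    """Remove drift below ``cutoff`` by projecting out the DCT basis.

    Works on 1-D series or T x P arrays; removes the DC component too.
    """
    ts = np.asarray(ts, dtype=float)
    one_d = ts.ndim == 1
    Y = ts[:, None] if one_d else ts
    B = dct_basis(Y.shape[0], tr, cutoff)
    if Y.shape[0] <= B.shape[1]:
        raise ValueError("time series shorter than filter order")
    out = Y - B @ (B.T @ Y)
    return out[:, 0] if one_d else out


@dataclass
class GlmFit:
    """Per-run GLM estimates: betas, residuals and effective dof."""

    betas: np.ndarray  # Q x P
    residuals: np.ndarray  # T x P (in the whitened space for AR(1) fits)
    labels: list[str]
    dof: int
    ar1: float | None = None

    def beta(self, label: str) -> np.ndarray:
        return self.betas[self.labels.index(label)]


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design matrix (rank {rank} < {X.shape[1]})")
    betas, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ betas
    return betas, resid, X.shape[0] - rank


def fit(
    ts: np.ndarray,
    design: DesignMatrix,
    whiten: str = "none",
    highpass_cutoff: float | None = 1.0 / 52.0,
) -> GlmFit:
    """Estimate run-wise betas by OLS or AR(1)-prewhitened GLS.

    When a high-pass cutoff is given, data *and* design are filtered with
    the same DCT projection so drift removal does not bias the betas.
    For ``whiten="ar1"`` the lag-1 coefficient is estimated from pooled
    OLS residuals and both sides are prewhitened by the standard AR(1)
    transform before refitting.
    """
    Y = np.asarray(ts, dtype=float)
    X = design.X
    if Y.shape[0] != X.shape[0]:
        raise ValueError("time series / design length mismatch")
    if Y.shape[0] <= X.shape[1]:
        raise ValueError("need more volumes than regressors")
    if highpass_cutoff is not None:
        Y = highpass(Y, design.tr, highpass_cutoff)
        X = highpass(X, design.tr, highpass_cutoff)

    betas, resid, dof = _ols(X, Y)
    if whiten == "none":
        return GlmFit(betas, resid, list(design.labels), dof)
    if whiten != "ar1":
        raise ValueError(f"unknown whitening {whiten!r}")

    num = float(np.sum(resid[1:] * resid[:-1]))
    den = float(np.sum(resid[:-1] ** 2))
    rho = 0.0 if den == 0 else np.clip(num / den, -0.99, 0.99)

    def ar1_transform(A: np.ndarray) -> np.ndarray:
        out = np.empty_like(A)
        out[0] = A[0] * np.sqrt(1.0 - rho**2)
        out[1:] = A[1:] - rho * A[:-1]
        return out

    betas, resid, dof = _ols(ar1_transform(X), ar1_transform(Y))
    return GlmFit(betas, resid, list(design.labels), dof, ar1=float(rho))


def contrast(fits: list[GlmFit], weights: dict[str, float]) -> np.ndarray:
    """Per-voxel contrast value: weighted sum of run-averaged betas."""
    if not fits:
        raise ValueError("no fits supplied")
    labels = fits[0].labels
    for f in fits:
        if f.labels != labels:
            raise ValueError("inconsistent regressor labels across runs")
    unknown = set(weights) - set(labels)
    if unknown:
        raise ValueError(f"weights refer to unknown regressors {sorted(unknown)}")
    mean_betas = np.mean([f.betas for f in fits], axis=0)
    out = np.zeros(mean_betas.shape[1])
    for label, w in weights.items():
        out += w * mean_betas[labels.index(label)]
    return out
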