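"""Synthetic-study generator.

Produces ground-truth voxel patterns, BOLD-like run time series and
trial-level behavioral logs with the statistical structure the analysis
assumes, so every downstream stage (GLM, crossnobis, searchlight,
inference) can be exercised and validated without any real data.

What is emulated
----------------
* Scanning structure: 2 sessions x 10 runs x 8 sequence regressors
  (4 trained + 4 untrained), 13 s boxcar video events, TR 2.6 s,
  136 recorded volumes per run.
* Sequence-specific signal: each sequence has a latent voxel pattern;
  within a condition all sequences share a condition mean, and the
  sequence-specific component is scaled by a per-(session, condition)
  amplitude.  Amplitude 0 means no sequence information (the crossnobis
  null).
* Noise: temporally AR(1), spatially correlated with an
  exponential-decay covariance by voxel distance, plus slow cosine
  drift.
* Behavior: pre/post key-press execution trials with log-normal
  initiation and execution times, persistent subject-by-condition
  idiosyncrasies, and a trained-condition post-training speed-up of
  controllable size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import glm
from .design import SessionSchedule, TrialEvent

__all__ = [
    "PatternParams",
    "GroundTruth",
    "BehaviorParams",
    "SimulatedStudy",
    "exponential_noise_cov",
    "simulate_patterns",
    "simulate_bold",
    "simulate_run_patterns",
    "simulate_behavior",
]

SESSIONS = ("pre", "post")
CONDITIONS = ("trained", "untrained")


def exponential_noise_cov(
    positions_mm: np.ndarray, variance: float = 1.0, length_scale_mm: float = 4.0
) -> np.ndarray:
    """Spatial noise covariance with exponential distance decay.

    ``Sigma_ij = variance * exp(-||x_i - x_j|| / length_scale)``; cheap,
    positive definite, and non-spherical enough that prewhitening matters.
    """
    pos = np.atleast_2d(np.asarray(positions_mm, dtype=float))
    if pos.shape[0] == 1 and pos.size > 1:
        pos = pos.T
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    return variance * np.exp(-d / length_scale_mm)


@dataclass
class PatternParams:
    """Knobs of the voxel-pattern generative model."""

    n_voxels: int = 200
    #: scale of the sequence-specific pattern component per (session, condition)
    signal_amplitude: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            (s, c): 0.5 for s in SESSIONS for c in CONDITIONS
        }
    )
    condition_mean_scale: float = 1.0
    noise_variance: float = 1.0
    noise_length_scale_mm: float = 4.0
    voxel_size_mm: float = 2.0
    ar1_coef: float = 0.3
    drift_amplitude: float = 1.0
    voxel_positions_mm: np.ndarray | None = None  # (P, 3); default 1-D line


@dataclass
class GroundTruth:
    """Latent quantities the analysis is meant to recover."""

    base_patterns: np.ndarray  # (8, P) unit-scale sequence components
    condition_mean: np.ndarray  # (2, P), rows = trained, untrained
    signal_amplitude: dict[tuple[str, str], float]
    noise_cov: np.ndarray  # (P, P)
    ar1_coef: float
    drift_amplitude: float
    noise_chol: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        s = self.noise_cov
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("noise covariance must be symmetric")
        try:
            self.noise_chol = np.linalg.cholesky(s)
        except np.linalg.LinAlgError as err:
            raise ValueError("noise covariance must be positive definite") from err
        for amp in self.signal_amplitude.values():
            if amp < 0:
                raise ValueError("signal amplitudes must be >= 0")

    @property
    def n_voxels(self) -> int:
        return self.base_patterns.shape[1]

    def condition_of(self, sequence_id: int) -> str:
        return "trained" if sequence_id < 4 else "untrained"

    def true_pattern(self, sequence_id: int, session: str) -> np.ndarray:
        """Expected activation pattern of one sequence in one session."""
        cond = self.condition_of(sequence_id)
        amp = self.signal_amplitude[(session, cond)]
        mean = self.condition_mean[0 if cond == "trained" else 1]
        return mean + amp * self.base_patterns[sequence_id]

    def pattern_matrix(self, session: str, condition: str) -> np.ndarray:
        """(4, P) true patterns of one condition's sequences."""
        ids = range(4) if condition == "trained" else range(4, 8)
        return np.stack([self.true_pattern(i, session) for i in ids])


def simulate_patterns(
    params: PatternParams, seed: int | np.random.Generator
) -> GroundTruth:
    """Draw the latent sequence patterns and noise model.

    Sequence components are i.i.d. standard normal over voxels (unit
    scale; the per-(session, condition) amplitude multiplies them), and
    the two condition means are drawn once and shared by the four
    sequences of a condition, so amplitude 0 leaves only the shared mean.
    """
    rng = np.random.default_rng(seed)
    P = params.n_voxels
    if P < 1:
        raise ValueError("need at least one voxel")
    if params.voxel_positions_mm is not None:
        pos = np.asarray(params.voxel_positions_mm, dtype=float)
    else:
        pos = np.arange(P)[:, None] * params.voxel_size_mm
    sigma = exponential_noise_cov(
        pos, params.noise_variance, params.noise_length_scale_mm
    )
    return GroundTruth(
        base_patterns=rng.standard_normal((8, P)),
        condition_mean=params.condition_mean_scale * rng.standard_normal((2, P)),
        signal_amplitude=dict(params.signal_amplitude),
        noise_cov=sigma,
        ar1_coef=params.ar1_coef,
        drift_amplitude=params.drift_amplitude,
    )


def _ar1_spatial_noise(
    T: int, chol: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """T x P noise, AR(1) in time, marginal spatial covariance ``chol chol'``."""
    P = chol.shape[0]
    innov = rng.standard_normal((T, P)) @ chol.T
    if rho == 0:
        return innov
    out = np.empty_like(innov)
    out[0] = innov[0]
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, T):
        out[t] = rho * out[t - 1] + scale * innov[t]
    return out


@dataclass
class SimulatedStudy:
    """One subject-session of simulated scanning data."""

    session: str
    bold_runs: list[np.ndarray]  # T x P per run
    designs: list[glm.DesignMatrix]
    events: SessionSchedule
    truth: GroundTruth
    true_betas: list[np.ndarray]  # Q x P generating coefficients per run


def simulate_bold(
    schedule: SessionSchedule,
    truth: GroundTruth,
    session: str = "pre",
    seed: int | np.random.Generator = 0,
    noise_scale: float = 1.0,
    hrf: np.ndarray | None = None,
) -> SimulatedStudy:
    """Generate BOLD-like run time series ``y = X B + drift + noise``.

    ``X`` is the mvpa8 design (sequence regressors + nuisance columns)
    built by the glm module from the scanning schedule, so a noiseless
    simulation is recovered exactly by the same GLM.  Noise is AR(1) in
    time and spatially correlated via the ground-truth covariance;
    drift is a sum of slow cosines (including a constant offset).
    """
    if schedule.kind != "scanning":
        raise ValueError("simulate_bold expects a scanning schedule")
    if session not in SESSIONS:
        raise ValueError(f"unknown session {session!r}")
    rng = np.random.default_rng(seed)
    tr = schedule.meta["tr"]
    n_vol = schedule.meta["n_volumes"]
    P = truth.n_voxels
    bold_runs, designs, true_betas = [], [], []
    for run_events in schedule.blocks_or_runs:
        X = glm.build_design(run_events, "mvpa8", tr, n_vol, hrf=hrf)
        B = np.zeros((len(X.labels), P))
        for q, label in enumerate(X.labels):
            if label.startswith("seq_"):
                B[q] = truth.true_pattern(int(label[4:]), session)
            else:  # nuisance responses: weak unstructured patterns
                B[q] = 0.2 * rng.standard_normal(P)
        drift = np.zeros((n_vol, P))
        if truth.drift_amplitude > 0:
            # random low-frequency drift spanned by the slowest discrete-
            # cosine components (constant + two slow cosines per voxel)
            basis = glm.dct_basis(n_vol, tr, cutoff=1.0 / 52.0)[:, :3]
            weights = truth.drift_amplitude * np.sqrt(n_vol) * rng.standard_normal((3, P))
            drift = basis @ weights
        noise = (
            noise_scale * _ar1_spatial_noise(n_vol, truth.noise_chol, truth.ar1_coef, rng)
            if noise_scale > 0
            else np.zeros((n_vol, P))
        )
        bold_runs.append(X.X @ B + drift + noise)
        designs.append(X)
        true_betas.append(B)
    return SimulatedStudy(session, bold_runs, designs, schedule, truth, true_betas)


def simulate_run_patterns(
    truth: GroundTruth,
    session: str,
    condition: str,
    n_runs: int = 10,
    noise_scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Fast path: noisy per-run activation estimates, skipping the GLM.

    Returns (4, n_runs, P): the condition's true sequence patterns plus
    independent spatially correlated estimation noise per run, emulating
    the sampling distribution of GLM betas.  Used by Monte-Carlo suites
    where simulating and refitting full time series would be wasteful.
    """
    rng = np.random.default_rng(seed)
    true = truth.pattern_matrix(session, condition)  # (4, P)
    P = true.shape[1]
    noise = rng.standard_normal((4, n_runs, P)) @ (noise_scale * truth.noise_chol).T
    return true[:, None, :] + noise


@dataclass
class BehaviorParams:
    """Generative parameters of the pre/post key-press behavior (ms).

    Defaults mirror the study conditions: 16 subjects, 8 sequences x 5
    executions per session, initiation times around 700 ms and execution
    times around 1450 ms before training, training effects of 84 ms
    (initiation) and 115 ms (execution), and a ~12% error rate.
    """

    n_subjects: int = 16
    executions_per_sequence: int = 5
    init_mean: float = 700.0
    exec_mean: float = 1450.0
    trial_sd_init: float = 150.0
    trial_sd_exec: float = 250.0
    subject_sd: float = 120.0
    cond_sd: float = 40.0  # persistent subject-by-condition idiosyncrasy
    delta_init: float = 84.0
    delta_exec: float = 115.0
    error_prob: float = 0.12

    def __post_init__(self) -> None:
        for name in ("init_mean", "exec_mean", "trial_sd_init", "trial_sd_exec"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.error_prob <= 1:
            raise ValueError("error_prob must lie in [0, 1]")


def _lognormal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Log-normal draws with the requested mean and SD (moment matching)."""
    if mean <= 0:
        raise ValueError("time parameters must be positive")
    if sd == 0:
        return np.full(size, mean)
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), size)


def simulate_behavior(
    params: BehaviorParams | None = None,
    seed: int | np.random.Generator = 0,
    sequences: list[tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Trial-level key-press logs for the pre and post test sessions.

    Each row is one sequence execution with the go-signal time, the five
    key-press timestamps, the pressed keys and per-press correctness.
    Post-session trained trials have their initiation / execution means
    reduced by the training effects ``delta_init`` / ``delta_exec``.
    """
    params = params or BehaviorParams()
    rng = np.random.default_rng(seed)
    if sequences is None:
        sequences = [tuple(np.roll([1, 2, 3, 4, 5], i)) for i in range(8)]
    if len(sequences) != 8:
        raise ValueError("behavior needs the 8 active sequences")

    rows = []
    n_exec = params.executions_per_sequence
    for subj in range(params.n_subjects):
        subj_init = rng.normal(0.0, params.subject_sd)
        subj_exec = rng.normal(0.0, params.subject_sd)
        cond_init = {c: rng.normal(0.0, params.cond_sd) for c in CONDITIONS}
        cond_exec = {c: rng.normal(0.0, params.cond_sd) for c in CONDITIONS}
        for session in SESSIONS:
            clock = 0.0
            seq_order = rng.permutation(8)
            for sid in seq_order:
                cond = "trained" if sid < 4 else "untrained"
                trained_now = session == "post" and cond == "trained"
                m_init = (
                    params.init_mean
                    + subj_init
                    + cond_init[cond]
                    - (params.delta_init if trained_now else 0.0)
                )
                m_exec = (
                    params.exec_mean
                    + subj_exec
                    + cond_exec[cond]
                    - (params.delta_exec if trained_now else 0.0)
                )
                inits = _lognormal(rng, m_init, params.trial_sd_init, n_exec)
                execs = _lognormal(rng, m_exec, params.trial_sd_exec, n_exec)
                for trial in range(n_exec):
                    clock += 3000.0  # cue + fixation before the go signal
                    go = clock
                    t1 = go + inits[trial]
                    # split total execution time over the 4 inter-press gaps
                    frac = rng.dirichlet(np.full(4, 8.0))
                    press_times = t1 + np.concatenate(
                        [[0.0], np.cumsum(frac) * execs[trial]]
                    )
                    keys = list(sequences[sid])
                    correct = [True] * 5
                    if rng.random() < params.error_prob:
                        bad = int(rng.integers(0, 5))
                        wrong = int(rng.choice([k for k in range(1, 6) if k != keys[bad]]))
                        keys[bad] = wrong
                        correct[bad] = False
                    row = {
                        "subject": subj,
                        "session": session,
                        "condition": cond,
                        "sequence_id": int(sid),
                        "execution": trial,
                        "go_time": go,
                    }
                    for i in range(5):
                        row[f"press_time_{i + 1}"] = press_times[i]
                        row[f"press_key_{i + 1}"] = keys[i]
                        row[f"correct_{i + 1}"] = correct[i]
                    rows.append(row)
                    clock = press_times[-1] + 1000.0
    return pd.DataFrame(rows)


def with_amplitude(truth: GroundTruth, amplitude: float) -> GroundTruth:
    """Copy of ``truth`` with one common signal amplitude everywhere."""
    return replace(
        truth,
        signal_amplitude={k: amplitude for k in truth.signal_amplitude},
    )
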