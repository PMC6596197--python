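"""Behavioral measures from trial-level key-press logs.

A trial is one execution of a five-key sequence: a go signal followed by
five key presses, each with a timestamp, the pressed key, and a
correctness flag.  Measures:

* initiation time — go signal to first key press (ms);
* execution time — first to fifth key press (ms);
* error rate — percentage of executions containing any wrong press
  (incorrect executions are excluded from the timing summaries);
* trial-by-trial speed feedback relative to the running median of prior
  correct executions (green / red / blue / fast);
* accuracy on the error-detection questions of the observation task.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "initiation_time",
    "execution_time",
    "is_correct",
    "error_rate",
    "feedback_code",
    "error_question_accuracy",
    "summarize",
]

PRESS_TIME_COLS = [f"press_time_{i}" for i in range(1, 6)]
CORRECT_COLS = [f"correct_{i}" for i in range(1, 6)]

#: speed-feedback window: within +-20% of the prior median is plain green
SLOW_FACTOR = 1.2
FAST_FACTOR = 0.8


def _press_times(trial: Mapping) -> np.ndarray:
    try:
        times = np.array([float(trial[c]) for c in PRESS_TIME_COLS])
    except KeyError as err:
        raise ValueError(f"trial is missing press timestamp {err}") from err
    if np.any(np.diff(times) <= 0):
        raise ValueError("press timestamps must be strictly increasing")
    return times


def initiation_time(trial: Mapping) -> float:
    """Duration between the go signal and the first key press (ms)."""
    return float(_press_times(trial)[0]) - float(trial["go_time"])


def execution_time(trial: Mapping) -> float:
    """Duration between the first and fifth key presses (ms)."""
    times = _press_times(trial)
    return float(times[4] - times[0])


def is_correct(trial: Mapping) -> bool:
    """An execution is correct iff all five presses hit the right key."""
    return all(bool(trial[c]) for c in CORRECT_COLS)


def error_rate(trials: pd.DataFrame) -> float:
    """Percentage of incorrect sequence executions."""
    if len(trials) == 0:
        raise ValueError("empty trial set")
    n_bad = int((~trials[CORRECT_COLS].all(axis=1)).sum())
    return 100.0 * n_bad / len(trials)


def feedback_code(
    current_exec_ms: float, correct: bool, prior_median_ms: float | None
) -> str:
    """Trial feedback: red (error), blue (slow), fast, or green.

    Blue marks a correct execution more than 20% slower than the median
    execution time of the prior correct trials; "fast" (three green
    asterisks on screen) marks one more than 20% faster.  With no prior
    median (first trials) a correct execution is plain green.
    """
    if not correct:
        return "red"
    if prior_median_ms is None:
        return "green"
    if prior_median_ms <= 0:
        raise ValueError("prior median must be positive")
    if current_exec_ms > SLOW_FACTOR * prior_median_ms:
        return "blue"
    if current_exec_ms < FAST_FACTOR * prior_median_ms:
        return "fast"
    return "green"


def error_question_accuracy(responses: Iterable[tuple[bool, bool]]) -> float:
    """Percent of correct yes/no answers; items are (answer, truth) pairs."""
    pairs = list(responses)
    if not pairs:
        raise ValueError("empty response log")
    n_ok = sum(bool(a) == bool(t) for a, t in pairs)
    return 100.0 * n_ok / len(pairs)


def summarize(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject x session x condition behavioral summary.

    Mean initiation and execution times are computed over correct trials
    only; the error rate over all trials.  Output is order-invariant in
    the input rows.
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    press = trials[PRESS_TIME_COLS].to_numpy(dtype=float)
    if np.any(np.diff(press, axis=1) <= 0):
        raise ValueError("press timestamps must be strictly increasing")
    df = trials.assign(
        _init=press[:, 0] - trials["go_time"].to_numpy(dtype=float),
        _exec=press[:, 4] - press[:, 0],
        _ok=trials[CORRECT_COLS].all(axis=1),
    )
    keys = ["subject", "session", "condition"]
    grouped = df.groupby(keys, sort=True)
    ok_means = (
        df[df["_ok"]].groupby(keys, sort=True)[["_init", "_exec"]].mean()
    )
    out = pd.DataFrame(
        {
            "error_rate_pct": 100.0 * (1.0 - grouped["_ok"].mean()),
            "n_trials_included": grouped["_ok"].sum().astype(int),
        }
    )
    out = out.join(ok_means)
    out = out.rename(columns={"_init": "initiation_ms", "_exec": "execution_ms"})
    cols = [
        "initiation_ms",
        "execution_ms",
        "error_rate_pct",
        "n_trials_included",
    ]
    return out.reset_index()[keys + cols]


def condition_differences(
    summary: pd.DataFrame, measure: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject trained-minus-untrained differences (pre, post).

    The pre-training differences feed the intercept regression as the
    predictor and the post-training differences as the outcome.
    """
    wide = summary.pivot_table(
        index="subject", columns=["session", "condition"], values=measure
    )
    pre = (wide[("pre", "trained")] - wide[("pre", "untrained")]).to_numpy()
    post = (wide[("post", "trained")] - wide[("post", "untrained")]).to_numpy()
    return pre, post
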