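"""Combinatorial structure of the observational sequence-learning experiment.

Five-finger key-press sequences, their allocation to trained / untrained /
unused conditions, the stimulus video catalog, and the trial-by-trial
schedules of observational-training sessions and scanning sessions.

Conventions
-----------
Fingers are indexed 1 (thumb) .. 5 (little finger).  A sequence is an
ordered 5-tuple in which every finger occurs exactly once.  Sequences are
admissible when they contain no monotone run of more than three adjacent
fingers, i.e. no length-4 window whose successive elements all differ by
+1 or all by -1 (so (1,2,3,4,5) is out, (1,3,5,2,4) is in).

All timing is in seconds.  Scanning-run timelines are expressed relative
to the first *recorded* volume (dummy scans discarded).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Sequence",
    "ConditionAllocation",
    "VideoCatalog",
    "TrialEvent",
    "SessionSchedule",
    "is_admissible",
    "enumerate_sequence_pool",
    "sample_sequence_pool",
    "allocate_conditions",
    "build_training_session",
    "build_scanning_session",
    "events_to_table",
]

Sequence = tuple[int, int, int, int, int]

N_FINGERS = 5
POOL_SIZE = 12
#: length of the shortest forbidden monotone neighbouring-finger run
MAX_ADJACENT_RUN = 3

# stimulus / trial timing constants
VIDEO_DURATION = 13.0
CUE_DURATION = 2.6
FIXATION_DURATION = 0.4
QUESTION_DURATION = 2.6
REST_DURATION = 13.0

TR = 2.6
N_DUMMY_VOLUMES = 2
N_RECORDED_VOLUMES = 136
N_RUNS = 10

TRAINING_BLOCKS = 4
VIDEOS_PER_BLOCK = 20
CORRECT_VERSIONS_PER_SEQUENCE = 5
REPETITIONS_PER_VIDEO = 5


def is_admissible(seq: Sequence, max_run: int = MAX_ADJACENT_RUN) -> bool:
    """True if ``seq`` has no monotone adjacent-finger run longer than ``max_run``.

    A run of length ``r`` means ``r`` consecutive presses whose finger
    indices step by exactly +1 each time (or exactly -1).  With the
    default ``max_run=3``, any window of 4 presses stepping 1,1,1 (or
    -1,-1,-1) disqualifies the sequence.
    """
    steps = np.diff(seq)
    window = max_run  # number of steps in a run of max_run + 1 presses
    for i in range(len(steps) - window + 1):
        chunk = steps[i : i + window]
        if np.all(chunk == 1) or np.all(chunk == -1):
            return False
    return True


def enumerate_sequence_pool(max_run: int = MAX_ADJACENT_RUN) -> list[Sequence]:
    """All permutations of (1..5) satisfying the adjacency constraint.

    Exhaustive enumeration over the 120 permutations; the stimulus pool of
    12 is drawn from this set by :func:`sample_sequence_pool`.
    """
    return [
        perm
        for perm in itertools.permutations(range(1, N_FINGERS + 1))
        if is_admissible(perm, max_run)
    ]


def sample_sequence_pool(seed: int | np.random.Generator) -> list[Sequence]:
    """Draw the 12-sequence stimulus pool reproducibly from a seed."""
    rng = np.random.default_rng(seed)
    admissible = enumerate_sequence_pool()
    idx = rng.choice(len(admissible), size=POOL_SIZE, replace=False)
    return [admissible[i] for i in idx]


@dataclass(frozen=True)
class ConditionAllocation:
    """Random 4/4/4 partition of the 12-sequence pool."""

    trained: tuple[Sequence, ...]
    untrained: tuple[Sequence, ...]
    unused: tuple[Sequence, ...]

    def __post_init__(self) -> None:
        sets = [set(self.trained), set(self.untrained), set(self.unused)]
        if any(len(s) != 4 for s in sets):
            raise ValueError("each condition must hold exactly 4 sequences")
        union = sets[0] | sets[1] | sets[2]
        if len(union) != POOL_SIZE:
            raise ValueError("conditions must be disjoint and cover the pool")

    @property
    def active(self) -> tuple[Sequence, ...]:
        """The 8 sequences shown in the scanner (trained + untrained)."""
        return self.trained + self.untrained

    def condition_of(self, seq: Sequence) -> str:
        if seq in self.trained:
            return "trained"
        if seq in self.untrained:
            return "untrained"
        return "unused"


def allocate_conditions(
    pool: list[Sequence], seed: int | np.random.Generator
) -> ConditionAllocation:
    """Randomly allocate 4 sequences each to trained/untrained/unused."""
    if len(pool) != POOL_SIZE or len(set(pool)) != POOL_SIZE:
        raise ValueError(f"pool must contain {POOL_SIZE} distinct sequences")
    rng = np.random.default_rng(seed)
    order = rng.permutation(POOL_SIZE)
    shuffled = [pool[i] for i in order]
    return ConditionAllocation(
        trained=tuple(shuffled[:4]),
        untrained=tuple(shuffled[4:8]),
        unused=tuple(shuffled[8:]),
    )


@dataclass(frozen=True)
class VideoEntry:
    sequence_id: int  # index into the allocation's active/pool ordering
    version: int  # 1..6
    is_error: bool
    duration: float = VIDEO_DURATION


@dataclass
class VideoCatalog:
    """Stimulus catalog: per sequence, 5 correct versions and 1 error version."""

    entries: list[VideoEntry]

    @classmethod
    def for_pool(cls, n_sequences: int = POOL_SIZE) -> "VideoCatalog":
        entries = []
        for sid in range(n_sequences):
            for version in range(1, CORRECT_VERSIONS_PER_SEQUENCE + 1):
                entries.append(VideoEntry(sid, version, is_error=False))
            entries.append(
                VideoEntry(sid, CORRECT_VERSIONS_PER_SEQUENCE + 1, is_error=True)
            )
        return cls(entries)

    def validate(self) -> None:
        by_seq: dict[int, list[VideoEntry]] = {}
        for e in self.entries:
            by_seq.setdefault(e.sequence_id, []).append(e)
        for sid, items in by_seq.items():
            n_err = sum(e.is_error for e in items)
            if n_err != 1 or len(items) != 6:
                raise ValueError(f"sequence {sid}: need 5 correct + 1 error video")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class TrialEvent:
    onset: float
    duration: float
    label: str  # cue | video | error_video | question | rest
    sequence_id: int | None = None  # None for rest / question


@dataclass
class SessionSchedule:
    """Ordered event lists for one session (training blocks or scanning runs)."""

    kind: str  # "training" | "scanning"
    blocks_or_runs: list[list[TrialEvent]]
    allocation: ConditionAllocation | None = None
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind == "training":
            _validate_training(self)
        elif self.kind == "scanning":
            _validate_scanning(self)
        else:
            raise ValueError(f"unknown session kind {self.kind!r}")


def _append_observation_trial(
    events: list[TrialEvent],
    t: float,
    sequence_id: int,
    is_error: bool,
    ask_question: bool,
) -> float:
    """Fixation + cue + video (+ optional question); returns the new clock."""
    t += FIXATION_DURATION
    events.append(TrialEvent(t, CUE_DURATION, "cue", sequence_id))
    t += CUE_DURATION
    label = "error_video" if is_error else "video"
    events.append(TrialEvent(t, VIDEO_DURATION, label, sequence_id))
    t += VIDEO_DURATION
    if ask_question:
        events.append(TrialEvent(t, QUESTION_DURATION, "question", None))
        t += QUESTION_DURATION
    return t


def build_training_session(
    alloc: ConditionAllocation, seed: int | np.random.Generator
) -> SessionSchedule:
    """One observational-training session: 4 blocks of 20 videos.

    Per block each trained sequence contributes its error video once and
    4 correct videos (drawn from the 5 correct versions), shown in random
    order; the error question is asked after 5-7 randomly chosen videos.
    With 5 correct repetitions per correct video this yields at least
    4 blocks x 4 videos x 5 = 80 correct executions per sequence.
    """
    rng = np.random.default_rng(seed)
    trained_ids = list(range(4))  # positions within alloc.trained
    blocks: list[list[TrialEvent]] = []
    for _ in range(TRAINING_BLOCKS):
        slots: list[tuple[int, bool]] = []
        for sid in trained_ids:
            slots.extend((sid, False) for _ in range(4))
            slots.append((sid, True))
        order = rng.permutation(len(slots))
        slots = [slots[i] for i in order]
        n_questions = int(rng.integers(5, 8))
        q_slots = set(rng.choice(len(slots), size=n_questions, replace=False))
        events: list[TrialEvent] = []
        t = 0.0
        for i, (sid, is_err) in enumerate(slots):
            t = _append_observation_trial(events, t, sid, is_err, i in q_slots)
        blocks.append(events)
    sched = SessionSchedule("training", blocks, alloc)
    sched.validate()
    return sched


def build_scanning_session(
    alloc: ConditionAllocation, seed: int | np.random.Generator
) -> SessionSchedule:
    """One scanning session: 10 runs of 17 videos each.

    Per run: the 8 active sequences twice each plus one error video (random
    sequence), in random order; 5 rest phases of 13 s, the first at run
    onset and 4 in distinct gaps between trials (hence never consecutive);
    2 error questions, one after the error video and one after a random
    correct video.  Sequence ids index ``alloc.active`` (0-3 trained,
    4-7 untrained).
    """
    rng = np.random.default_rng(seed)
    run_duration = N_RECORDED_VOLUMES * TR
    runs: list[list[TrialEvent]] = []
    for _ in range(N_RUNS):
        slots: list[tuple[int, bool]] = [(sid, False) for sid in range(8)] * 2
        slots.append((int(rng.integers(0, 8)), True))
        order = rng.permutation(len(slots))
        slots = [slots[i] for i in order]
        err_pos = next(i for i, (_, e) in enumerate(slots) if e)
        correct_positions = [i for i in range(len(slots)) if i != err_pos]
        q_positions = {err_pos, int(rng.choice(correct_positions))}
        # 4 interior rests in distinct gaps after trials 1..16
        rest_gaps = set(rng.choice(np.arange(1, len(slots)), size=4, replace=False))
        events: list[TrialEvent] = [TrialEvent(0.0, REST_DURATION, "rest", None)]
        t = REST_DURATION
        for i, (sid, is_err) in enumerate(slots):
            if i in rest_gaps:
                events.append(TrialEvent(t, REST_DURATION, "rest", None))
                t += REST_DURATION
            t = _append_observation_trial(events, t, sid, is_err, i in q_positions)
        if t > run_duration:
            raise ValueError(
                f"run timeline {t:.1f}s exceeds recorded duration {run_duration:.1f}s"
            )
        runs.append(events)
    sched = SessionSchedule(
        "scanning",
        runs,
        alloc,
        meta={
            "tr": TR,
            "n_volumes": N_RECORDED_VOLUMES,
            "n_dummy": N_DUMMY_VOLUMES,
            "run_duration": run_duration,
        },
    )
    sched.validate()
    return sched


def _validate_training(sched: SessionSchedule) -> None:
    if len(sched.blocks_or_runs) != TRAINING_BLOCKS:
        raise ValueError("training session must have 4 blocks")
    for block in sched.blocks_or_runs:
        vids = [e for e in block if e.label in ("video", "error_video")]
        if len(vids) != VIDEOS_PER_BLOCK:
            raise ValueError("training block must show 20 videos")
        n_q = sum(e.label == "question" for e in block)
        if not 5 <= n_q <= 7:
            raise ValueError("training block must ask 5-7 error questions")
        per_seq_correct: dict[int, int] = {}
        per_seq_error: dict[int, int] = {}
        for e in vids:
            d = per_seq_error if e.label == "error_video" else per_seq_correct
            d[e.sequence_id] = d.get(e.sequence_id, 0) + 1
        if sorted(per_seq_correct.values()) != [4, 4, 4, 4]:
            raise ValueError("each trained sequence needs 4 correct videos per block")
        if sorted(per_seq_error.values()) != [1, 1, 1, 1]:
            raise ValueError("each trained sequence needs 1 error video per block")
    _check_monotone_onsets(sched)


def _validate_scanning(sched: SessionSchedule) -> None:
    if len(sched.blocks_or_runs) != N_RUNS:
        raise ValueError("scanning session must have 10 runs")
    for run in sched.blocks_or_runs:
        vids = [e for e in run if e.label in ("video", "error_video")]
        if len(vids) != 17:
            raise ValueError("scanning run must show 17 videos")
        if sum(e.label == "error_video" for e in run) != 1:
            raise ValueError("scanning run must show exactly one error video")
        counts: dict[int, int] = {}
        for e in vids:
            if e.label == "video":
                counts[e.sequence_id] = counts.get(e.sequence_id, 0) + 1
        if sorted(counts.items()) != [(sid, 2) for sid in range(8)]:
            raise ValueError("each of the 8 sequences must appear twice per run")
        rests = [e for e in run if e.label == "rest"]
        if len(rests) != 5:
            raise ValueError("scanning run must contain 5 rest phases")
        if rests[0].onset != 0.0:
            raise ValueError("first rest phase must start at run onset")
        rest_onsets = sorted(e.onset for e in rests)
        for a, b in itertools.pairwise(rest_onsets):
            if abs((a + REST_DURATION) - b) < 1e-9:
                raise ValueError("rest phases must not be consecutive")
        if sum(e.label == "question" for e in run) != 2:
            raise ValueError("scanning run must ask exactly 2 questions")
    _check_monotone_onsets(sched)


def _check_monotone_onsets(sched: SessionSchedule) -> None:
    for unit in sched.blocks_or_runs:
        onsets = [e.onset for e in unit]
        if any(b < a for a, b in itertools.pairwise(onsets)):
            raise ValueError("event onsets must be nondecreasing")


def events_to_table(events: list[TrialEvent]) -> pd.DataFrame:
    """BIDS-events-style table with onset, duration, trial_type, sequence_id."""
    return pd.DataFrame(
        {
            "onset": [e.onset for e in events],
            "duration": [e.duration for e in events],
            "trial_type": [e.label for e in events],
            "sequence_id": [
                "n/a" if e.sequence_id is None else e.sequence_id for e in events
            ],
        }
    )
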