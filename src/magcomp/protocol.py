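"""Experimental design: stimulus sets, trial schedules, session plans.

The experiments this package models are same/different magnitude
comparisons performed at rest, while running on a treadmill, or right
after running.  A session interleaves *encoding* phases (the reference
stimulus shown a few times, no response) with 66-trial *decoding* phases
in which nine test magnitudes, log-spaced around the reference, are each
judged "same" or "different" relative to the memorized reference.

Three session kinds are supported:

``duration_while``
    600 ms reference; measurement phases T1 (baseline), RUN_TEST (while
    running at ~80% of age-predicted maximum heart rate) and T2
    (post-run baseline) — three decoding phases per block.
``duration_after``
    identical stimuli, but the test phase starts immediately after the
    treadmill stops and there is no T2 — two decoding phases per block.
``numerosity_while``
    dot-array stimuli with a 24-dot reference, same phase structure as
    ``duration_while``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "StimulusSet",
    "DecodingSchedule",
    "SessionPlan",
    "Phase",
    "HeartRatePolicy",
    "ExperimentKind",
    "make_log_spaced_tests",
    "build_decoding_schedule",
    "build_session_plan",
    "target_heart_rate",
    "duration_stimulus_set",
    "numerosity_stimulus_set",
    "schedule_to_frame",
    "DURATION_REFERENCE_MS",
    "NUMEROSITY_REFERENCE",
    "NUMEROSITY_TESTS",
    "REPS_NONREFERENCE",
    "REPS_REFERENCE",
]

ExperimentKind = Literal["duration_while", "duration_after", "numerosity_while"]
EXPERIMENT_KINDS: tuple[str, ...] = (
    "duration_while",
    "duration_after",
    "numerosity_while",
)

#: Study constants: 600 ms reference duration, 1268 ms most extreme test,
#: 24-dot reference numerosity, 6 repeats per non-reference level and 18
#: repeats of the reference in every 66-trial decoding phase.
DURATION_REFERENCE_MS = 600.0
DURATION_EXTREME_MS = 1268.0
NUMEROSITY_REFERENCE = 24.0
#: The printed numerosity test levels.  These are stored verbatim rather
#: than generated: no single-ratio log-spacing rule reproduces the 17
#: (the geometric rule from 24 and 51 gives 16), so the published list is
#: treated as the design ground truth.
NUMEROSITY_TESTS: tuple[float, ...] = (11, 14, 17, 20, 24, 29, 35, 42, 51)
REPS_NONREFERENCE = 6
REPS_REFERENCE = 18

#: Rest/run phase durations in seconds (while-running and after-running
#: designs differ in the rest before T1 and in when testing happens).
REST_BEFORE_T1_WHILE_S = 180.0
REST_BEFORE_T1_AFTER_S = 480.0
RUN_WARMUP_S = 180.0
RUN_TEST_S = 300.0
ENCODING_PRESENTATIONS = 5
TRAINING_BLOCK_TRIALS = 9


def _round_half_away(x: float) -> float:
    """Round to nearest integer, halves away from zero."""
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


@dataclass(frozen=True)
class StimulusSet:
    """A reference magnitude with its ordered test levels.

    ``tests`` holds the display values (integer-rounded when ``rounded``
    is set); ``exact_tests`` retains the unrounded geometric levels for
    anything numeric downstream.
    """

    reference: float
    tests: tuple[float, ...]
    unit_label: str = "ms"
    rounded: bool = False
    exact_tests: tuple[float, ...] = ()

    def __post_init__(self):
        if self.reference <= 0:
            raise InvalidArgumentError("reference must be positive")
        if len(self.tests) % 2 == 0 or len(self.tests) < 3:
            raise InvalidArgumentError("tests must have odd length >= 3")
        if any(t <= 0 for t in self.tests):
            raise InvalidArgumentError("all test magnitudes must be positive")
        if list(self.tests) != sorted(self.tests):
            raise InvalidArgumentError("tests must be sorted ascending")
        mid = self.tests[len(self.tests) // 2]
        if mid != self.reference:
            raise InvalidArgumentError(
                f"middle test level ({mid}) must equal the reference "
                f"({self.reference})"
            )
        if sum(t == self.reference for t in self.tests) != 1:
            raise InvalidArgumentError("exactly one level may equal the reference")
        if not self.exact_tests:
            object.__setattr__(self, "exact_tests", tuple(self.tests))

    @property
    def n_levels(self) -> int:
        return len(self.tests)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "tests": list(self.tests),
            "unit_label": self.unit_label,
            "rounded": self.rounded,
        }


def make_log_spaced_tests(
    reference: float,
    extreme: float,
    steps_per_side: int = 4,
    round_to_integer: bool = False,
    unit_label: str = "ms",
) -> StimulusSet:
    """Generate ``2*steps_per_side + 1`` geometrically spaced test levels.

    Levels are built outward from the reference anchor as
    ``reference * r**k`` for ``k = -steps_per_side .. steps_per_side``
    with ``r = (extreme/reference)**(1/steps_per_side)``, so the middle
    level is exactly the reference and consecutive levels share a
    constant ratio.  With the study's duration parameters
    (600 ms reference, 1268 ms extreme, 4 steps per side, rounding on)
    this yields 284, 342, 413, 498, 600, 723, 872, 1052, 1268 ms.

    Parameters
    ----------
    reference
        Middle (anchor) magnitude; must be positive.
    extreme
        Largest test level; must exceed the reference.
    steps_per_side
        Number of levels on each side of the reference.
    round_to_integer
        Round display values half-away-from-zero; the unrounded levels
        are kept in ``exact_tests``.
    """
    if reference <= 0:
        raise InvalidArgumentError("reference must be positive")
    if extreme <= reference:
        raise InvalidArgumentError("extreme must exceed the reference")
    if steps_per_side < 1:
        raise InvalidArgumentError("steps_per_side must be >= 1")
    ratio = (extreme / reference) ** (1.0 / steps_per_side)
    exact = tuple(
        reference * ratio**k for k in range(-steps_per_side, steps_per_side + 1)
    )
    # anchor the middle element exactly (no float round-trip error)
    exact = exact[:steps_per_side] + (float(reference),) + exact[steps_per_side + 1 :]
    shown = (
        tuple(float(_round_half_away(v)) for v in exact) if round_to_integer else exact
    )
    return StimulusSet(
        reference=float(reference),
        tests=shown,
        unit_label=unit_label,
        rounded=round_to_integer,
        exact_tests=exact,
    )


def duration_stimulus_set() -> StimulusSet:
    """The 9-level duration set around the 600 ms reference."""
    return make_log_spaced_tests(
        DURATION_REFERENCE_MS, DURATION_EXTREME_MS, 4, round_to_integer=True
    )


def numerosity_stimulus_set() -> StimulusSet:
    """The 9-level dot-numerosity set around the 24-dot reference.

    Stored as the published list (11 … 51 dots) rather than generated;
    see :data:`NUMEROSITY_TESTS`.
    """
    return StimulusSet(
        reference=NUMEROSITY_REFERENCE,
        tests=tuple(float(t) for t in NUMEROSITY_TESTS),
        unit_label="dots",
        rounded=True,
    )


@dataclass(frozen=True)
class DecodingSchedule:
    """A shuffled trial list for one decoding phase."""

    trials: tuple[float, ...]
    reps_nonreference: int
    reps_reference: int
    shuffle_seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def build_decoding_schedule(
    stimuli: StimulusSet,
    reps_nonreference: int = REPS_NONREFERENCE,
    reps_reference: int = REPS_REFERENCE,
    seed: int = 0,
) -> DecodingSchedule:
    """Build one decoding phase: a uniformly shuffled trial list.

    Every non-reference level appears ``reps_nonreference`` times and the
    reference ``reps_reference`` times (66 trials with the study defaults
    of 6 and 18).  The same seed always yields the same order.
    """
    if reps_nonreference < 1 or reps_reference < 1:
        raise InvalidArgumentError("repetition counts must be >= 1")
    pool: list[float] = []
    for level in stimuli.tests:
        reps = reps_reference if level == stimuli.reference else reps_nonreference
        pool.extend([level] * reps)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    return DecodingSchedule(
        trials=tuple(pool[i] for i in order),
        reps_nonreference=reps_nonreference,
        reps_reference=reps_reference,
        shuffle_seed=seed,
    )


@dataclass(frozen=True)
class Phase:
    """One step of a session block.

    ``label`` is one of training, encoding, T1, RUN_WARMUP, RUN_TEST,
    TEST_AFTER, T2, rest.  Decoding (measurement) phases carry
    ``n_trials``; timed phases carry ``duration_s``; encoding carries
    ``n_presentations``.
    """

    label: str
    duration_s: float | None = None
    n_trials: int | None = None
    n_presentations: int | None = None

    @property
    def is_measurement(self) -> bool:
        return self.label in ("T1", "RUN_TEST", "TEST_AFTER", "T2")


@dataclass(frozen=True)
class SessionPlan:
    """Ordered phases for one participant's session."""

    experiment_kind: str
    stimuli: StimulusSet
    phases: tuple[Phase, ...]
    n_blocks: int
    reps_nonreference: int = REPS_NONREFERENCE
    reps_reference: int = REPS_REFERENCE

    @property
    def measurement_labels(self) -> tuple[str, ...]:
        """Decoding-phase labels within one block, in order."""
        seen: list[str] = []
        for p in self.phases:
            if p.is_measurement and p.label not in seen:
                seen.append(p.label)
        return tuple(seen)

    @property
    def n_measurement_phases(self) -> int:
        return len(self.measurement_labels)

    @property
    def trials_per_phase(self) -> int:
        return (
            (self.stimuli.n_levels - 1) * self.reps_nonreference
            + self.reps_reference
        )

    @property
    def total_decoding_trials(self) -> int:
        return self.n_measurement_phases * self.n_blocks * self.trials_per_phase

    def to_dict(self) -> dict:
        return {
            "experiment_kind": self.experiment_kind,
            "reference": self.stimuli.reference,
            "tests": list(self.stimuli.tests),
            "unit_label": self.stimuli.unit_label,
            "reps_nonreference": self.reps_nonreference,
            "reps_reference": self.reps_reference,
            "n_blocks": self.n_blocks,
        }


def _block_phases_while(n_trials: int) -> list[Phase]:
    return [
        Phase("training", n_trials=TRAINING_BLOCK_TRIALS),
        Phase("encoding", n_presentations=ENCODING_PRESENTATIONS),
        Phase("rest", duration_s=REST_BEFORE_T1_WHILE_S),
        Phase("T1", n_trials=n_trials),
        Phase("encoding", n_presentations=ENCODING_PRESENTATIONS),
        Phase("RUN_WARMUP", duration_s=RUN_WARMUP_S),
        Phase("RUN_TEST", n_trials=n_trials, duration_s=RUN_TEST_S),
        Phase("rest", duration_s=None),  # until heart rate returns to baseline
        Phase("encoding", n_presentations=ENCODING_PRESENTATIONS),
        Phase("T2", n_trials=n_trials),
    ]


def _block_phases_after(n_trials: int) -> list[Phase]:
    return [
        Phase("training", n_trials=TRAINING_BLOCK_TRIALS),
        Phase("encoding", n_presentations=ENCODING_PRESENTATIONS),
        Phase("rest", duration_s=REST_BEFORE_T1_AFTER_S),
        Phase("T1", n_trials=n_trials),
        Phase("encoding", n_presentations=ENCODING_PRESENTATIONS),
        Phase("RUN_WARMUP", duration_s=RUN_WARMUP_S),
        Phase("rest", duration_s=RUN_TEST_S),  # keeps running, no stimuli
        Phase("TEST_AFTER", n_trials=n_trials),
    ]


def build_session_plan(
    kind: str,
    stimuli: StimulusSet | None = None,
    n_blocks: int = 2,
    reps_nonreference: int = REPS_NONREFERENCE,
    reps_reference: int = REPS_REFERENCE,
) -> SessionPlan:
    """Assemble the phase sequence for one experiment kind.

    While-running sessions measure T1, RUN_TEST and T2 in each block
    (3 phases x 2 blocks x 66 trials = 396 decoding trials with study
    defaults); after-running sessions measure T1 and TEST_AFTER only
    (264 trials).  Training is represented as a fixed nine-trial
    placeholder phase: the feedback-driven 80%-correct loop human
    participants performed is a schedule constant here, not simulated
    learning.
    """
    if kind not in EXPERIMENT_KINDS:
        raise InvalidArgumentError(
            f"unknown experiment kind {kind!r}; expected one of {EXPERIMENT_KINDS}"
        )
    if n_blocks < 1:
        raise InvalidArgumentError("n_blocks must be >= 1")
    if stimuli is None:
        stimuli = (
            numerosity_stimulus_set()
            if kind == "numerosity_while"
            else duration_stimulus_set()
        )
    n_trials = (stimuli.n_levels - 1) * reps_nonreference + reps_reference
    block = (
        _block_phases_after(n_trials)
        if kind == "duration_after"
        else _block_phases_while(n_trials)
    )
    phases: list[Phase] = []
    for b in range(n_blocks):
        start = 1 if b > 0 else 0  # training only once per session
        phases.extend(block[start:])
    return SessionPlan(
        experiment_kind=kind,
        stimuli=stimuli,
        phases=tuple(phases),
        n_blocks=n_blocks,
        reps_nonreference=reps_nonreference,
        reps_reference=reps_reference,
    )


@dataclass(frozen=True)
class HeartRatePolicy:
    """Age-predicted heart-rate targeting for the running phases.

    Maximum heart rate follows the Tanaka-style rule
    ``hr_max = 208 - 0.7 * age`` and the treadmill speed is adjusted to
    hold the participant near ``target_fraction`` (default 0.8) of it.
    """

    age: float
    target_fraction: float = 0.8
    resting_hr: float = 87.06  # study-wide resting average, bpm
    hr_max: float = field(init=False)
    target_hr: float = field(init=False)

    def __post_init__(self):
        if not 0 < self.age < 120:
            raise InvalidArgumentError("age must be in (0, 120) years")
        if not 0 < self.target_fraction <= 1:
            raise InvalidArgumentError("target_fraction must be in (0, 1]")
        object.__setattr__(self, "hr_max", 208.0 - 0.7 * self.age)
        object.__setattr__(self, "target_hr", self.target_fraction * self.hr_max)


def target_heart_rate(age: float, fraction: float = 0.8) -> float:
    """Target heart rate in bpm: ``fraction * (208 - 0.7 * age)``."""
    return HeartRatePolicy(age=age, target_fraction=fraction).target_hr


def schedule_to_frame(
    plan: SessionPlan, seed: int = 0, block_offset: int = 1
) -> pd.DataFrame:
    """Export all decoding schedules of a plan as a tidy table.

    Columns: block, phase, trial_index, test_magnitude.  Each
    measurement phase gets an independently shuffled schedule with a
    seed derived deterministically from ``seed``.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(plan.n_blocks * plan.n_measurement_phases)
    i = 0
    for block in range(plan.n_blocks):
        for label in plan.measurement_labels:
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            sched = build_decoding_schedule(
                plan.stimuli,
                plan.reps_nonreference,
                plan.reps_reference,
                seed=child_seed,
            )
            for t, mag in enumerate(sched.trials):
                rows.append(
                    {
                        "block": block + block_offset,
                        "phase": label,
                        "trial_index": t,
                        "test_magnitude": mag,
                    }
                )
    return pd.DataFrame(rows)
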