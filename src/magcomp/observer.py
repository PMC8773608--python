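"""Generative same/different observer and heart-rate trace simulator.

The observer compares each test magnitude against a memorized reference
on an internal logarithmic scale.  The perceived log-difference on a
trial is

    d = ln(g * test / reference) + noise,   noise ~ N(0, sigma_d^2)

where ``g`` is a phase-specific multiplicative perceptual gain (g > 1
means test magnitudes are perceived as larger, e.g. running-induced time
dilation) and ``sigma_d**2 = sigma_s**2 + sigma_m**2`` pools sensory and
reference-memory noise.  The observer answers "same" when |d| < c, a
fixed criterion half-width in natural-log units, except on lapse trials
(probability ``lapse_rate``) where it answers "same" with probability
``lapse_same_prob`` regardless of the stimulus.

Closed form of the same-response probability:

    P(same | test) = (1 - lambda) * [Phi((c - mu_d)/sigma_d)
                                     - Phi((-c - mu_d)/sigma_d)] + lambda * gamma

with mu_d = ln(g * test / reference).  The curve is symmetric in
ln(test) around its peak at test = reference / g, which is therefore the
observer's true point of subjective equality (PSE): a gain of
600/513 puts the PSE at 513 ms against a 600 ms reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import DegenerateModelError, InvalidArgumentError
from .protocol import DecodingSchedule, SessionPlan, build_decoding_schedule

__all__ = [
    "ObserverParams",
    "CohortParams",
    "HeartTraceParams",
    "analytic_p_same",
    "simulate_trials",
    "simulate_cohort",
    "simulate_heart_trace",
    "duration_observer_params",
    "numerosity_observer_params",
    "TRIAL_SPACING_S",
]

#: Nominal spacing between decoding trials, seconds.  66 trials at this
#: pace fill the ~5 min test window the protocol allots.
TRIAL_SPACING_S = 4.5


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the gain + criterion same/different observer.

    ``sensory_noise`` and ``memory_noise`` are standard deviations in
    natural-log units; ``criterion`` is the half-width of the "same"
    region on the same scale.  ``gain_by_phase`` maps phase labels to
    multiplicative gains; phases not listed default to gain 1.
    """

    gain_by_phase: Mapping[str, float] = field(default_factory=dict)
    sensory_noise: float = 0.12
    memory_noise: float = 0.12
    criterion: float = 0.20
    lapse_rate: float = 0.05
    lapse_same_prob: float = 0.5

    def __post_init__(self):
        if self.sensory_noise < 0 or self.memory_noise < 0:
            raise InvalidArgumentError("noise SDs must be >= 0")
        if self.criterion <= 0:
            raise InvalidArgumentError("criterion must be > 0")
        if not 0 <= self.lapse_rate < 1:
            raise InvalidArgumentError("lapse_rate must be in [0, 1)")
        if not 0 <= self.lapse_same_prob <= 1:
            raise InvalidArgumentError("lapse_same_prob must be in [0, 1]")
        if any(g <= 0 for g in self.gain_by_phase.values()):
            raise InvalidArgumentError("gains must be positive")
        object.__setattr__(
            self, "gain_by_phase", MappingProxyType(dict(self.gain_by_phase))
        )

    @property
    def sigma_d(self) -> float:
        """Pooled decision noise in natural-log units."""
        return float(np.hypot(self.sensory_noise, self.memory_noise))

    def with_perturbation(
        self, log_gain_shift: float, log_criterion_shift: float
    ) -> "ObserverParams":
        """Participant-level log-normal perturbation of gain and criterion."""
        gains = {k: v * np.exp(log_gain_shift) for k, v in self.gain_by_phase.items()}
        # the shift applies to phases with implicit gain 1 as well
        gains.setdefault("__default__", float(np.exp(log_gain_shift)))
        return replace(
            self,
            gain_by_phase=gains,
            criterion=self.criterion * float(np.exp(log_criterion_shift)),
        )

    def gain_with_default(self, phase: str) -> float:
        g = self.gain_by_phase.get(phase)
        if g is None:
            g = self.gain_by_phase.get("__default__", 1.0)
        return float(g)


def duration_observer_params(run_gain: float = 600.0 / 513.0) -> ObserverParams:
    """Defaults calibrated for the duration task.

    Noise and criterion give a fitted Weber fraction near 0.25; the
    while-running gain defaults to 600/513 so the RUN_TEST PSE sits at
    513 ms against the 600 ms reference.
    """
    return ObserverParams(gain_by_phase={"RUN_TEST": run_gain})


def numerosity_observer_params(run_gain: float = 1.0) -> ObserverParams:
    """Defaults for the (more precise) numerosity task: Wf near 0.15.

    Running leaves numerosity unaffected, so the run gain defaults to 1.
    """
    return ObserverParams(
        gain_by_phase={"RUN_TEST": run_gain},
        sensory_noise=0.06,
        memory_noise=0.06,
        criterion=0.15,
    )


def analytic_p_same(
    test: float | np.ndarray,
    reference: float,
    params: ObserverParams,
    phase: str = "T1",
) -> float | np.ndarray:
    """Closed-form probability of a "same" response.

    Vectorized over ``test``.  Raises :class:`DegenerateModelError` when
    the pooled decision noise is zero (a deterministic observer has a
    discontinuous response curve and is not supported).
    """
    test = np.asarray(test, dtype=float)
    if np.any(test <= 0) or reference <= 0:
        raise InvalidArgumentError("magnitudes must be positive")
    sigma = params.sigma_d
    if sigma == 0:
        raise DegenerateModelError("sigma_s = sigma_m = 0: deterministic observer")
    g = params.gain_with_default(phase)
    mu_d = np.log(g * test / reference)
    c = params.criterion
    p_inside = ndtr((c - mu_d) / sigma) - ndtr((-c - mu_d) / sigma)
    p = (1.0 - params.lapse_rate) * p_inside + params.lapse_rate * params.lapse_same_prob
    return float(p) if p.ndim == 0 else p


def simulate_trials(
    schedule: DecodingSchedule,
    reference: float,
    params: ObserverParams,
    phase: str = "T1",
    seed: int | np.random.Generator = 0,
    participant_id: str = "P01",
    experiment_kind: str = "duration_while",
    block: int = 1,
    trial_spacing_s: float = TRIAL_SPACING_S,
) -> pd.DataFrame:
    """Simulate one decoding phase; returns the canonical trial table.

    One Bernoulli draw per trial with probability
    :func:`analytic_p_same`; timestamps advance by ``trial_spacing_s``
    from phase onset.  A seed (or an already-seeded Generator) makes the
    output fully deterministic.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mags = np.asarray(schedule.trials, dtype=float)
    p = analytic_p_same(mags, reference, params, phase)
    same = rng.random(mags.size) < p
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "experiment_kind": experiment_kind,
            "block": block,
            "phase": phase,
            "trial_index": np.arange(mags.size),
            "test_magnitude": mags,
            "response": np.where(same, "same", "different"),
            "seconds_since_phase_start": np.arange(mags.size) * trial_spacing_s,
        }
    )


@dataclass(frozen=True)
class CohortParams:
    """Between-participant structure of a simulated cohort.

    ``between_subject_sd`` is the SD (natural-log units) of each
    participant's log-normal perturbation of gain and criterion.  The
    gain perturbation is shared across phases within a participant,
    modelling a stable individual bias that cancels in within-subject
    contrasts.
    """

    n_participants: int = 15
    between_subject_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise InvalidArgumentError("n_participants must be >= 1")
        if self.between_subject_sd < 0:
            raise InvalidArgumentError("between_subject_sd must be >= 0")


def simulate_cohort(
    plan: SessionPlan,
    cohort: CohortParams,
    base_params: ObserverParams,
) -> pd.DataFrame:
    """Simulate a full cohort session; returns one pooled trial table.

    Each participant receives independently shuffled schedules and a
    log-normal perturbation of gain and criterion.  All randomness
    derives from ``cohort.seed`` via hierarchical seed spawning, so the
    same configuration reproduces byte-identical tables.
    """
    root = np.random.SeedSequence(cohort.seed)
    per_participant = root.spawn(cohort.n_participants)
    tables = []
    for i, pss in enumerate(per_participant):
        pid = f"P{i + 1:02d}"
        draw_rng = np.random.default_rng(pss.spawn(1)[0])
        if cohort.between_subject_sd > 0:
            shifts = draw_rng.normal(0.0, cohort.between_subject_sd, size=2)
        else:
            shifts = np.zeros(2)
        params_i = base_params.with_perturbation(shifts[0], shifts[1])
        phase_streams = pss.spawn(plan.n_blocks * plan.n_measurement_phases)
        j = 0
        for block in range(plan.n_blocks):
            for label in plan.measurement_labels:
                sched_seed = int(phase_streams[j].generate_state(1)[0] % (2**31))
                sched = build_decoding_schedule(
                    plan.stimuli,
                    plan.reps_nonreference,
                    plan.reps_reference,
                    seed=sched_seed,
                )
                trial_rng = np.random.default_rng(phase_streams[j])
                j += 1
                tables.append(
                    simulate_trials(
                        sched,
                        plan.stimuli.reference,
                        params_i,
                        phase=label,
                        seed=trial_rng,
                        participant_id=pid,
                        experiment_kind=plan.experiment_kind,
                        block=block + 1,
                    )
                )
    return pd.concat(tables, ignore_index=True)


@dataclass(frozen=True)
class HeartTraceParams:
    """Shape of the simulated heart-rate trace during a running phase.

    A saturating exponential ramp takes the rate from ``resting_hr`` to
    within 1% of ``target_hr`` over ``ramp_duration`` seconds, after
    which the rate fluctuates around the target for
    ``plateau_duration`` seconds (the speed-adjusted steady state).
    """

    resting_hr: float = 87.06
    target_hr: float = 150.9
    ramp_duration: float = 180.0
    plateau_duration: float = 300.0
    trace_noise_sd: float = 2.0
    sampling_rate: float = 1.0

    def __post_init__(self):
        if self.target_hr <= self.resting_hr:
            raise InvalidArgumentError("target_hr must exceed resting_hr")
        if self.ramp_duration <= 0 or self.plateau_duration <= 0:
            raise InvalidArgumentError("durations must be positive")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")


def simulate_heart_trace(
    params: HeartTraceParams, seed: int = 0
) -> pd.DataFrame:
    """Simulate a 1 Hz (by default) heart-rate trace for one run.

    Returns a frame with columns ``t_s`` and ``hr_bpm`` covering
    ramp + plateau.  The exponential time constant is chosen so the
    noise-free ramp lands within 1% of the target at ``ramp_duration``.
    """
    rng = np.random.default_rng(seed)
    n = int(round((params.ramp_duration + params.plateau_duration) * params.sampling_rate))
    t = np.arange(n) / params.sampling_rate
    span = params.target_hr - params.resting_hr
    # residual fraction at end of ramp = 1% of target
    k = np.log(span / (0.01 * params.target_hr))
    hr = params.target_hr - span * np.exp(-k * t / params.ramp_duration)
    hr = hr + rng.normal(0.0, params.trace_noise_sd, size=n)
    return pd.DataFrame({"t_s": t, "hr_bpm": hr})
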