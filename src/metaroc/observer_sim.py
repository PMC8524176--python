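"""Signal-detection observer simulator for staircase-calibrated discrimination.

Simulates observers performing a two-choice (S1 vs S2) discrimination task
whose difficulty is controlled online by a 1-up-2-down multiplicative
staircase on stimulus-onset asynchrony (SOA).  Each trial yields a binary
response, a continuous confidence rating in [0, 1] and a response time,
generated from an (optionally unequal-variance) SDT evidence model in which
confidence is a squashed monotone function of the distance between the
evidence sample and the decision threshold, and log response time decreases
linearly with confidence.

The simulator deliberately includes the pathologies that the preprocessing
stage's exclusion rules are designed to catch: lapses (random response and
confidence), comprehension-check failures, and — through parameter choice —
low accuracy, degenerate confidence distributions and extreme response
times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ObserverParams",
    "StaircaseState",
    "ExperimentDesign",
    "CohortSpec",
    "dprime_from_soa",
    "staircase_update",
    "simulate_trial",
    "simulate_subject",
    "simulate_cohort",
    "TRIAL_COLUMNS",
]

#: Canonical column order of the trial table.
TRIAL_COLUMNS = [
    "subject_id",
    "block",
    "trial_idx",
    "stimulus",
    "response",
    "correct",
    "confidence",
    "rt_ms",
    "soa_ms",
    "comprehension_passed",
]


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of a single simulated observer.

    The evidence axis follows the convention S2 ~ Normal(0, 1),
    S1 ~ Normal(d', sigma_s1); ``sigma_s1 != 1`` produces the
    unequal-variance structure that drives metacognitive asymmetry.

    Parameters
    ----------
    d_max
        Asymptotic sensitivity (d' units) of the psychometric function.
    tau_ms
        Time constant (ms) of the saturating-exponential d'(SOA) link.
    sigma_s1
        Standard deviation of the S1 evidence distribution (S2 fixed at 1).
    criterion_shift
        Additive shift of the decision threshold away from the unbiased
        midpoint d'/2, in evidence units.  Positive values bias the
        observer away from S1 responses.
    conf_gain
        Scaling from |evidence - threshold| to raw confidence.
    metacog_noise_sd
        SD of zero-mean Gaussian noise added to raw confidence before
        squashing; models imperfect metacognitive readout.
    rt_base_ms
        Median response time at confidence 0 (ms).
    rt_conf_slope
        Decrease in log response time per unit confidence.
    rt_noise_sd
        SD of log-RT noise.
    lapse_rate
        Probability that response and confidence are replaced by uniform
        random draws.
    comprehension_fail_prob
        Probability that the subject fails the comprehension check.
    """

    d_max: float = 2.5
    tau_ms: float = 40.0
    sigma_s1: float = 1.0
    criterion_shift: float = 0.0
    conf_gain: float = 1.5
    metacog_noise_sd: float = 0.1
    rt_base_ms: float = 800.0
    rt_conf_slope: float = 0.5
    rt_noise_sd: float = 0.3
    lapse_rate: float = 0.02
    comprehension_fail_prob: float = 0.02

    def __post_init__(self) -> None:
        if self.d_max < 0:
            raise ValueError("d_max must be >= 0")
        if self.tau_ms <= 0:
            raise ValueError("tau_ms must be > 0")
        if self.sigma_s1 <= 0:
            raise ValueError("sigma_s1 must be > 0")
        if not 0 <= self.lapse_rate < 1:
            raise ValueError("lapse_rate must be in [0, 1)")
        if self.rt_base_ms <= 0:
            raise ValueError("rt_base_ms must be > 0")
        if not 0 <= self.comprehension_fail_prob <= 1:
            raise ValueError("comprehension_fail_prob must be in [0, 1]")


@dataclass
class StaircaseState:
    """State of the 1-up-2-down multiplicative SOA staircase."""

    soa_ms: float
    correct_streak: int = 0
    step_factor: float = 0.9
    soa_min_ms: float = 1.0
    soa_max_ms: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.step_factor < 1:
            raise ValueError("step_factor must be in (0, 1)")
        if self.correct_streak not in (0, 1):
            raise ValueError("correct_streak must be 0 or 1")
        if not self.soa_min_ms <= self.soa_ms <= self.soa_max_ms:
            raise ValueError("soa_ms outside [soa_min_ms, soa_max_ms]")


@dataclass(frozen=True)
class ExperimentDesign:
    """Structural parameters of one simulated experiment.

    ``fixed_soa_ms``, when set, disables the staircase and presents every
    trial at that SOA — used for large fixed-difficulty oracle simulations.
    """

    n_subjects: int = 106
    n_trials: int = 96
    n_blocks: int = 6
    soa_start_ms: float = 30.0
    seed: int = 0
    fixed_soa_ms: float | None = None

    def __post_init__(self) -> None:
        if self.n_trials % self.n_blocks:
            raise ValueError("n_trials must be divisible by n_blocks")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Population distribution of observer parameters.

    ``mean`` gives the population-typical observer.  ``dispersion`` maps a
    subset of ``ObserverParams`` field names to between-subject spread:
    log-normal multiplicative scatter (sigma of log) for strictly positive
    parameters, additive normal scatter for ``criterion_shift``.  Fields
    absent from ``dispersion`` are identical across subjects.  Probability
    parameters (``lapse_rate``, ``comprehension_fail_prob``) do not admit
    dispersion.
    """

    mean: ObserverParams = field(default_factory=ObserverParams)
    dispersion: dict[str, float] = field(default_factory=dict)

    _POSITIVE = frozenset(
        {"d_max", "tau_ms", "sigma_s1", "conf_gain", "metacog_noise_sd",
         "rt_base_ms", "rt_conf_slope", "rt_noise_sd"}
    )
    _ADDITIVE = frozenset({"criterion_shift"})

    def __post_init__(self) -> None:
        valid = {f.name for f in fields(ObserverParams)}
        for name, sd in self.dispersion.items():
            if name not in valid:
                raise ValueError(f"unknown ObserverParams field {name!r}")
            if name not in self._POSITIVE | self._ADDITIVE:
                raise ValueError(f"field {name!r} does not admit dispersion")
            if sd <= 0:
                raise ValueError(f"dispersion for {name!r} must be > 0")

    def draw(self, rng: np.random.Generator) -> ObserverParams:
        """Draw one subject's parameters from the population."""
        updates: dict[str, float] = {}
        for name, sd in self.dispersion.items():
            base = getattr(self.mean, name)
            if name in self._ADDITIVE:
                updates[name] = base + rng.normal(0.0, sd)
            else:
                updates[name] = base * math.exp(rng.normal(0.0, sd))
        return replace(self.mean, **updates) if updates else self.mean


def dprime_from_soa(params: ObserverParams, soa_ms: float) -> float:
    """Sensitivity d' at a given SOA via a saturating-exponential link.

    d'(SOA) = d_max * (1 - exp(-SOA / tau)); zero at SOA 0, asymptoting at
    ``d_max``.  Strictly increasing, so the staircase has a well-defined
    fixed point.
    """
    if soa_ms < 0:
        raise ValueError("soa_ms must be >= 0")
    return params.d_max * (1.0 - math.exp(-soa_ms / params.tau_ms))


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """One 1-up-2-down step: easier after an error, harder after two correct.

    An incorrect response divides the SOA by the step factor (longer SOA =
    easier) and resets the streak; a correct response with one already
    banked multiplies by the step factor; a first correct response only
    banks the streak.  The asymptotic accuracy of this rule is
    sqrt(0.5) ~ 0.707 for any monotone psychometric function.
    """
    soa = state.soa_ms
    streak = state.correct_streak
    if not correct:
        soa = soa / state.step_factor
        streak = 0
    elif streak == 1:
        soa = soa * state.step_factor
        streak = 0
    else:
        streak = 1
    soa = min(max(soa, state.soa_min_ms), state.soa_max_ms)
    return StaircaseState(
        soa_ms=soa,
        correct_streak=streak,
        step_factor=state.step_factor,
        soa_min_ms=state.soa_min_ms,
        soa_max_ms=state.soa_max_ms,
    )


def simulate_trial(
    params: ObserverParams,
    stimulus: Literal["S1", "S2"],
    soa_ms: float,
    rng: np.random.Generator,
) -> dict:
    """Simulate one trial: evidence draw, decision, confidence, RT.

    Evidence x ~ Normal(d'(SOA), sigma_s1) under S1 and Normal(0, 1) under
    S2; the observer responds S1 iff x exceeds the threshold
    k = d'/2 + criterion_shift.  Raw confidence is
    conf_gain * |x - k| plus metacognitive noise, squashed to [0, 1) by
    u -> 1 - exp(-max(u, 0)).  log RT = log(rt_base) - slope * confidence
    + noise.  With probability ``lapse_rate`` the response and confidence
    are replaced by uniform draws (RT is then computed from the lapsed
    confidence).
    """
    d = dprime_from_soa(params, soa_ms)
    k = d / 2.0 + params.criterion_shift
    if stimulus == "S1":
        x = rng.normal(d, params.sigma_s1)
    else:
        x = rng.normal(0.0, 1.0)
    response = "S1" if x > k else "S2"

    u = params.conf_gain * abs(x - k)
    if params.metacog_noise_sd > 0:
        u += rng.normal(0.0, params.metacog_noise_sd)
    confidence = max(0.0, 1.0 - math.exp(-max(u, 0.0)))

    if params.lapse_rate > 0 and rng.random() < params.lapse_rate:
        response = "S1" if rng.random() < 0.5 else "S2"
        confidence = rng.random()

    log_rt = (
        math.log(params.rt_base_ms)
        - params.rt_conf_slope * confidence
        + rng.normal(0.0, params.rt_noise_sd)
    )
    return {
        "stimulus": stimulus,
        "response": response,
        "correct": response == stimulus,
        "confidence": confidence,
        "rt_ms": math.exp(log_rt),
        "soa_ms": soa_ms,
    }


def simulate_subject(
    params: ObserverParams,
    design: ExperimentDesign,
    rng: np.random.Generator,
    subject_id: str = "s001",
) -> pd.DataFrame:
    """Simulate one subject's full session as a trial table.

    The stimulus sequence is a random permutation of an exactly balanced
    half-S1 / half-S2 list; SOA evolves by the staircase from
    ``design.soa_start_ms`` (or stays at ``design.fixed_soa_ms``); the
    comprehension-check outcome is drawn once per subject.
    """
    n = design.n_trials
    stimuli = np.array(["S1"] * (n // 2) + ["S2"] * (n - n // 2))
    rng.shuffle(stimuli)
    comprehension_passed = rng.random() >= params.comprehension_fail_prob

    state = StaircaseState(soa_ms=design.soa_start_ms)
    per_block = n // design.n_blocks
    rows = []
    for i, stim in enumerate(stimuli):
        soa = design.fixed_soa_ms if design.fixed_soa_ms is not None else state.soa_ms
        rec = simulate_trial(params, stim, soa, rng)
        rec["subject_id"] = subject_id
        rec["block"] = i // per_block + 1
        rec["trial_idx"] = i + 1
        rec["comprehension_passed"] = comprehension_passed
        rows.append(rec)
        if design.fixed_soa_ms is None:
            state = staircase_update(state, rec["correct"])
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    # spawn_key keyed by index: subject i's stream is invariant to cohort size
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject_index,))
    )


def simulate_cohort(
    cohort: CohortSpec,
    design: ExperimentDesign,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a cohort of subjects with between-subject heterogeneity.

    Per-subject observer parameters are drawn from ``cohort`` inside each
    subject's own RNG stream (derived deterministically from the root
    seed), so a given subject's data are reproducible and independent of
    cohort size.
    """
    root_seed = design.seed if seed is None else seed
    tables = []
    for i in range(design.n_subjects):
        rng = _subject_rng(root_seed, i)
        params = cohort.draw(rng)
        sid = f"s{i + 1:03d}"
        tables.append(simulate_subject(params, design, rng, subject_id=sid))
    if not tables:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(tables, ignore_index=True)
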