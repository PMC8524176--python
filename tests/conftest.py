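import numpy as np
import pandas as pd
import pytest

from metaroc.observer_sim import (
    CohortSpec,
    ExperimentDesign,
    ObserverParams,
    simulate_cohort,
)


def make_table(
    confidences,
    corrects,
    responses=None,
    stimuli=None,
    rts=None,
    subject_id="s001",
    soa=30.0,
):
    """Assemble a minimal valid trial table from per-trial vectors."""
    n = len(confidences)
    corrects = list(corrects)
    if responses is None:
        responses = ["S1"] * n
    if stimuli is None:
        stimuli = [
            r if c else ("S2" if r == "S1" else "S1")
            for r, c in zip(responses, corrects)
        ]
    if rts is None:
        rts = [800.0] * n
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "block": [(i * 6) // n + 1 for i in range(n)],
            "trial_idx": range(1, n + 1),
            "stimulus": stimuli,
            "response": responses,
            "correct": corrects,
            "confidence": confidences,
            "rt_ms": rts,
            "soa_ms": soa,
            "comprehension_passed": True,
        }
    )


def pairwise_concordance(conf_correct, conf_incorrect):
    """Brute-force auROC2 oracle: P(c > i) + 0.5 P(c == i) over all pairs."""
    total = 0.0
    for c in conf_correct:
        for i in conf_incorrect:
            if c > i:
                total += 1.0
            elif c == i:
                total += 0.5
    return total / (len(conf_correct) * len(conf_incorrect))


@pytest.fixture(scope="session")
def symmetric_cohort_table():
    """Equal-variance unbiased cohort under the default study conditions."""
    cohort = CohortSpec(dispersion={"d_max": 0.15, "rt_base_ms": 0.15})
    design = ExperimentDesign(n_subjects=40, seed=101)
    return simulate_cohort(cohort, design)


@pytest.fixture(scope="session")
def unequal_variance_subject():
    """One long fixed-difficulty session from a wide-S1 observer."""
    params = ObserverParams(sigma_s1=1.25, metacog_noise_sd=0.0, lapse_rate=0.0)
    design = ExperimentDesign(
        n_subjects=1, n_trials=20_000, n_blocks=10, fixed_soa_ms=40.0
    )
    rng = np.random.default_rng(42)
    from metaroc.observer_sim import simulate_subject

    return simulate_subject(params, design, rng)
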