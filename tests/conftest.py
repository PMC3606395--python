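import hypothesis
import numpy as np
import pytest

from dspval import CohortConfig, NormativeReference, generate_cohort

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=60
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def reference():
    return NormativeReference.load()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: same structure, smaller groups."""
    return CohortConfig(
        group_sizes={"prevalent_case": 60, "incident_control": 25, "incident_case": 10},
        n_extra_controls=12,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config, reference):
    return generate_cohort(small_config, reference=reference)


@pytest.fixture(scope="session")
def default_cohort(reference):
    """The full 406-subject study-sized cohort with label enforcement."""
    return generate_cohort(CohortConfig(seed=11), reference=reference)


def brute_force_auc(values, labels, direction):
    """Independent pairwise-counting AROC oracle (ties count one half)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    scores = -values if direction == "abnormal_low" else values
    cases, controls = scores[labels], scores[~labels]
    wins = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                wins += 1.0
            elif c == k:
                wins += 0.5
    return wins / (len(cases) * len(controls))
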