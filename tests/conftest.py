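import numpy as np
import pytest

from moswo.pareto import Individual


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_population(objectives, violations=None):
    """Wrap an objective matrix into Individuals with dummy positions."""
    objectives = np.atleast_2d(np.asarray(objectives, dtype=float))
    violations = (
        np.zeros(len(objectives)) if violations is None else np.asarray(violations)
    )
    return [
        Individual(position=np.zeros(2), objectives=f, violation=float(v))
        for f, v in zip(objectives, violations)
    ]


@pytest.fixture
def small_cohort():
    from moswo.therapy import generate_cohort

    return generate_cohort(150, seed=42)
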