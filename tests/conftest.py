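import numpy as np
import pytest

from survsig import Cohort, SimulationSpec, simulate_cohort


@pytest.fixture
def toy_cohort():
    """Five patients exercising both training-filter rules.

    dead 20 d, dead 400 d, duplicate of the 400 d patient, alive 900 d,
    dead 90 d — exactly two (400 d, 90 d) survive the training filter.
    """
    days = np.array([20.0, 400.0, 400.0, 900.0, 90.0])
    return Cohort(
        sample_ids=["p1", "p2", "p2-dup", "p4", "p5"],
        feature_names=["fA", "fB"],
        X=np.arange(10, dtype=float).reshape(5, 2),
        y=days / 30.44,
        censored=np.array([False, False, False, True, False]),
    )


@pytest.fixture
def toy_cohort_with_duplicate(toy_cohort):
    """Same five patients but with a true duplicate identifier."""
    c = toy_cohort
    ids = list(c.sample_ids)
    ids[2] = "p2"
    return Cohort.unchecked(ids, c.feature_names, c.X, c.y, c.censored)


@pytest.fixture(scope="session")
def planted_cohort():
    """Benchmark cohort: 150 x 40 with a 4-feature planted signal."""
    spec = SimulationSpec(seed=11)
    cohort, planted = simulate_cohort(spec)
    return cohort, planted, spec
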