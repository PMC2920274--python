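import numpy as np
import pytest

import conscore as cs


@pytest.fixture(scope="session")
def matrices():
    return cs.default_matrices()


@pytest.fixture(scope="session")
def properties():
    return cs.default_properties()


@pytest.fixture(scope="session")
def worked_example():
    return cs.make_worked_example()


@pytest.fixture(scope="session")
def worked_example_scores(worked_example):
    alignment, annotations = worked_example
    return cs.score_alignment(alignment, annotations)


@pytest.fixture(scope="session")
def small_collection():
    """A small simulated collection shared by comparison/evaluation tests."""
    cfg = cs.SimConfig(
        n_alignments=12,
        N_range=(8, 30),
        L_range=(40, 70),
        catalytic_fraction=0.04,
        rng_seed=7,
    )
    return cs.simulate_collection(cfg)
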