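import numpy as np
import pytest

import microdiet as md


@pytest.fixture(scope="session")
def separable_cohort():
    """Strongly separated cohorts: two taxa shifted by ±2 log2 at low noise."""
    spec = md.default_cohort_spec(
        60, 60, n_taxa=50,
        effect_taxa={"Faecalibacterium": -2.0, "Ruminococcus": 2.0},
        log_sd=0.5, zero_inflation=0.1, seed=11,
    )
    return md.generate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """No group effect at all: labels are exchangeable."""
    spec = md.default_cohort_spec(30, 30, n_taxa=40, effect_taxa={},
                                  zero_inflation=0.1, seed=23)
    return md.generate_cohort(spec)


@pytest.fixture(scope="session")
def trained_model(separable_cohort):
    table, labels = separable_cohort
    return md.train_index_model(table, labels, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def four_leaf_tree():
    from microdiet.io import read_tree
    return read_tree("((A:1,B:1):1,(C:1,D:1):1):0;")
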