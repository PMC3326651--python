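import numpy as np
import pytest

import tissueorigin as to


@pytest.fixture(scope="session")
def cohort():
    """Desk-scale cohort with a strong planted signal (100/100, 2,000
    probesets, 50 markers at 2 log2 units, 61 stable probesets)."""
    params = to.SimParams(n_class_a=100, n_class_b=100, n_probesets=2000,
                          n_markers=50, effect_size=2.0, seed=7)
    return to.simulate_cohort(params)


@pytest.fixture(scope="session")
def standardized(cohort):
    """Stable-probeset reference and standardized log2 matrix."""
    ids = to.select_stable_probesets(cohort.matrix, 61)
    ref = to.fit_reference(cohort.matrix, ids)
    Z = to.standardize_matrix(cohort.matrix, ref)
    labels = cohort.truth["labels"].to_numpy()
    return Z, labels, ref


@pytest.fixture(scope="session")
def split(standardized):
    """Deterministic 140/60 train/test split of the shared cohort."""
    Z, labels, _ = standardized
    rng = np.random.default_rng(0)
    idx = rng.permutation(Z.shape[1])
    return idx[:140], idx[140:]


@pytest.fixture(scope="session")
def trained_model(standardized, split):
    Z, labels, _ = standardized
    train_idx, _ = split
    return to.fit_model(Z.iloc[:, train_idx], labels[train_idx], 50)


@pytest.fixture()
def processing_fixture():
    return to.make_processing_fixture()
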