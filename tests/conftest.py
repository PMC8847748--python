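import numpy as np
import pytest

import cogconv as cc
from cogconv.model import aligned_labels, design_matrices
from cogconv.preprocess import label_conversion, standardize


@pytest.fixture(scope="session")
def small_cohort():
    """Modest default-parameter cohort used across modules."""
    return cc.generate_cohort(cc.CohortSpec(n_patients=120, seed=3))


@pytest.fixture(scope="session")
def planted():
    """Planted-signal cohort: design matrices + aligned labels."""
    spec = cc.planted_signal_spec(n=600, seed=7)
    table = cc.generate_cohort(spec)
    labels = label_conversion(table)
    scaled, _ = standardize(table)
    ids, X, seq, names = design_matrices(scaled)
    y3 = aligned_labels(labels, ids, 3)
    y6 = aligned_labels(labels, ids, 6)
    return dict(table=table, labels=labels, ids=ids, X=X, seq=seq,
                names=names, y3=y3, y6=y6)


@pytest.fixture(scope="session")
def planted_model(planted):
    """A quickly trained model on the planted-signal cohort."""
    cfg = cc.TrainingConfig(epochs=60, seed=0)
    return cc.train_model(planted["X"], planted["seq"], planted["y3"],
                          planted["y6"], cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
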