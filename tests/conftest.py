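"""Shared fixtures: small stable ground truths and simulated table sets.

All fixtures use predominantly competitive interaction draws so that every
simulated community has bounded dynamics.
"""

import numpy as np
import pytest

import micos
from micos.glv import design_test_communities, metabolites_from_abundances


STABLE = dict(a_offdiag_mean=-0.15, a_offdiag_sd=0.25, a_diag_range=(-2.0, -1.0))


@pytest.fixture(scope="session")
def truth5():
    """A 5-species pairwise-only ground truth with bounded dynamics."""
    return micos.generate_ground_truth(5, "none", seed=4, **STABLE)


@pytest.fixture(scope="session")
def tables5(truth5):
    """All 31 distinct 5-species communities simulated on the 8-h grid."""
    designs = design_test_communities(5, n=31, min_richness=1, seed=1)
    times = np.arange(0.0, 48.0 + 1e-9, 8.0)
    return [micos.simulate_glv(truth5, d, times=times, sample_id=f"c{i:02d}")
            for i, d in enumerate(designs)]


@pytest.fixture(scope="session")
def linked_tables5(tables5):
    """The 5-species tables with metabolites driven linearly by abundances."""
    rng = np.random.default_rng(3)
    W = np.abs(rng.normal(1.5, 1.0, (4, 5)))
    return [metabolites_from_abundances(tb, W, mode="instant") for tb in tables5]


@pytest.fixture(scope="session")
def trained_model5(tables5):
    """A small sequence model trained on the 5-species tables."""
    cfg = micos.TrainingConfig(hidden_dim=32, epochs=80, batch_size=10, seed=0)
    return micos.train_teacher_forcing(tables5[:24], cfg)
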