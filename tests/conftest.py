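import numpy as np
import pytest

import resttask as rt
from resttask.pipeline import connectivity_features, observed_task_maps


@pytest.fixture(scope="session")
def default_cohort():
    """Default-scale cohort (m=30, K=8, P=10, n=2000) shared across tests."""
    return rt.generate_cohort(rt.CohortSpec(seed=7))


@pytest.fixture(scope="session")
def default_run(default_cohort):
    """Observed maps, features, leave-one-out predictions and similarity
    matrix for the default cohort, computed once."""
    c = default_cohort
    observed = observed_task_maps(c)
    features = connectivity_features(c)
    preds, betas = rt.run_loo(features, observed, c.parcellation)
    S = rt.similarity_matrix(observed, preds)
    return {"cohort": c, "observed": observed, "features": features,
            "preds": preds, "betas": betas, "S": S}


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, fast cohort for structural and wiring tests."""
    spec = rt.CohortSpec(n_controls=4, n_patients=4, K=3, P=4,
                         width=24, height=18, T_rest=40, seed=5)
    return rt.generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
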