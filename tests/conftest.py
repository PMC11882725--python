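import numpy as np
import pytest

import gsubtract as gs


@pytest.fixture(scope="session")
def toy_truth():
    """Small 3-trait architecture used across module tests."""
    return gs.TruthSet(loadings=[0.6, 0.7, 0.8], h2=[0.2, 0.15, 0.25],
                       n=[20_000] * 3, m=5_000, block_size=10,
                       rho=(0.2, 0.8), seed=7)


@pytest.fixture(scope="session")
def toy_panel(toy_truth):
    panel, draws = gs.simulate_panel(toy_truth)
    return panel, draws


@pytest.fixture(scope="session")
def toy_solution(toy_panel):
    panel, _ = toy_panel
    gc = gs.build_S_V(panel)
    return gc, gs.fit_common_factor(gc)


def exact_factor_gc(loadings, resid, traits=None, v_scale=1e-4):
    """GeneticCovariance holding an exactly model-implied S (for recovery
    checks) with a uniform diagonal V."""
    lam = np.asarray(loadings, float)
    u = np.asarray(resid, float)
    S = np.outer(lam, lam) + np.diag(u)
    k = len(lam)
    p = k * (k + 1) // 2
    from gsubtract.ldsc import genetic_covariance_from_matrices
    return genetic_covariance_from_matrices(S, v_scale * np.eye(p), traits)
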