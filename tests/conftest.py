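"""Shared fixtures: replicate batches of simulate -> infer runs.

The expensive batches are session-scoped so the recovery-benchmark tests
(power of detection, threshold sensitivity) share one set of fits.
"""

from __future__ import annotations

import numpy as np
import pytest

from lrbi import LRBI, LRBIConfig, SimConfig, simulate


def fit_replicates(m: int, N: int, n_reps: int, seed0: int, sigma2: float = 0.01,
                   **config_kwargs):
    """Simulate and fit ``n_reps`` independent acyclic networks."""
    batch = []
    for rep in range(n_reps):
        seed = seed0 + rep
        truth, data = simulate(SimConfig(m=m, N=N, sigma2=sigma2, seed=seed))
        res = LRBI(data, LRBIConfig(seed=seed, **config_kwargs)).fit()
        batch.append((truth, res))
    return batch


@pytest.fixture(scope="session")
def m10_n20_batch():
    """20 replicate fits: 10 genes, 20 samples, noise variance 0.01."""
    return fit_replicates(m=10, N=20, n_reps=20, seed0=1000)


@pytest.fixture(scope="session")
def m30_n20_batch():
    """20 replicate fits: 30 genes, 20 samples, noise variance 0.01."""
    return fit_replicates(m=30, N=20, n_reps=20, seed0=2000)


@pytest.fixture()
def tiny_dataset():
    """Hand-sized dataset with a known generating network (m=3, N=50)."""
    from lrbi import GRNModel, NoiseSpec, generate_expression

    rng = np.random.default_rng(7)
    B = np.array([[0.0, 0.8, 0.0], [0.0, 0.0, -0.6], [0.0, 0.0, 0.0]])
    model = GRNModel(B=B, F=np.eye(3))
    X = rng.choice([0, 1, 2], size=(3, 50), p=[0.25, 0.5, 0.25])
    data = generate_expression(model, X, NoiseSpec(0.01), seed=11)
    return model, data
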