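"""Shared fixtures.

The expensive benchmark fit (the recovery-study panel fitted at the full
4-chain, 1000+1000 sampler settings) is session-scoped so that the
convergence, recovery and posterior-predictive checks all reuse one run.
"""

import numpy as np
import pytest

from coverstate.inference import SamplerConfig, sample_posterior
from coverstate.simulator import SimConfig, simulate


@pytest.fixture(scope="session")
def bench_sim():
    """One panel from the benchmark generating scheme (10 quadrats x 15
    occasions, theta1=-6, drift 0.3, sds 0.5, delta=0.05)."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def bench_fit(bench_sim):
    """Full-scale fit of the benchmark panel: 4 chains, 1000+1000."""
    draws = sample_posterior(
        bench_sim.panel, bench_sim.grid,
        SamplerConfig(chains=4, warmup=1000, draws=1000, seed=11),
    )
    return bench_sim, draws


@pytest.fixture(scope="session")
def tiny_sim():
    """Small model-matched panel for fast sampler tests."""
    return simulate(SimConfig(n_quadrats=4, n_occasions=6, theta1=-1.0,
                              drift=0.2, sigma_theta=0.4, sigma_r=0.5,
                              delta=0.15, seed=42, variant="model"))


@pytest.fixture(scope="session")
def tiny_fit(tiny_sim):
    draws = sample_posterior(
        tiny_sim.panel, tiny_sim.grid,
        SamplerConfig(chains=2, warmup=300, draws=300, seed=5),
    )
    return tiny_sim, draws
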