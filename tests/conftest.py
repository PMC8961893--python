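"""Shared fixtures: small simulated panels built fresh per test session."""

import numpy as np
import pytest

from lcpopgen import SimulationConfig, simulate_panel


@pytest.fixture(scope="session")
def structured_panel():
    """Three diverged subpopulations at high depth: clean structure signal."""
    cfg = SimulationConfig(
        n_subpops=3,
        samples_per_subpop=(60, 60, 60),
        n_snps=2000,
        divergence_F=0.04,
        mean_depth=30.0,
        seed=101,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def null_panel():
    """One homogeneous population at low depth: no structure, no signal."""
    cfg = SimulationConfig(
        n_subpops=3,
        samples_per_subpop=(40, 40, 40),
        n_snps=600,
        divergence_F=0.0,
        mean_depth=3.0,
        seed=202,
    )
    return simulate_panel(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
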