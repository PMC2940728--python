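"""Shared fixtures: small synthetic trajectories generated at test time."""

import numpy as np
import pytest

import difftrace as dt
from difftrace.profiles import ScalarSeries


@pytest.fixture(scope="session")
def brownian_series() -> ScalarSeries:
    """Free diffusion (flat potential), D = 1, 10^5 saved frames."""
    cfg = dt.DoubleWellConfig(barrier_height=0.0, diffusion_coeff=1.0,
                              n_steps=1_000_000, dt_integrate=1e-3,
                              save_stride=10, seed=101)
    return dt.simulate_doublewell(cfg)


@pytest.fixture(scope="session")
def doublewell_series() -> ScalarSeries:
    """Barrier 4 kT, D = 1, 10^6 saved frames at 0.01 tau spacing."""
    cfg = dt.DoubleWellConfig(barrier_height=4.0, well_separation=2.0,
                              n_steps=10_000_000, dt_integrate=1e-3,
                              save_stride=10, seed=11)
    return dt.simulate_doublewell(cfg)


@pytest.fixture(scope="session")
def twostate() -> tuple:
    """Reduced two-state atom trajectory (2x10^5 frames) + latent truth."""
    latent = dt.DoubleWellConfig(barrier_height=4.0, n_steps=400_000,
                                 dt_integrate=1e-3, save_stride=2, seed=7)
    cfg = dt.TwoStateAtomsConfig(latent=latent, noise_amp=0.5,
                                 noise_corr_time=10.0, seed=7)
    return dt.simulate_two_state_atoms(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
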