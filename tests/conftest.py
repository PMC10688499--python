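import numpy as np
import pytest

from chipbind import SystemConfig, SynthesisPattern, build_trap_pattern


@pytest.fixture
def fig2_config():
    """One-box bench-unit kinetics: alpha=1e-3/s, kappa=0.1/s."""
    return SystemConfig(
        alpha_syn=1e-3, kappa_bin=0.1, D_tilde=0.0, dt=0.1,
        n_steps=10, M=1, record_every=1, rate_units="per_time",
    )


@pytest.fixture
def small_chip():
    """A 20-box chip with a central source block and homogeneous traps."""
    config = SystemConfig(
        alpha_syn=0.01, kappa_bin=0.005, D_tilde=0.05, dt=1.0,
        n_steps=2000, M=20, record_every=1, rate_units="per_dt",
    )
    traps = build_trap_pattern(5.0, 20)
    sources = SynthesisPattern.block(9, 12)
    return config, traps, sources


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
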