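import pytest

from permflux import (
    LangevinConfig,
    ThermoState,
    generate_window_set,
    make_membrane_model,
    simulate_window,
)


@pytest.fixture(scope="session")
def thermo():
    return ThermoState()


@pytest.fixture(scope="session")
def ou_window(thermo):
    """Harmonically restrained window on a flat landscape: an exact
    Ornstein-Uhlenbeck process with known variance and force ACF."""
    flat = make_membrane_model("flat")
    cfg = LangevinConfig(timestep=0.01, n_steps=1_000_000,
                         equilibration_steps=5_000, seed=42)
    return simulate_window(flat, 0.0, 1000.0, cfg, thermo)


@pytest.fixture(scope="session")
def flat_window_set(thermo):
    """51 windows x 3 replicates sampled on W == 0; the recovered PMF
    should be statistically indistinguishable from zero."""
    flat = make_membrane_model("flat")
    cfg = LangevinConfig(timestep=0.01, n_steps=40_000,
                         equilibration_steps=4_000, seed=7)
    return generate_window_set(flat, -2.5, 2.5, spacing=0.1, k_u=1000.0,
                               n_replicates=3, config=cfg, thermo=thermo)
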