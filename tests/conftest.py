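import pytest
from hypothesis import settings

from iomrm.synthetic_data import SimulationConfig, simulate_panel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_bundle():
    """A 6-peptide simulation of every design arm, fixed seed."""
    cfg = SimulationConfig(panel_size=6, seed=7)
    records, truth = simulate_panel(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def zero_noise_bundle():
    """Degenerate-noise simulation: every stochastic component switched off."""
    cfg = SimulationConfig(
        panel_size=5,
        seed=11,
        sigma_intra=0.0,
        sigma_inter=0.0,
        sigma_process=0.0,
        noise_floor=0.0,
        site_shift_log2_sd=0.0,
        sample_log2_sd=0.0,
        stability_shift_log2_sd=0.0,
    )
    records, truth = simulate_panel(cfg)
    return cfg, records, truth
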