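import numpy as np
import pytest

from msipipe import PhantomConfig, Species, make_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, drift-free 8x8 phantom with one lesion-confined and one
    tissue-wide species; lock masses off to keep spectra minimal."""
    cfg = PhantomConfig(
        width=8, height=8,
        species_table=[
            Species("tissue_met", 180.05, {"tissue": 100.0, "lesion": 100.0}),
            Species("lesion_met", 200.10, {"lesion": 50.0}),
        ],
        lockmass_list=(),
        drift_ppm_sd=0.0, noise_sd=0.0, baseline_level=0.0, seed=7,
    )
    return cfg, *make_phantom(cfg)


@pytest.fixture(scope="session")
def noisy_phantom():
    """16x16 phantom with drift, noise and a chemical baseline: the
    standard conditions for detection/recalibration round trips."""
    cfg = PhantomConfig(
        width=16, height=16,
        species_table=[
            Species("met_a", 180.05, {"tissue": 120.0, "lesion": 120.0}),
            Species("met_b", 200.10, {"lesion": 150.0}),
        ],
        drift_ppm_sd=5.0, noise_sd=2.0, baseline_level=5.0, seed=11,
    )
    return cfg, *make_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
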