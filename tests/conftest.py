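import numpy as np
import pytest

from mircos.simulate import PeakSpec, SyntheticConfig, default_band_table, generate_spectra


@pytest.fixture
def small_config():
    """A fast two-class campaign: 8+6 samples, coarse grid, 3 replicates."""
    return SyntheticConfig(
        n_per_class={"cultivated": 8, "wild": 6},
        grid=(4000.0, 450.0, 10.0),
        seed=42,
    )


@pytest.fixture
def small_spectra(small_config):
    return generate_spectra(small_config)


@pytest.fixture
def clean_config():
    """Distortion-free single-replicate campaign (deterministic spectra)."""
    return SyntheticConfig(
        n_per_class={"cultivated": 4, "wild": 3},
        grid=(4000.0, 450.0, 10.0),
        noise_sd=0.0,
        baseline_offset_range=(0.0, 0.0),
        baseline_slope_range=(0.0, 0.0),
        scatter_range=(1.0, 1.0),
        replicates=1,
        replicate_jitter_sd=0.0,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
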