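import numpy as np
import pytest

from maldiclust import SimConfig, SpectrumPreprocessor, SpectrumSet, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale study: 3 genera x 2 species x 2 strains, 2 replicates."""
    return SimConfig(
        n_genera=3,
        species_per_genus=2,
        strains_per_species=2,
        replicates=2,
        n_genus_peaks=6,
        n_species_peaks=8,
        sequence_length=400,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_spectrum_set(small_dataset) -> SpectrumSet:
    pre = SpectrumPreprocessor()
    return SpectrumSet(
        pre.transform_spectra(small_dataset.spectra), small_dataset.manifest, pre.grid
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
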