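import numpy as np
import pytest

from mrsport.synthetic import (
    PhantomConfig,
    default_basis,
    default_ppm_axis,
    generate_phantom,
)


@pytest.fixture(scope="session")
def basis():
    return default_basis()


@pytest.fixture(scope="session")
def ppm():
    return default_ppm_axis()


@pytest.fixture(scope="session")
def phantom_wt():
    """One IDH-wildtype glioma phantom with raw spectra (default geometry)."""
    study, truth = generate_phantom(PhantomConfig(subtype="wt", seed=11))
    return study, truth


@pytest.fixture(scope="session")
def phantom_table_only():
    """Fast phantom without spectra, for table-level tests."""
    study, truth = generate_phantom(
        PhantomConfig(subtype="IDH", with_spectra=False, seed=12))
    return study, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
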