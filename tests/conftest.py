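import numpy as np
import pytest

import fragspec as fs


@pytest.fixture(scope="session")
def ethane():
    return fs.parse_molecule("CC")


@pytest.fixture(scope="session")
def methane():
    return fs.parse_molecule("C")


@pytest.fixture(scope="session")
def ethanol():
    return fs.parse_molecule("OCC")


@pytest.fixture(scope="session")
def glucose_formula():
    return fs.Formula.from_string("C6H12O6")


@pytest.fixture(scope="session")
def toy_molecules():
    """20 deterministic small synthetic molecules shared across tests."""
    return fs.enumerate_toy_molecules(max_heavy_atoms=8, n=20, seed=7)


def random_spectrum(rng, resolution=1.0, max_bins=60, max_mz_bin=300):
    n = int(rng.integers(3, max_bins))
    bins = np.sort(rng.choice(np.arange(1, max_mz_bin), size=n, replace=False))
    intens = rng.random(n) + 1e-3
    return fs.Spectrum(bins.astype(np.int64), intens, resolution)
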