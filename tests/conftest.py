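import numpy as np
import pytest

import repclim as rc


@pytest.fixture(scope="session")
def bounds():
    return rc.default_trait_bounds()


@pytest.fixture(scope="session")
def climate_small():
    """2 sites x 6 years = 12 series; enough structure for pipeline tests."""
    return rc.generate_climate_set(n_sites=2, years=range(2000, 2006), seed=7)


@pytest.fixture(scope="session")
def basis_small(bounds):
    return rc.sample_lhs_basis(4, bounds, seed=11)


@pytest.fixture(scope="session")
def yields_small(basis_small, climate_small):
    return rc.yield_matrix(basis_small, climate_small)


@pytest.fixture(scope="session")
def delta_small(climate_small, yields_small):
    return rc.combined_dissimilarity(climate_small, yields_small)


def random_phenotypes(bounds, n, seed):
    rng = np.random.default_rng(seed)
    return [
        rc.Phenotype(bounds.lower + rng.random(bounds.d) * bounds.width, bounds)
        for _ in range(n)
    ]
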