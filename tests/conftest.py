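import numpy as np
import pytest

from fcsubtypes import SyntheticSpec, generate_cross_sectional, make_toy_fixture
from fcsubtypes.residualize import ConfoundRegressor

#: desk-scale analysis threshold for k=3 orthogonal-prototype cohorts
SYNTH_THETA = 0.5
COVARIATES = ["site", "age", "mean_fd"]


@pytest.fixture(scope="session")
def toy():
    """12 individuals x 8 features, 2 near-anticorrelated planted subtypes."""
    fc, labels = make_toy_fixture()
    return fc, labels


@pytest.fixture(scope="session")
def cohort():
    """Default cross-sectional cohort (200 individuals, 2 networks, k=3)."""
    spec = SyntheticSpec(rng_seed=7)
    fc, phen, truth = generate_cross_sectional(spec)
    return spec, fc, phen, truth


@pytest.fixture(scope="session")
def residuals(cohort):
    """Residualized maps of the default cohort, per network."""
    _, fc, phen, _ = cohort
    return {
        net: ConfoundRegressor(covariates=COVARIATES).fit_transform(mat.values, phen)
        for net, mat in fc.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
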