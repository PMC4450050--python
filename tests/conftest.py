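import numpy as np
import pandas as pd
import pytest

import cfdrshare as cf


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def mixture():
    """Reference effect-size mixture: 90% null, non-null SD 3."""
    return cf.NullMixture(pi0=0.9, sigma2=9.0)


@pytest.fixture
def spec_half(mixture):
    """Half-shared-control null spec (rho = 0.5)."""
    return cf.BivariateNullSpec(rho=0.5, mixture=mixture)


@pytest.fixture
def spec_indep(mixture):
    return cf.BivariateNullSpec(rho=0.0, mixture=mixture)


@pytest.fixture
def toy_pairs():
    """Six p value pairs used for hand-counted cFDR checks."""
    return pd.DataFrame({
        "snp_id": list("ABCDEF"),
        "p_i": [0.001, 0.01, 0.05, 0.2, 0.5, 1.0],
        "p_j": [0.01, 0.02, 0.5, 0.03, 0.9, 1.0],
    })


@pytest.fixture(scope="session")
def pleiotropy_sim():
    """A shared-control pair with overlapping non-null SNPs."""
    return cf.simulate_pair(cf.SimulationConfig(
        n_snps=20_000, pi0_i=0.95, pi0_j=0.9, sigma_i=4.0, sigma_j=3.0,
        overlap=0.5, rho=0.5, seed=7,
    ))


@pytest.fixture(scope="session")
def pleiotropy_cfdr(pleiotropy_sim):
    """cfdr table + spec for the session pleiotropy simulation."""
    fit = cf.fit_em(pleiotropy_sim["z_j"].to_numpy())
    spec = cf.BivariateNullSpec(rho=0.5, mixture=fit)
    table = cf.cfdr_table(pleiotropy_sim, spec)
    return table, spec
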