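import numpy as np
import pytest

from dhaflux import FitConfig, KineticParameters, MetaboliteParams, generate_culture
from dhaflux.synthetic import GeneratorConfig, NoiseSpec, wildtype_params


@pytest.fixture(scope="session")
def wt_params() -> KineticParameters:
    return wildtype_params()


@pytest.fixture(scope="session")
def noiseless_culture(wt_params):
    cfg = GeneratorConfig(
        params=wt_params,
        biomass_noise=NoiseSpec(),
        metabolite_noise=NoiseSpec(),
    )
    tc, truth = generate_culture(cfg)
    return tc, truth


@pytest.fixture(scope="session")
def noisy_culture(wt_params):
    tc, truth = generate_culture(GeneratorConfig(params=wt_params, seed=42))
    return tc, truth


@pytest.fixture()
def wt_fit_config():
    return FitConfig(k_fixed={"DHA": 0.0086}, seed=42)


@pytest.fixture(scope="session")
def lagged_params() -> KineticParameters:
    return KineticParameters(
        x0=0.0185,
        mu=0.15,
        t_lag=4.0,
        metabolites=(MetaboliteParams(name="DHA", m0=15.0, q=-5.2, k=0.0086),),
    )


@pytest.fixture(scope="session")
def grid_0_20() -> np.ndarray:
    return np.linspace(0.0, 20.0, 41)
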