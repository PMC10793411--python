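import numpy as np
import pytest

from colonystats import GeneratorParams, SizeRegulationModel, StrategyConfig, generate_dataset

LN2 = float(np.log(2.0))


@pytest.fixture(scope="session")
def adder_unit_config():
    """Dimensionless adder: unit mean added size, one doubling per unit time."""
    return StrategyConfig(
        strategy="adder",
        growth_rate_mu=LN2,
        mean_delta_d=1.0,
        cv2_delta_d=0.1,
        mean_sb=1.0,
        cv2_sb=0.0,
    )


@pytest.fixture(scope="session")
def small_params():
    """A small but realistic synthetic experiment (12 colonies, defaults otherwise)."""
    return GeneratorParams(n_colonies=12, seed=42)


@pytest.fixture(scope="session")
def small_table(small_params):
    return generate_dataset(small_params)


@pytest.fixture(scope="session")
def small_fit(small_table):
    return SizeRegulationModel(small_table.frames).fit(n_boot=200, seed=0)
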