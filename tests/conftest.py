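import numpy as np
import pytest

from smrnet import preprocess, smr, synth


@pytest.fixture(scope="session")
def default_config():
    return synth.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def small_config():
    """Cheap panel: 30 provinces, 8 indicators, 2 years."""
    return synth.SyntheticConfig(
        n_provinces=30,
        n_indicators=8,
        years=(2015, 2016),
        effect_spec={"o3": (0.4, "linear")},
        negative_effect_spec={},
        indicator_correlation=0.0,
        noise_sd=0.1,
        missing_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    panel = synth.generate_panel(small_config)
    mortality = synth.generate_mortality(small_config, panel)
    return panel, mortality


@pytest.fixture(scope="session")
def small_xy(small_config, small_dataset):
    panel, mortality = small_dataset
    table = smr.compute_smr_table(mortality)
    X, y, names = preprocess.assemble(panel, table, 2015)
    return X, y, names


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
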