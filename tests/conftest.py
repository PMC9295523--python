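import pytest

from pprscout.synthetic_data import SyntheticSpec, default_region_pwms
from pprscout.target_prediction import load_code_table, load_reference_predictions


@pytest.fixture(scope="session")
def region_pwms():
    return default_region_pwms()


@pytest.fixture(scope="session")
def code_table():
    return load_code_table()


@pytest.fixture(scope="session")
def reference_predictions():
    """Packaged table of published patterns and predicted targets."""
    return load_reference_predictions()


@pytest.fixture()
def noiseless_spec():
    return SyntheticSpec(seed=7, n_sequences=200, score_noise_sd=0.0)
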