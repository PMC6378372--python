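import numpy as np
import pandas as pd
import pytest

from fingercue.matching_error import baseline_correct, raw_errors
from fingercue.synthetic_data import GeneratorConfig, generate_all, generate_experiment


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def exp1_trials(default_config) -> pd.DataFrame:
    return generate_experiment(default_config, 1, seed=7)


@pytest.fixture(scope="session")
def all_trials(default_config) -> pd.DataFrame:
    return generate_all(default_config, seed=7)


@pytest.fixture(scope="session")
def corrected_errors(all_trials) -> pd.DataFrame:
    return baseline_correct(raw_errors(all_trials))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trial(
    condition="TUP_IDN",
    sense_dy=1.0,
    sense_dz=65.5,
    thumb_fn=4.5,
    index_fn=4.5,
    thumb_ft=3.0,
    index_ft=-3.0,
    **kw,
):
    """Hand-built single trial row for compliance tests."""
    row = {
        "subject_id": "S101",
        "experiment": 1,
        "condition": condition,
        "repetition": 1,
        "sense_dy": sense_dy,
        "hold_dy": sense_dy,
        "sense_dz": sense_dz,
        "thumb_fn": thumb_fn,
        "index_fn": index_fn,
        "thumb_ft": thumb_ft,
        "index_ft": index_ft,
        "qc_pass": pd.NA,
    }
    row.update(kw)
    return row
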