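from pathlib import Path

import pytest

from vancopk.pk_core import CovariateSet, PopulationParams

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def example_dataset_path() -> Path:
    return DATA_DIR / "example_20subjects.csv"


@pytest.fixture()
def median_covariates() -> CovariateSet:
    """A subject at the study's median baseline characteristics."""
    return CovariateSet(
        weight=9.1,
        height=69.7,
        age=13.3,
        sex="female",
        scr=0.16,
        dflt=17.0,
        albumin=3.1,
        alt=54.7,
        underlying_disease="biliary_atresia",
    )


@pytest.fixture()
def final_params() -> PopulationParams:
    """Final-model population parameters (package defaults)."""
    return PopulationParams()
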