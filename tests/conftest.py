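import numpy as np
import pytest
from hypothesis import settings

import whalecost as wc

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")
from whalecost.bioenergetics import (
    WhaleParams,
    krill_from_config,
    load_bioenergetics_config,
)
from whalecost.simulate import load_er_functions


@pytest.fixture(scope="session")
def small_records():
    """A small synthetic tag dataset (~8 deployments) with default parameters."""
    return wc.generate_deployments(wc.GeneratorParams(n_deployments=8), seed=11)


@pytest.fixture(scope="session")
def activity_model(small_records):
    return wc.ActivityModel.fit(small_records, seed=0)


@pytest.fixture(scope="session")
def bio_config():
    return load_bioenergetics_config()


@pytest.fixture(scope="session")
def whale22(bio_config):
    return WhaleParams.from_config(bio_config, length_m=22.0)


@pytest.fixture(scope="session")
def krill_lower(bio_config):
    return krill_from_config(bio_config, "lower")


@pytest.fixture(scope="session")
def krill_upper(bio_config):
    return krill_from_config(bio_config, "upper")


@pytest.fixture(scope="session")
def er_functions():
    return load_er_functions()


@pytest.fixture(scope="session")
def reference_mixture():
    """Depth mixture at the published component values (33/20 and 157/75 m)."""
    return wc.DepthMixture(means=(33.0, 157.0), sds=(20.0, 75.0), weights=(0.5, 0.5))
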