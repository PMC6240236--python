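import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nucscreen import default_channel_spec
from nucscreen.synthdata import default_class_params, sample_two_class

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def channel_spec():
    return default_channel_spec()


@pytest.fixture(scope="session")
def class_params(channel_spec):
    return default_class_params(channel_spec)


@pytest.fixture(scope="session")
def two_class_pops(channel_spec, class_params):
    """Moderate-size pure-class control populations (healthy, progeria)."""
    return sample_two_class(2000, class_params, 1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


@pytest.fixture()
def small_feature_frame(channel_spec, rng):
    """Tiny valid feature table (3 cells, all metrics)."""
    rows = []
    for i in range(3):
        row = {"plate": "P1", "replicate": 1, "well": "B03", "field": 1, "cell_id": i}
        for m in channel_spec.metric_names:
            row[m] = float(rng.normal())
        rows.append(row)
    return pd.DataFrame(rows)
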