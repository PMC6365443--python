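import numpy as np
import pytest

from ctdm.landmark_io import LandmarkConfiguration, ShapeSample
from ctdm.synthetic import default_schema, default_template


@pytest.fixture
def schema():
    return default_schema()


@pytest.fixture
def template():
    return default_template()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tps_text():
    """Three 4-landmark records exercising ID/IMAGE/SCALE keys."""
    return (
        "LM=4\n"
        "0.0 0.0\n"
        "1.0 0.0\n"
        "1.0 1.0\n"
        "0.0 1.0\n"
        "IMAGE=face_a.jpg\n"
        "ID=A\n"
        "LM=4\n"
        "10 4\n"
        "2 2\n"
        "3 1\n"
        "0 0\n"
        "ID=B\n"
        "SCALE=0.5\n"
        "LM=4\n"
        "0.5 0.25\n"
        "1.5 0.25\n"
        "1.0 2.0\n"
        "0.25 1.0\n"
        "ID=C\n"
        "COMMENT=third record\n"
    )


def make_sample(coords_list, groups=None, schema=None, prefix="s"):
    groups = groups or [None] * len(coords_list)
    configs = [
        LandmarkConfiguration(specimen_id=f"{prefix}{i:03d}", coords=c, group=g)
        for i, (c, g) in enumerate(zip(coords_list, groups))
    ]
    return ShapeSample(configurations=configs, schema=schema)


@pytest.fixture
def make_shape_sample():
    return make_sample
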