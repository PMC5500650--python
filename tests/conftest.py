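import numpy as np
import pytest

from netfalff.synthetic import generate_templates
from netfalff.types import VertexTimeSeries


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_templates():
    return generate_templates(400, 3, seed=7)


@pytest.fixture()
def random_scan(rng):
    return VertexTimeSeries(rng.standard_normal((64, 30)) + 100.0, tr=2.0, subject_id="s1")
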