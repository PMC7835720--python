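import numpy as np
import pytest
from hypothesis import settings

from polygrasp.objects import build_object

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def single_cube():
    return build_object([(0, 0, 0)], "wood")


@pytest.fixture
def rod10():
    return build_object([(i, 0, 0) for i in range(10)], "wood", name="rod10")


@pytest.fixture
def rod5():
    return build_object([(i, 0, 0) for i in range(5)], "wood", name="rod5")
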