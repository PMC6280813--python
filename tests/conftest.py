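import numpy as np
import pytest

from balshrink import RestrictedMeanProblem, SphericalFamilySpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def normal_family():
    return SphericalFamilySpec("normal")


@pytest.fixture
def t13_family():
    return SphericalFamilySpec("student_t", nu=13)


@pytest.fixture
def small_problem():
    return RestrictedMeanProblem(
        p=6, q=2, k=10, theta=np.array([1.0, 0.5, -0.3, 0.0, 0.2, -1.0]), sigma2=1.0
    )
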