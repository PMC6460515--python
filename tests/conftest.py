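import numpy as np
import pytest

from multinomogram import (
    Covariate,
    CovariateProfile,
    ModelSpec,
    build_layout,
    build_scoring_chart,
    load_fixture,
)


@pytest.fixture(scope="session")
def delivery_model():
    """The packaged five-category antepartum operative-delivery model."""
    return load_fixture()


@pytest.fixture(scope="session")
def case_profile():
    """The worked hypothetical case: 32 y, 40 wk, nulliparous, male fetus,
    3540 g estimated birthweight, maternal diabetes."""
    return CovariateProfile([32.0, 40.0, 1.0, 0.0, 0.0, 35.4, 1.0])


@pytest.fixture(scope="session")
def toy_model():
    """Small K=3 model with hand-computable points system.

    With x1 in [0, 10] and binary x2, coefficient rows (0.2, 1.0) and
    (-0.1, 2.0), the largest effect span is 2.0 log-odds, so r = 50.
    """
    return ModelSpec(
        categories=("A", "B", "ref"),
        covariates=(
            Covariate("x1", "continuous", "", 0.0, 10.0),
            Covariate("x2", "binary"),
        ),
        intercepts=np.array([-2.0, -1.0]),
        coefficients=np.array([[0.2, 1.0], [-0.1, 2.0]]),
    )


@pytest.fixture(scope="session")
def toy_chart(toy_model):
    return build_scoring_chart(toy_model)


@pytest.fixture(scope="session")
def toy_layout():
    """Hand-checkable layout: h=10, d=10, l in [-5,0], s in [-2,0] gives
    m1=2, m3=5, m2=10/7, d_LO=20/7, o_low=-7."""
    return build_layout(10.0, 10.0, (-5.0, 0.0), (-2.0, 0.0))
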