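import warnings

import pytest

import bifacet as bf
from bifacet.estimation import HeywoodWarning  # noqa: F401  (re-export for tests)


@pytest.fixture(scope="session")
def moments():
    return bf.ability_grades()


@pytest.fixture(scope="session")
def first_order_fit(moments):
    return bf.fit(bf.make_model("fig2b"), moments)


@pytest.fixture(scope="session")
def first_order_regression_fit(moments):
    return bf.fit(bf.make_model("fig2c"), moments)


@pytest.fixture(scope="session")
def s1_fit_an(moments):
    return bf.fit(bf.make_model("fig3b", "AN"), moments)


@pytest.fixture(scope="session")
def s1_regression_fit_an(moments):
    return bf.fit(bf.make_model("fig3c", "AN"), moments)


@pytest.fixture(scope="session")
def free_g_fit(moments):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bf.fit(bf.make_model("fig1b_free_g"), moments)


@pytest.fixture
def two_indicator_config():
    return {
        "mode": "measurement-only",
        "variables": [
            {"name": "Y1", "role": "indicator", "facet": "F"},
            {"name": "Y2", "role": "indicator", "facet": "F"},
        ],
        "factors": [{"name": "F", "kind": "facet", "scaling": "one-loading-fixed"}],
        "loadings": [
            {"var": "Y1", "factor": "F", "status": "fixed", "value": 1.0},
            {"var": "Y2", "factor": "F", "status": "fixed", "value": 1.0},
        ],
    }
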