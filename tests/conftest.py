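import pytest

from dyrknet import (
    Perturbation,
    build_dyrk1a_model,
    concentration_response,
    knockdown_screen,
    run_to_steady_state,
)


@pytest.fixture(scope="session")
def dyrk1a_model():
    return build_dyrk1a_model()


@pytest.fixture(scope="session")
def baseline(dyrk1a_model):
    res = run_to_steady_state(dyrk1a_model)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def dyrk1a_curve(dyrk1a_model):
    """Concentration response of the reference network, 1% increments."""
    return concentration_response(dyrk1a_model, target="DYRK1A", step=0.01)


@pytest.fixture(scope="session")
def ko_screen(dyrk1a_model):
    """Knockout screen in the 100% DYRK1A-knockdown context."""
    return knockdown_screen(dyrk1a_model, context=(Perturbation.knockdown("DYRK1A", 1.0),))
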