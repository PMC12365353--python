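"""Shared fixtures: canonical specs and one cached normal-swallow run."""

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from peristalsim import model_core as mc
from peristalsim import metrics as mx
from peristalsim.dynamics import simulate


@pytest.fixture(scope="session")
def normal_spec():
    """Canonical model with a single swallow at t0 = 1."""
    return mc.default_spec(
        t_end=20.0,
        program=mc.StimulusProgram(events=(mc.SwallowEvent(t0=1.0),)),
    )


@pytest.fixture(scope="session")
def normal_result(normal_spec):
    return simulate(normal_spec, seed=0)


@pytest.fixture(scope="session")
def w_threshold(normal_spec):
    return mx.default_threshold(normal_spec)


@pytest.fixture(scope="session")
def normal_ref():
    return mx.normal_reference()


@pytest.fixture
def body_params():
    return mc.default_body_params()


@pytest.fixture
def les_params():
    return mc.default_les_params()
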