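"""Shared fixtures: reference model, constraint suite, cached dynamics."""

import pytest

from chemoswitch.logic_engine import parse_model
from chemoswitch.ruleset_search import reference_trajectories
from chemoswitch.switch_model import (
    ModelDynamics,
    constraint_suite,
    reference_model,
)


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


@pytest.fixture(scope="session")
def suite():
    return constraint_suite()


@pytest.fixture(scope="session")
def ref_dynamics(ref_model):
    return ModelDynamics(ref_model)


@pytest.fixture(scope="session")
def ref_trajs(ref_model):
    return reference_trajectories(ref_model)


@pytest.fixture
def identity_model():
    """One binary internal variable that copies itself (two fixed points)."""
    return parse_model("var A:2\nrule A = A\n")
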