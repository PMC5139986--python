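"""Shared fixtures: a calibrated default configuration and derived objects.

Session-scoped because calibration (which verifies the directional targets by
steady-state solves) is deterministic and read-only.
"""

import pytest

from fnirsim.config import default_config
from fnirsim.scenarios import standard_templates


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def templates(config):
    return standard_templates(config)


@pytest.fixture(scope="session")
def activation(config, templates):
    """(dHbO2, dHHb) of the model's canonical activation response [uM]."""
    act = templates[0]
    assert act.label == "activation"
    return act.dHbO2, act.dHHb
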