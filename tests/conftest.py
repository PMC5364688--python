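"""Shared fixtures: model-generated targets are computed once per session."""

import numpy as np
import pytest

from oculofit.model import ModelParameters
from oculofit.synthetic import (
    OSCILLATORY_PRESETS,
    SACCADE_PRESET,
    generate_nystagmus_target,
    generate_saccade_targets,
)


@pytest.fixture(scope="session")
def preset() -> ModelParameters:
    """The first frozen oscillatory preset (period ~0.78 s, ~7.8 deg p-p)."""
    return OSCILLATORY_PRESETS[0]


@pytest.fixture(scope="session")
def target_cycle(preset):
    return generate_nystagmus_target(preset)


@pytest.fixture(scope="session")
def saccade_targets():
    return generate_saccade_targets(SACCADE_PRESET)
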