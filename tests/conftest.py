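import numpy as np
import pytest

from smlssi import (
    Scenario,
    make_beam_profile,
    minflux_sequence,
    rastmin_sequence,
)


@pytest.fixture
def beam647():
    return make_beam_profile(647.0, 1.4)


@pytest.fixture
def minflux_scenario(beam647):
    """Reference configuration: MINFLUX, L = 100 nm, N = 500, SBR = 4, c = 1."""
    return Scenario(
        beam=beam647,
        sequence=minflux_sequence(100.0),
        order=1.0,
        N=500,
        SBR=4.0,
        emitter_position=np.zeros(2),
    )


@pytest.fixture
def rastmin_scenario(beam647):
    return Scenario(
        beam=beam647,
        sequence=rastmin_sequence(100.0, 4),
        order=1.0,
        N=500,
        SBR=4.0,
        emitter_position=np.zeros(2),
    )
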