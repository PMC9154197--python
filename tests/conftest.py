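"""Shared fixtures: the two reference oscillators and their iPRCs.

Computing a limit cycle plus its adjoint takes a few seconds, so both
reference parameter points (the fast gamma oscillator at Ie_ext = 10 and
the Hopf-proximal one at Ie_ext = 8.4) are built once per session.
"""

import pytest

from pingctc import ModelParams, find_limit_cycle, solve_adjoint


@pytest.fixture(scope="session")
def params10():
    return ModelParams()  # Ie_ext_bar = 10, Ii_ext_bar = 0


@pytest.fixture(scope="session")
def params84():
    return ModelParams().with_drives(Ie=8.4)


@pytest.fixture(scope="session")
def cycle10(params10):
    cyc = find_limit_cycle(params10)
    assert cyc is not None
    return cyc


@pytest.fixture(scope="session")
def cycle84(params84):
    cyc = find_limit_cycle(params84)
    assert cyc is not None
    return cyc


@pytest.fixture(scope="session")
def iprc10(cycle10):
    return solve_adjoint(cycle10)


@pytest.fixture(scope="session")
def iprc84(cycle84):
    return solve_adjoint(cycle84)
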