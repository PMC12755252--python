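import numpy as np
import pytest

import grnswitch as gs
from grnswitch import Reaction, ReactionNetwork


@pytest.fixture(scope="session")
def toggle():
    return gs.make_toggle()


@pytest.fixture(scope="session")
def pfl():
    return gs.make_pfl()


@pytest.fixture(scope="session")
def phage():
    return gs.make_phage()


@pytest.fixture(scope="session")
def toggle_regions(toggle):
    return gs.make_regions(toggle)


@pytest.fixture(scope="session")
def birth_death():
    """Constant birth at rate 10, unit-rate death: stationary mean 10."""
    return ReactionNetwork(
        species=["Q"],
        reactions=[
            Reaction("birth", "constant", (10.0,), (), (1,)),
            Reaction("death", "linear", (1.0,), (0,), (-1,)),
        ],
        initial_state=[0],
    )


@pytest.fixture(scope="session")
def delayed_birth():
    """Pure delayed production at constant rate, no degradation."""
    return ReactionNetwork(
        species=["Q"],
        reactions=[
            Reaction("birth", "constant", (5.0,), (), (1,), delayed=True, kernel_ref="k"),
        ],
        initial_state=[0],
    )


@pytest.fixture(scope="session")
def toggle_mu3_baseline(toggle, toggle_regions):
    """Fixed-delay (tau=3) toggle residence/attempt baseline, shared by the
    delay-noise sweep and the delay-switching comparisons."""
    from grnswitch.residence import run_residence_cell

    return run_residence_cell(
        toggle,
        kernels={"production": gs.make_kernel("fixed", 3.0)},
        regions=toggle_regions,
        min_residences=24,
        seeds=(31, 32),
        max_events=3 * 10**9,
        want_attempts=True,
    )
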