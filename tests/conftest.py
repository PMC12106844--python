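import numpy as np
import pytest

from colonysim import ParameterSet


@pytest.fixture
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def scaled_params(C_g_init: float, seed: int = 1) -> ParameterSet:
    """Reduced-domain study conditions used for phenomenology runs.

    A 4.8 mm x 1.6 mm agar cross-section keeps the agar glucose reservoir
    large relative to colony demand (as on a real plate) while staying
    tractable on one CPU; h = 8 um resolves the colony's vertical
    nutrient gradients with a few grid rows.
    """
    return ParameterSet().replace(
        domain_width=4800.0, agar_depth=1600.0, air_height=120.0,
        h_grid=8.0, dt_macro=3.0, pde_tol=1e-4,
        C_g_init=C_g_init, seed=seed)


@pytest.fixture(scope="session")
def scaled_run_10():
    """Shared 10 mM scaled simulation (session-scoped; several minutes)."""
    from colonysim import run_simulation

    return run_simulation(scaled_params(10.0), t_end=15.0, snapshot_every=0.5)


@pytest.fixture(scope="session")
def scaled_run_20():
    """Shared 20 mM scaled simulation (session-scoped)."""
    from colonysim import run_simulation

    return run_simulation(scaled_params(20.0), t_end=15.0, snapshot_every=0.5)
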