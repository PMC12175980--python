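import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import flowpet as fp

settings.register_profile(
    "suite", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def htr_schedule():
    return fp.FrameSchedule.htr_early_dynamic()


@pytest.fixture(scope="session")
def default_aif():
    return fp.generate_aif(fp.AIFModelParams())


@pytest.fixture(scope="session")
def presets():
    return fp.region_presets()


@pytest.fixture(scope="session")
def small_grid():
    """Reduced search grid for fast fitting tests (truths drawn on nodes)."""
    return fp.GridConfig(
        k2=np.geomspace(0.05, 2.0, 10),
        tc=np.arange(0.0, 12.0 + 1e-9, 0.5),
        td=np.arange(0.0, 4.0 + 1e-9, 0.5),
    )


@pytest.fixture(scope="session")
def aath_basis_small(default_aif, htr_schedule, small_grid):
    return fp.build_basis(default_aif, htr_schedule, small_grid, "aath")


@pytest.fixture(scope="session")
def s1tc_basis_small(default_aif, htr_schedule, small_grid):
    return fp.build_basis(default_aif, htr_schedule, small_grid, "s1tc")


@pytest.fixture(scope="session")
def preset_exact_grid(presets):
    """Grid whose nodes contain the first three regional presets exactly,
    so noiseless phantom/recovery checks are limited only by round-off."""
    sub = presets[:3]
    return fp.GridConfig(
        k2=np.array(sorted({p.k2 for p in sub} | {0.1, 1.0})),
        tc=np.array(sorted({p.Tc for p in sub} | {0.0, 2.0, 9.0})),
        td=np.array([0.0, 1.0]),
    )
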