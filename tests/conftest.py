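import numpy as np
import pytest

from reachsketch import (
    LevelBounds,
    PRESETS,
    layout_monitor,
    reference_bounds,
)


@pytest.fixture(scope="session")
def layout():
    return layout_monitor(1600, 900)


@pytest.fixture(scope="session")
def canonical_bounds():
    """Fixed per-level bands anchored at the pattern's geometric length.

    Band (0.9, 1.3) around the ideal 642 px polyline: an ideal sketch has
    ratio 1.0 and is unpenalized, which the engine-level expectations
    (perfect source scores 100) rely on.
    """
    return {
        lvl: LevelBounds(lvl, traj_length_opt_px=642.0, r_min=0.9, r_max=1.3)
        for lvl in range(1, 7)
    }


@pytest.fixture(scope="session")
def cohort_bounds():
    """Bands estimated from the simulated unimpaired reference cohort."""
    return reference_bounds()


@pytest.fixture(scope="session")
def perfect_params():
    """Deterministic noise-free virtual user: ideal sketches."""
    from reachsketch import VirtualUserParams
    return VirtualUserParams(skill=1.0, jitter_sd_px=0.0, overshoot_frac=0.0,
                             miss_prob=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
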