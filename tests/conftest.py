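import numpy as np
import pytest

from coilquant import (
    Burst,
    DishSpec,
    EnhanceConfig,
    HoughConfig,
    make_schedule,
    simulate_video,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dish():
    """4-egg, 20 s darkfield dish with a fixed schedule; shared ground truth
    for detection, tracing, and recovery tests."""
    spec = DishSpec(
        n_eggs=4, frame_shape=(160, 160), duration_s=20.0, fps=30.0, seed=3
    )
    schedule = make_schedule(spec, coils_per_embryo=[2, 3, 2, 3])
    stack, truth = simulate_video(spec, schedule)
    return stack, truth


@pytest.fixture(scope="session")
def small_dish_noisy():
    spec = DishSpec(
        n_eggs=4, frame_shape=(160, 160), duration_s=20.0, fps=30.0, seed=3,
        noise_sigma=1.0,
    )
    schedule = make_schedule(spec, coils_per_embryo=[2, 3, 2, 3])
    stack, truth = simulate_video(spec, schedule)
    return stack, truth


@pytest.fixture(scope="session")
def dish_hough_config():
    """Hough search matched to the synthetic dishes (radii 18-24 px)."""
    return HoughConfig(r_min=16, r_max=26, blur_sigma=2.0)


def fig4_style_trace(n=3600, centers=(300, 800, 1300, 1320, 1900, 2500, 3100),
                     half_width=3, height=1.0):
    """Zero-baseline trace with narrow triangular bumps: the worked example
    used for the 7-vs-6 peak-distance behaviour."""
    v = np.zeros(n)
    for c in centers:
        for k in range(-half_width, half_width + 1):
            v[c + k] = max(v[c + k], height * (1 - abs(k) / (half_width + 1)))
    return v
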