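import numpy as np
import pytest

import microcirc as mc


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return np.logical_and(a, b).sum() / union if union else 1.0


@pytest.fixture(scope="session")
def kymo_slow():
    """200 Hz capillary movie at 1.1 mm/s (10% contrast noise, seed 1)."""
    cfg = mc.KymographSimConfig(n_frames=2000, frame_rate=200.0, pixel_size=0.5,
                                rbc_speed=1.1, hematocrit=0.3, rbc_length=6.0,
                                noise_sd=8.0, seed=1)
    return mc.make_kymograph_movie(cfg)


@pytest.fixture(scope="session")
def kymo_fast():
    """Same conditions at 5.2 mm/s, seed 2."""
    cfg = mc.KymographSimConfig(n_frames=2000, frame_rate=200.0, pixel_size=0.5,
                                rbc_speed=5.2, hematocrit=0.3, rbc_length=6.0,
                                noise_sd=8.0, seed=2)
    return mc.make_kymograph_movie(cfg)


@pytest.fixture(scope="session")
def hyperemia_default():
    """Two-stimulus (30 s / 65 s) awake-protocol movie, 15% / 12% dilation."""
    cfg = mc.HyperemiaSimConfig(seed=11)
    stack, truth = mc.make_hyperemia_movie(cfg)
    return cfg, stack, truth


def capillary_center_row(truth: mc.SimulationTruth) -> int:
    lo, hi = truth.params["capillary_rows"]
    return (lo + hi) // 2
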