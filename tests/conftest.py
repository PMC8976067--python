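import numpy as np
import pytest

from phasortrack.phasor import TCSPCStack
from phasortrack.synthetic import SceneConfig, generate_flim_scene

PERIOD = 12.5
NBINS = 256
OMEGA = 2 * np.pi / PERIOD


def make_stack(counts: np.ndarray, period: float = PERIOD) -> TCSPCStack:
    counts = np.asarray(counts, dtype=float)
    return TCSPCStack(counts, period, period / counts.shape[2])


@pytest.fixture(scope="session")
def small_scene():
    """9-cell homogeneous scene at f_bound 0.8, moderate photons."""
    cfg = SceneConfig(n_cells=9, f_bound=0.8, photons_per_cell=3e4, seed=11)
    stack, truth = generate_flim_scene(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def hoechst_scene():
    """Scene with bright Hoechst nuclei for thresholding tests."""
    cfg = SceneConfig(
        n_cells=12, f_bound=0.8, photons_per_cell=3e4, hoechst=True, seed=13
    )
    stack, truth = generate_flim_scene(cfg)
    return cfg, stack, truth
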