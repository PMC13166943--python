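import numpy as np
import pytest

from mifquant import generate_scene, preset_spec


def count_loop(*masks) -> int:
    """Naive nested-loop pixel-counting oracle: pixels true in every mask."""
    h, w = masks[0].shape
    n = 0
    for i in range(h):
        for j in range(w):
            if all(m[i, j] for m in masks):
                n += 1
    return n


@pytest.fixture(scope="session")
def small_scene():
    """A small, quick, deterministic scene with moderate marker expression."""
    spec = preset_spec("moderate", seed=42, height=128, width=128, n_cells=6)
    return generate_scene(spec)


@pytest.fixture
def mask_rng():
    return np.random.default_rng(2024)
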