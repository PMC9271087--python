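import numpy as np
import pytest

from bacteval import GrayImage, InstanceLabelMap, SceneSpec, generate_scene


@pytest.fixture
def small_scene():
    """A deterministic 10-cell non-touching rod scene with its clean image."""
    clean, labels = generate_scene(SceneSpec(n_cells=10, seed=1))
    return clean, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def perturbed_prediction(labels: InstanceLabelMap, seed: int) -> InstanceLabelMap:
    """A plausible 'network output': ground truth with objects shifted,
    dropped, or duplicated, for exercising matching code."""
    rng = np.random.default_rng(seed)
    arr = labels.labels
    out = np.zeros_like(arr)
    next_id = 1
    for lab in np.unique(arr):
        if lab == 0:
            continue
        mask = arr == lab
        action = rng.random()
        if action < 0.15:
            continue  # dropped object
        dy, dx = rng.integers(-2, 3, size=2)
        shifted = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
        out[shifted & (out == 0)] = next_id
        next_id += 1
        if action > 0.9:  # spurious extra detection next to the object
            dup = np.roll(shifted, 5, axis=1)
            out[dup & (out == 0)] = next_id
            next_id += 1
    return InstanceLabelMap(out)
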