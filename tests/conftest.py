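import numpy as np
import pytest

from nervemosaic.synth import PhantomSpec, generate_phantom_sequence, generate_scene
from nervemosaic.trace import make_training_candidates, train_classifier


@pytest.fixture(scope="session")
def small_scene():
    """A 3×3-raster scene with ground truth, shared across tests."""
    spec = PhantomSpec(frame_grid=(3, 3), seed=7)
    scene, truth = generate_scene(spec)
    return spec, scene, truth


@pytest.fixture(scope="session")
def small_sequence():
    """A small distorted frame sequence with truth (2×2 raster)."""
    spec = PhantomSpec(frame_grid=(2, 2), frame_overlap_frac=0.4,
                       motion_amplitude_px=2.0, noise_sigma=0.02,
                       defocus_frames_frac=0.0, seed=3)
    frames, truth, scene = generate_phantom_sequence(spec)
    return spec, frames, truth, scene


@pytest.fixture(scope="session")
def nerve_classifier():
    """Phantom-trained nerve/other SVM (expensive: session scope)."""
    candidates = make_training_candidates(seed=1234, n_scenes=2)
    return train_classifier(candidates, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
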