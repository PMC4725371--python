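import numpy as np
import pytest

import avmvpa as m

SMALL_GRID = (14, 14, 8)
SMALL_ROIS = {
    "gender_1": 10,
    "emotion_1": 10,
    "het_left_stg": 12,
    "het_right_stg": 12,
    "het_left_prc": 12,
    "het_right_prc": 12,
}

TINY_GRID = (10, 10, 6)
TINY_ROIS = {
    "gender_1": 8,
    "emotion_1": 8,
    "het_left_stg": 10,
    "het_right_stg": 10,
    "het_left_prc": 10,
    "het_right_prc": 10,
}


@pytest.fixture(scope="session")
def small_phantom():
    return m.make_phantom(SMALL_GRID, SMALL_ROIS, seed=11)


@pytest.fixture(scope="session")
def tiny_phantom():
    return m.make_phantom(TINY_GRID, TINY_ROIS, seed=5)


@pytest.fixture(scope="session")
def default_model():
    return m.NeuralModel()


@pytest.fixture(scope="session")
def null_model():
    """No class information, no coupling: pure evoked + noise."""
    return m.NeuralModel(class_contrast=0.0, coupling_strength=0.0)


@pytest.fixture(scope="session")
def gender_av_run(small_phantom, default_model):
    design = m.build_run_design("gender", "AV", seed=21)
    return m.simulate_run(design, small_phantom, default_model, seed=31)


@pytest.fixture(scope="session")
def gender_av_patterns(gender_av_run):
    return m.extract_patterns(m.preprocess_run(gender_av_run))


def make_pattern_set(rng, n_voxels=60, signal=0.0, grid=(8, 8, 4)):
    """Synthetic TrialPatternSet: 10 block-folds of 8 trials, 4/4 balanced
    in both label dimensions, optional gender signal on half the voxels."""
    design = m.build_run_design("bifeature", "AV", seed=int(rng.integers(2**31)))
    gender = design.labels("gender")
    emotion = design.labels("emotion")
    coords = np.argwhere(np.ones(grid, dtype=bool))[:n_voxels]
    X = rng.standard_normal((80, n_voxels))
    if signal:
        X[:, : n_voxels // 2] += signal * (1 - 2 * gender)[:, None]
    return m.TrialPatternSet(
        patterns=X,
        gender_labels=gender,
        emotion_labels=emotion,
        fold_assignment=design.block_index(),
        voxel_index=coords,
        mask_shape=grid,
    )
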