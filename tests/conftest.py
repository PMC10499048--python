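import numpy as np
import pytest

from leafrefine.synthetic import PerturbSpec, SceneConfig, generate_scenes, mock_predict


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 3-leaf scene with no occlusion."""
    cfg = SceneConfig(
        image_size=(96, 96),
        n_leaves=(3, 3),
        leaf_size=(8, 14),
        occlusion_probability=0.0,
        blur_fraction=0.0,
        background="flat",
        seed=7,
    )
    bundle, ledger = generate_scenes(cfg, 1)
    return bundle, ledger


@pytest.fixture(scope="session")
def cluttered_bundle():
    """A 5-image default-condition dataset with occlusion and blur."""
    bundle, ledger = generate_scenes(SceneConfig(seed=42), 5)
    return bundle, ledger


@pytest.fixture(scope="session")
def noisy_predictions(cluttered_bundle):
    bundle, _ = cluttered_bundle
    spec = PerturbSpec(
        translation=2,
        morph_pixels=-1,
        drop_probability=0.15,
        spurious_rate=0.8,
        tp_score_range=(0.55, 1.0),
    )
    return mock_predict(bundle, spec, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
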