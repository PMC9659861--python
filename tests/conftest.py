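import numpy as np
import pytest

from mcvit.cast import CASTConfig
from mcvit.synthetic import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_cast_config():
    """Desk-scale architecture: same topology as the full model, small dims."""
    return CASTConfig(
        stage_dims=(16, 32, 64), stage_heads=(2, 4, 8), stage_mlp_ratios=(2, 2, 2),
        img_sizes=(16, 32, 64), stage1_patch=(2, 4, 8), window=4,
        sr_ratios=(2, 2, 1), embed_dim_out=48, n_classes=10)


@pytest.fixture
def small_synth_config():
    return SynthConfig(scene_size=64, patches_per_wsi=16, n_wsis_per_type=2)


@pytest.fixture
def tiny_triplet_batch(small_synth_config, rng):
    from mcvit.synthetic import make_triplet, render_scene

    imgs = {"img10": [], "img20": [], "img40": [], "label": []}
    for lab in (0, 4, 9):
        t = make_triplet(render_scene(lab, rng, small_synth_config), lab)
        imgs["img10"].append(t.img10)
        imgs["img20"].append(t.img20)
        imgs["img40"].append(t.img40)
        imgs["label"].append(lab)
    return {k: np.asarray(v) for k, v in imgs.items()}
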