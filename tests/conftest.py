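import numpy as np
import pytest

from shootscan import AnalysisConfig, analyze_image
from shootscan import fixtures as fx

from helpers import SCENE_CORNER_FRAC


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig(corner_window_frac=SCENE_CORNER_FRAC)


@pytest.fixture(scope="session")
def coleoptile_cfg():
    return AnalysisConfig(plant_type="coleoptile", corner_window_frac=SCENE_CORNER_FRAC)


@pytest.fixture(scope="session")
def two_leaf_spec():
    rng = np.random.default_rng(2024)
    return fx.random_seedling_spec(rng, 2, base=(1080, 800))


@pytest.fixture(scope="session")
def two_leaf_scene(two_leaf_spec):
    scene = fx.SceneSpec(seed=7)
    img, truth = fx.make_seedling_scene([two_leaf_spec], scene)
    return img, truth


@pytest.fixture(scope="session")
def two_leaf_result(two_leaf_scene, cfg):
    img, _ = two_leaf_scene
    return analyze_image(img, cfg)


@pytest.fixture(scope="session")
def coleoptile_scene():
    rng = np.random.default_rng(99)
    spec = fx.random_coleoptile_spec(rng, base=(880, 800))
    scene = fx.SceneSpec(seed=13, height=1000)
    img, truth = fx.make_coleoptile_scene([spec], scene)
    return img, truth


@pytest.fixture(scope="session")
def coleoptile_result(coleoptile_scene, coleoptile_cfg):
    img, _ = coleoptile_scene
    return analyze_image(img, coleoptile_cfg)
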