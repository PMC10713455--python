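import numpy as np
import pytest

from emcaps.core import BarcodeClass, PixelScale, class_templates
from emcaps.segment import MatchedFilterEngine
from emcaps.simulate import SceneSpec, render_scene


@pytest.fixture(scope="session")
def scale():
    return PixelScale()


@pytest.fixture(scope="session")
def templates(scale):
    return class_templates(scale)


@pytest.fixture(scope="session")
def engine(templates, scale):
    return MatchedFilterEngine(templates, scale)


@pytest.fixture(scope="session")
def scene_factory(scale):
    """Render small scenes on demand; noiseless by default for round trips."""

    def make(classes=(BarcodeClass.QT_1M,), n_each=1, size=(160, 160), seed=0,
             noiseless=True, **kw):
        defaults = dict(noise_sigma=0.0, texture_sigma=0.0, radius_jitter=0.0) \
            if noiseless else {}
        defaults.update(kw)
        spec = SceneSpec(image_size_px=size, scale=scale,
                         particles=tuple((c, n_each) for c in classes),
                         seed=seed, **defaults)
        return render_scene(spec)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
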