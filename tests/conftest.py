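import numpy as np
import pytest

from fruitseg.fixtures import IlluminationSpec, SceneSpec, generate_dataset
from fruitseg.training import fit
from fruitseg.tuning import TuningResult, sample_light_levels, tune_light_thresholds

# Small canvases keep the unit suite fast; zone edges (1/2, 3/4) stay aligned
# with the quadrant splitting at this size.
SMALL = dict(size=(128, 128), n_fruits=3, axis_range=(12.0, 18.0))


def quick_fit(images, space, std_stop=10.0):
    """Tune the light cutoffs on the given images and fit a model."""
    levels = sample_light_levels(im.rgb for im in images)
    t1, t2 = tune_light_thresholds(levels)
    return fit(images, TuningResult(t1=t1, t2=t2, std_stop=std_stop), space)


@pytest.fixture(scope="session")
def flat_dataset():
    """Separable red-on-green scenes under uniform illumination."""
    spec = SceneSpec(
        **SMALL, illumination=IlluminationSpec(min_gain=1.0, max_gain=1.0), seed=7
    )
    return generate_dataset(spec, 8)


@pytest.fixture(scope="session")
def gradient_dataset():
    """Same scenes under a strong three-zone illumination gradient."""
    spec = SceneSpec(
        **SMALL,
        illumination=IlluminationSpec(min_gain=0.2, max_gain=1.2, zones=3),
        seed=11,
    )
    return generate_dataset(spec, 8)


@pytest.fixture(scope="session")
def flat_model_rgb(flat_dataset):
    return quick_fit(flat_dataset, "rgb")


@pytest.fixture(scope="session")
def gradient_model_rgb(gradient_dataset):
    return quick_fit(gradient_dataset, "rgb")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
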