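import numpy as np
import pytest

from spagen import effunet, geometry, model, synth


@pytest.fixture(scope="session")
def concentric_circles():
    """Raster mask of concentric circles, cup radius 40 inside disc radius 80."""
    cfg = synth.SynthMaskConfig(
        image_size=(200, 200),
        disc=geometry.Ellipse((100.0, 100.0), (80.0, 80.0)),
        cup=geometry.Ellipse((100.0, 100.0), (40.0, 40.0)),
    )
    return synth.render_masks(cfg)


@pytest.fixture(scope="session")
def training_cohort():
    """n = 500 labeled eyes simulated from the reference generating truth."""
    return synth.sample_profiles(synth.SynthProfileConfig(n_eyes=500, seed=42))


@pytest.fixture(scope="session")
def fitted_model(training_cohort):
    return model.fit_ml(list(training_cohort), model.ModelConfig())


@pytest.fixture(scope="session")
def pseudo_fundus_pair():
    """One pseudo-fundus image with its ground-truth mask at 96 x 96."""
    cfg = synth.SynthMaskConfig(
        image_size=(128, 128),
        disc=geometry.Ellipse((64.0, 64.0), (40.0, 34.0)),
        cup=geometry.Ellipse((64.0, 64.0), (20.0, 17.0)),
    )
    mask, _ = synth.render_masks(cfg)
    img = synth.render_pseudo_fundus(mask, seed=3)
    image, labels = effunet.preprocess_image(img, size=(96, 96), mask=mask.pixels)
    return image, labels


@pytest.fixture(scope="session")
def overfit_run(pseudo_fundus_pair):
    """Overfit the network on the single pseudo-fundus image (< 200 steps)."""
    image, labels = pseudo_fundus_pair
    net = effunet.build_network(seed=0)
    spec = effunet.TrainSpec(epochs=80, learning_rate=3e-3, seed=0)
    net, trace = effunet.train_segmentation(net, image, labels, spec)
    return net, image, labels, trace
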