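import numpy as np
import pytest

from mgp import synthetic as syn
from mgp.classifiers import CNNModel, CNNSpec

STRONG_MIX = {"mirror": ("uniform", 0.85, 1.0), "glass": ("uniform", 0.0, 0.15)}


@pytest.fixture(scope="session")
def strong_cue_dataset():
    """Strongly cued mirror/glass renderings (all cues on)."""
    specs = syn.generate_specs(60, STRONG_MIX, master_seed=11)
    images = syn.render_specs(specs)
    labels = np.array([s.true_class for s in specs])
    return specs, images, labels


GRADIENT_GAINS = syn.CueGains(
    gradient=0.3, contrast=0.0, saturation=0.0, luminance=0.0
)
SPATIAL_GAINS = syn.CueGains(
    gradient=0.0, contrast=0.0, saturation=0.0, luminance=0.0,
    top_luminance=0.2, bottom_saturation=0.6,
)


@pytest.fixture(scope="session")
def gradient_cue_dataset():
    """Renderings whose only class cue is the vertical luminance gradient
    (zero-mean: flipping inverts the cue)."""
    specs = syn.generate_specs(60, STRONG_MIX, master_seed=12)
    images = syn.render_specs(specs, GRADIENT_GAINS)
    labels = np.array([s.true_class for s in specs])
    return specs, images, labels


@pytest.fixture(scope="session")
def spatial_cue_dataset():
    """Renderings with one-sided vertical cues (mirror: bright upper
    half; glass: saturated lower half)."""
    specs = syn.generate_specs(80, STRONG_MIX, master_seed=12)
    images = syn.render_specs(specs, SPATIAL_GAINS)
    labels = np.array([s.true_class for s in specs])
    return specs, images, labels


@pytest.fixture(scope="session")
def trained_gap_model(spatial_cue_dataset):
    """GAP-head CNN trained on the one-sided spatial cues (CAM tests)."""
    _, images, labels = spatial_cue_dataset
    model = CNNModel(CNNSpec(depth=3, head="gap"), seed=3, max_epochs=10)
    model.fit(images, labels)
    return model


@pytest.fixture(scope="session")
def trained_gradient_model(gradient_cue_dataset):
    """Dense-head CNN trained on the pure-gradient cue (inversion tests)."""
    _, images, labels = gradient_cue_dataset
    model = CNNModel(CNNSpec(depth=2), seed=5, max_epochs=8)
    model.fit(images, labels)
    return model


@pytest.fixture(scope="session")
def trained_dense_model(strong_cue_dataset):
    _, images, labels = strong_cue_dataset
    model = CNNModel(CNNSpec(depth=2), seed=6, max_epochs=8)
    model.fit(images, labels)
    return model
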