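import numpy as np
import pytest
from hypothesis import settings

from spocflow import spoc, synthgen

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def small_scene():
    """A cheap planted scene: 8 channels, 200 epochs, strong comodulation."""
    scene = synthgen.SyntheticScene(
        n_channels=8,
        n_epochs=200,
        sampling_rate=200.0,
        epoch_length=0.75,
        sources=[synthgen.SourceSpec(comodulation_r=0.9)],
        noise_power=0.1,
        seed=1,
    )
    epochs, z, patterns = synthgen.generate_scene(scene)
    return epochs, z, patterns


@pytest.fixture
def small_null_scene():
    """Same geometry but the source power is independent of the target."""
    scene = synthgen.SyntheticScene(
        n_channels=8,
        n_epochs=200,
        sampling_rate=200.0,
        epoch_length=0.75,
        sources=[synthgen.SourceSpec(comodulation_r=0.0)],
        noise_power=0.1,
        seed=2,
    )
    epochs, z, patterns = synthgen.generate_scene(scene)
    return epochs, z, patterns


@pytest.fixture
def small_covs(small_scene):
    epochs, z, patterns = small_scene
    return spoc.epoch_covariances(epochs), z, patterns


def make_scene(seed, n_channels=8, n_epochs=200, r=0.9, noise=0.1, **kw):
    scene = synthgen.SyntheticScene(
        n_channels=n_channels,
        n_epochs=n_epochs,
        sampling_rate=200.0,
        epoch_length=0.75,
        sources=[synthgen.SourceSpec(comodulation_r=r)],
        noise_power=noise,
        seed=seed,
        **kw,
    )
    return synthgen.generate_scene(scene)
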