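import numpy as np
import pytest

import mbrainseg as mb


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, bias-free phantom with its exact multi-label mask."""
    spec = mb.PhantomSpec(noise_sigma=0.0, bias_amplitude=0.0, seed=1)
    return mb.generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-condition phantom (noise + bias field)."""
    return mb.generate_phantom(mb.PhantomSpec(seed=2))


@pytest.fixture()
def sphere_mask():
    """Binary sphere of radius 10 voxels in a 32^3 unit-spacing grid."""
    n = 32
    idx = np.indices((n, n, n))
    c = (n - 1) / 2
    sphere = ((idx - c) ** 2).sum(axis=0) <= 10.0**2
    return mb.LabelMask(sphere.astype(np.int32), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A small network memorizing one staged phantom; reused by pipeline tests.

    Trained at 32x32x16 / depth 2 so the fixture stays cheap; accuracy is
    checked by the dedicated memorization test, not here.
    """
    from mbrainseg.nn import NetworkConfig, TrainConfig, build_model, train

    spec = mb.PhantomSpec(seed=7)
    vol, mask = mb.generate_phantom(spec)
    cfg = mb.StagingConfig(target_spacing=(0.35, 0.35, 0.7), target_shape=(32, 32, 16))
    img, msk = mb.stage_pair(vol, mask, cfg)
    dataset = [(img.data, msk.data)]
    model = build_model(NetworkConfig(depth=2, base_filters=8, dropout_rate=0.0, seed=0))
    tcfg = TrainConfig(initial_lr=2e-3, max_epochs=60, seed=0)
    model, history = train(model, dataset, tcfg)
    return model, cfg, history
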