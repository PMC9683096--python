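import numpy as np
import pytest

import tandemflow as tf


@pytest.fixture(scope="session")
def straight_tube():
    """Clean straight tube, radius 2 mm, length 20 mm, no bulges."""
    spec = tf.PhantomSpec(
        centerline_kind="line", length=20.0, radius=2.0,
        circumferential_resolution=32, axial_resolution=40,
    )
    return tf.make_phantom(spec)


@pytest.fixture(scope="session")
def tandem_phantom():
    """Arc-centerline tandem phantom used by restoration tests."""
    spec = tf.PhantomSpec(
        centerline_kind="arc", length=40.0, radius=2.0,
        bulges=[tf.Bulge(14.0, 2.2, 2.8, [0, 0, 1]), tf.Bulge(26.0, 2.8, 3.2, [0, 0, 1])],
        circumferential_resolution=48, axial_resolution=140,
    )
    return tf.make_phantom(spec)


@pytest.fixture(scope="session")
def fine_phantom():
    """Finer tandem phantom for ROI footprint comparisons."""
    spec = tf.PhantomSpec(
        centerline_kind="arc", length=40.0, radius=2.0,
        bulges=[tf.Bulge(14.0, 2.2, 2.8, [0, 0, 1]), tf.Bulge(26.0, 2.8, 3.2, [0, 0, 1])],
        circumferential_resolution=64, axial_resolution=200,
    )
    return tf.make_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20221109)
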