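import numpy as np
import pytest

from pllptools import (SyntheticSpec, generate_edu_channel,
                       generate_primordium, generate_timelapse)
from pllptools.pipeline import count_pipeline

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def primordium(default_spec):
    """One default synthetic acquisition (volume, ground truth)."""
    return generate_primordium(default_spec)


@pytest.fixture(scope="session")
def noisefree_primordium():
    spec = SyntheticSpec(seed=DEFAULT_SEED, noise_sigma=0.0)
    return generate_primordium(spec), spec


@pytest.fixture(scope="session")
def pipeline_result(primordium):
    vol, _gt = primordium
    return count_pipeline(vol)


@pytest.fixture(scope="session")
def edu_acquisition():
    spec = SyntheticSpec(seed=11, edu_fraction=0.3)
    vol, gt = generate_primordium(spec)
    edu, gt = generate_edu_channel(gt, spec)
    return vol, edu, gt, spec


def small_timelapse_spec(**overrides):
    base = dict(
        n_cells=40, domain_semi_axes=(9.0, 10.0, 18.0), shape=(28, 52, 256),
        speed=60.0, frame_interval=10.0, n_frames=5, seed=2, noise_sigma=0.0,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


@pytest.fixture(scope="session")
def timelapse():
    spec = small_timelapse_spec()
    return generate_timelapse(spec), spec
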