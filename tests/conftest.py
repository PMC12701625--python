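import numpy as np
import pytest

from ctmotion import (PhantomSpec, RigidTransform, SegmentationParams,
                      generate_pair, segment_bone, segment_implant)

# one known micromotion reused across the suite: mixed translation + rotation
KNOWN_MOTION = RigidTransform.from_euler_deg(
    0.3, -0.5, 0.4, translation=[0.5, -0.3, 0.2], center=[20.4, 49.0, 20.4])


@pytest.fixture(scope="session")
def compact_spec():
    return PhantomSpec.compact(noise_sd=20.0, seed=1, implant_motion=KNOWN_MOTION)


@pytest.fixture(scope="session")
def compact_pair(compact_spec):
    """Compact noisy phantom pair with a known implant micromotion."""
    baseline, followup, truth = generate_pair(compact_spec)
    return baseline, followup, truth


@pytest.fixture(scope="session")
def compact_masks(compact_pair):
    baseline, _, _ = compact_pair
    params = SegmentationParams()
    implant = segment_implant(baseline, params)
    bone = segment_bone(baseline, params, implant=implant)
    return bone, implant


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
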