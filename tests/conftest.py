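import numpy as np
import pytest

from ankle_adl.config import DetectionConfig
from ankle_adl.synthetic_generator import (make_static_script, make_tug_script,
                                           simulate_recording)


@pytest.fixture(scope="session")
def cfg():
    return DetectionConfig()


@pytest.fixture(scope="session")
def static_rec():
    return simulate_recording(make_static_script(seed=42)).recording


@pytest.fixture(scope="session")
def tug():
    """Noiseless TUG trial with ground truth."""
    return simulate_recording(make_tug_script(seed=1))


def random_segments(rng, n, duration=100.0, label=None):
    """n sorted, disjoint half-open intervals in [0, duration)."""
    from ankle_adl.types import ActivityLabel, Segment, SegmentSet
    label = label or ActivityLabel.WALKING
    cuts = np.sort(rng.uniform(0, duration, 2 * n))
    segs = []
    for i in range(n):
        a, b = cuts[2 * i], cuts[2 * i + 1]
        if b - a < 1e-3:
            b = a + 1e-3
        segs.append(Segment(a, min(b, duration + 1.0), label))
    # enforce disjointness after the length fix-up
    fixed = []
    for s in segs:
        if fixed and s.start < fixed[-1].end:
            if fixed[-1].end + 1e-3 >= s.end:
                continue
            s = Segment(fixed[-1].end, s.end, label)
        fixed.append(s)
    return SegmentSet(label, tuple(fixed))
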