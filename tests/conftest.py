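import numpy as np
import pytest

from spinedyn.model import SegmentDataset, SessionAxis, SpineTimeline


def make_segment(
    spines,
    length_um=80.0,
    segment_id="segA",
    animal_id="m1",
    group="test",
    labels=("s1", "s2", "s3"),
):
    """Build a segment from (spine_id, position, plaque_dist, presence) tuples."""
    axis = SessionAxis(tuple(labels))
    timelines = [
        SpineTimeline(spine_id=sid, segment_id=segment_id, position_um=pos,
                      dist_plaque_um=dist, presence=presence)
        for sid, pos, dist, presence in spines
    ]
    return SegmentDataset(segment_id=segment_id, animal_id=animal_id, group=group,
                          length_um=length_um, spines=timelines, sessions=axis)


@pytest.fixture
def three_session_segment():
    """A hand-built segment covering every fate over two intervals."""
    return make_segment([
        ("sp01", 5.0, 10.0, (1, 1, 1)),    # survives throughout (old)
        ("sp02", 12.0, 40.0, (1, 0, 0)),   # eliminated in interval 0
        ("sp03", 20.0, 150.0, (0, 1, 1)),  # formed in interval 0, survives 1 (new)
        ("sp04", 30.0, 80.0, (0, 1, 0)),   # formed in interval 0, eliminated in 1
        ("sp05", 42.0, None, (1, 1, 0)),   # old spine eliminated in interval 1
        ("sp06", 55.0, 30.0, (0, 0, 1)),   # formed in interval 1
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
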