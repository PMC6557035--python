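import numpy as np
import pytest

from calnet import SpineRecord, SpineRecordTable, Spine, TraceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_traces(rng):
    """20 frames x 5 cells of positive fluorescence with a transient."""
    values = 50.0 + rng.normal(0, 1.0, size=(20, 5))
    values[10, 2] += 25.0
    return TraceMatrix(values=np.clip(values, 0, None), frame_period=5.0)


@pytest.fixture
def toy_spine_table():
    """Hand-built mixed-context spine records covering every filter rule."""
    return SpineRecordTable(
        records=[
            SpineRecord(
                dendrite_id="d1", animal_id="a1", context="ex-vivo",
                segment_length=120.0, shaft_width=3.0,
                spines=[Spine(0.3), Spine(0.5, marker_positive=True), Spine(1.2)],
            ),
            SpineRecord(
                dendrite_id="d2", animal_id="a1", context="ex-vivo",
                segment_length=150.0, shaft_width=5.0,
                spines=[Spine(1.0), Spine(2.0)],
            ),
            SpineRecord(
                dendrite_id="d3", animal_id="a2", context="in-vitro",
                segment_length=20.0,
                spines=[Spine(12.0), Spine(1.5, marker_positive=True), Spine(0.8)],
            ),
        ]
    )
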