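import numpy as np
import pytest

from dyadsync.design import Channel, ChannelLayout, ConditionBlock, ExperimentDesign


@pytest.fixture
def small_layout():
    """Six channels, one pair per ROI, nominal 3.5 cm separation."""
    centers = {
        "L.IFG": [(-7.0, 5.0, 2.0), (-6.0, 6.5, 2.0)],
        "dmPFC": [(0.0, 8.5, 5.0), (1.5, 8.5, 5.0)],
        "R.IFG": [(7.0, 5.0, 2.0), (6.0, 6.5, 2.0)],
    }
    channels = []
    k = 0
    for roi, mids in centers.items():
        for mid in mids:
            k += 1
            mid = np.asarray(mid)
            off = np.array([1.75, 0.0, 0.0])
            channels.append(Channel(f"ch{k}", mid - off, mid + off, roi=roi))
    return ChannelLayout(channels)


@pytest.fixture
def grid_layout():
    """4x4 grid at 1.5 cm pitch: dense enough for spatial filtering tests."""
    channels = []
    for i in range(4):
        for j in range(4):
            mid = np.array([1.5 * i, 1.5 * j, 0.0])
            off = np.array([1.75, 0.0, 0.0])
            channels.append(Channel(f"g{i}{j}", mid - off, mid + off))
    return ChannelLayout(channels)


@pytest.fixture
def design():
    return ExperimentDesign(
        dyad_id="dyad01",
        participant_ids=("p1", "p2"),
        condition_blocks=(
            ConditionBlock("BB", 0.0, 10.0),
            ConditionBlock("FM", 10.0, 10.0),
            ConditionBlock("IS", 20.0, 10.0),
        ),
    )
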