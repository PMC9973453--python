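import numpy as np
import pytest

from verserhythm.stimulus_model import build_grid, place_tacks
from verserhythm.synthetic_reader import ParticipantProfile


@pytest.fixture
def tiny_poems():
    """Two short poems, one per meter, with tacks from line 3 on."""
    iamb = build_grid("iambic", 6, 8, poem_id="I1")
    troch = build_grid("trochaic", 6, 7, poem_id="T1")
    return [place_tacks(iamb, 0.25, seed=5), place_tacks(troch, 0.25, seed=6)]


@pytest.fixture
def small_panel():
    """Six readers, half musically active, mixed instructions."""
    rows = []
    for i in range(6):
        active = i < 3
        rows.append(ParticipantProfile(
            participant_id=f"S{i + 1:02d}",
            musa_q4="yes" if active else "no",
            musa_instrument="daily" if active else "Not at all",
            instruction=["no_instruction", "rhythmic", "on_beat"][i % 3],
        ))
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
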