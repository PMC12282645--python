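import numpy as np
import pytest

from nightscratch.intervals import normalize_track


@pytest.fixture
def track():
    """Factory for normalized scratch tracks with shared night metadata."""

    def make(intervals, source="R1", night="N1", pid="P1", kind="scratch"):
        return normalize_track(
            intervals, participant_id=pid, night_id=night, source=source, kind=kind
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
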