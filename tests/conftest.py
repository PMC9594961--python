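import datetime as dt

import numpy as np
import pytest

from ethobudget.io_formats import (
    EPOCH_S,
    EPOCHS_PER_DAY,
    ETHOGRAM,
    LABEL_TO_INDEX,
    BehaviourSequence,
)


def make_sequence(codes, day=dt.date(2021, 1, 10), animal_id="d01",
                  start="00:00:00"):
    """Build a BehaviourSequence from integer codes or labels, with epoch
    times on the 2-s grid starting at ``start`` UTC."""
    codes = np.asarray(
        [LABEL_TO_INDEX[c] if isinstance(c, str) else c for c in codes],
        dtype=np.int8,
    )
    t0 = np.datetime64(f"{day.isoformat()}T{start}", "s")
    times = t0 + np.arange(codes.size) * np.timedelta64(EPOCH_S, "s")
    return BehaviourSequence(animal_id, day, times, codes)


@pytest.fixture
def seq_factory():
    return make_sequence


@pytest.fixture
def full_day_factory():
    """A full 43,200-epoch day dominated by one behaviour."""

    def _make(label="resting", day=dt.date(2021, 1, 10), animal_id="d01"):
        return make_sequence([LABEL_TO_INDEX[label]] * EPOCHS_PER_DAY, day,
                             animal_id)

    return _make
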