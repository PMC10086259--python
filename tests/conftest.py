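import numpy as np
import pandas as pd
import pytest

from ihtt.montage import EVENT_COLUMNS, ChannelMontage, load_montage
from ihtt.preprocess import EpochSet
from ihtt.windows import epoch_times_ms


@pytest.fixture(scope="session")
def montage() -> ChannelMontage:
    return load_montage()


@pytest.fixture
def times_ms():
    return epoch_times_ms()


def make_epochs(data, montage, visual_fields=None, correct=None):
    """Build an EpochSet around a raw trials x channels x samples tensor."""
    n = data.shape[0]
    visual_fields = visual_fields or ["LVF"] * n
    correct = [True] * n if correct is None else correct
    meta = pd.DataFrame({
        "trial_id": np.arange(1, n + 1),
        "onset_sample": np.arange(1, n + 1) * 3000,
        "block": np.ones(n, dtype=int),
        "visual_field": visual_fields,
        "match": [True] * n,
        "response_hand": ["left"] * n,
        "response": ["match" if c else "nonmatch" for c in correct],
        "rt_ms": np.full(n, 500.0),
        "correct": correct,
    })[EVENT_COLUMNS]
    return EpochSet(
        data=data,
        meta=meta,
        montage=montage,
        trial_status=["retained"] * n,
        channel_status=np.array(["good"] * montage.n_channels, dtype=object),
    )


@pytest.fixture
def epochs_factory(montage):
    def _make(data, **kw):
        return make_epochs(np.asarray(data, dtype=float), montage, **kw)

    return _make
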