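import datetime as dt

import numpy as np
import pytest

from cytomon import EventTable, default_gateset

CHANNELS = ["FSC-A", "SSC-A", "FL1-A", "FL3-A", "FL1-H"]


def make_table(events, channels=None, **kwargs):
    kwargs.setdefault("acquired_volume_uL", 61.0)
    kwargs.setdefault("dilution_factor", 100.0)
    kwargs.setdefault("timestamp", dt.datetime(2024, 1, 1, 8, 0, 0))
    kwargs.setdefault("sample_id", "test")
    return EventTable(
        events=np.asarray(events, dtype=float),
        channel_names=list(channels or CHANNELS),
        **kwargs,
    )


def cluster_table(rng, means, weights, n=1000, sd=0.12, channels=None):
    """Linear-scale table of log-normal clusters at the given mixing weights.

    ``means`` is a list of log10 centre vectors over (FSC, SSC, FL1, FL3);
    an FL1-H column mirroring FL1-A is appended.
    """
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    counts = rng.multinomial(n, weights)
    rows = []
    for mean, k in zip(means, counts):
        if k:
            rows.append(rng.normal(loc=mean, scale=sd, size=(k, 4)))
    logs = np.concatenate(rows)
    full = np.column_stack([logs, logs[:, 2] - 0.05])
    return make_table(np.power(10.0, full), channels=channels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gates():
    return default_gateset()
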