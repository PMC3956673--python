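"""Shared fixtures: small configurations and hand-crafted event logs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from groofiworld.config import SimConfig
from groofiworld.io import (EVENT_FIGHT, EVENT_GROOM, EVENT_MOVE, NONE_ID,
                            EventLog)


@pytest.fixture
def small_config():
    """A short run (60 periods, 30 burn-in) for engine smoke tests."""
    return SimConfig(n_periods=60, burn_in_periods=30, n_runs=2, seed=5)


def manual_log(actors, events=None, app=100, burn_in=0, run=1) -> EventLog:
    """Build a log from an explicit activation schedule.

    ``actors[t]`` is the individual activated at clock ``t`` (its event
    defaults to ``move``); ``events`` maps clocks to either
    ``("fight", aggressor, victim, winner)`` (the aggressor must be the
    scheduled actor) or ``("groom", partner)``.
    """
    actors = np.asarray(actors, dtype=np.int16)
    n = len(actors)
    event = np.full(n, EVENT_MOVE, dtype=np.int8)
    partner = np.full(n, NONE_ID, dtype=np.int16)
    agg = np.full(n, NONE_ID, dtype=np.int16)
    vct = np.full(n, NONE_ID, dtype=np.int16)
    win = np.full(n, NONE_ID, dtype=np.int16)
    for t, entry in (events or {}).items():
        if entry[0] == "fight":
            _, a, v, w = entry
            assert actors[t] == a, "fight must happen at the aggressor's activation"
            event[t], partner[t], agg[t], vct[t], win[t] = EVENT_FIGHT, v, a, v, w
        elif entry[0] == "groom":
            event[t], partner[t] = EVENT_GROOM, entry[1]
        else:
            raise ValueError(entry)
    clocks = np.arange(n, dtype=np.int64)
    return EventLog(run=run, activations_per_period=app, burn_in_periods=burn_in,
                    period=(clocks // app + 1).astype(np.int32),
                    index=(clocks % app).astype(np.int32),
                    event=event, actor=actors, partner=partner, aggressor=agg,
                    victim=vct, winner=win, x=np.zeros(n, np.float32),
                    y=np.zeros(n, np.float32))


@pytest.fixture
def round_robin_log():
    """Six individuals (females 0-3, males 4-5) in strict rotation for two
    periods of 60 activations; no fights or grooms yet."""
    actors = [t % 6 for t in range(120)]
    return manual_log(actors, app=60)
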