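"""Shared fixtures: hand-built event logs and a reusable large generated table."""

from __future__ import annotations

import pandas as pd
import pytest

from careflow.eventlog import EVENT_COLUMNS, EventLog
from careflow.synth import GeneratorConfig, generate_episodes


def make_log(traces: dict) -> EventLog:
    """Build an EventLog from {case_id: [activity, ...]}.

    The first activity gets lifecycle ``first``, the last ``last`` and any
    middle ones ``during`` (single-activity cases are ``first``);
    timestamps advance one day per position.
    """
    rows = []
    for case_id, acts in traces.items():
        for k, act in enumerate(acts):
            if k == 0:
                stage = "first"
            elif k == len(acts) - 1:
                stage = "last"
            else:
                stage = "during"
            rows.append(
                {
                    "case_id": str(case_id),
                    "activity": act,
                    "activity_instance": f"{case_id}:{k:02d}",
                    "lifecycle": stage,
                    "timestamp": pd.Timestamp("2010-01-01") + pd.Timedelta(days=k),
                }
            )
    return EventLog(pd.DataFrame(rows, columns=EVENT_COLUMNS))


@pytest.fixture(scope="session")
def large_table() -> pd.DataFrame:
    """One big generated table shared across recovery/locality checks."""
    return generate_episodes(GeneratorConfig(n_clients=20000, seed=20240901))


@pytest.fixture(scope="session")
def default_table() -> pd.DataFrame:
    """A default-size generated table (~2,933 episodes)."""
    return generate_episodes(GeneratorConfig(seed=11))
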