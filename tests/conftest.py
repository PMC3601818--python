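import numpy as np
import pandas as pd
import pytest

import vmsync as v
from vmsync.synthgen import EVENT_COLUMNS


def make_event_log(rows, duration_s=60.0):
    """Hand-build an EventLog from (time, compartment, offset, amp, kind) tuples."""
    return v.EventLog(
        events=pd.DataFrame(rows, columns=EVENT_COLUMNS), duration_s=duration_s
    )


@pytest.fixture
def short_wt():
    """One-minute wild-type recording config (events + traces are cheap)."""
    return v.wildtype(duration_s=60.0, seed=7)


@pytest.fixture
def noiseless_wt():
    """Noise-free short wild-type config for end-to-end identities."""
    return v.wildtype(duration_s=30.0, seed=11, noise_sd=0.0, background_sd=0.0)


def ideal_delta_traces(cfg, events=None):
    """Trace-mode shortcut: ideal dR/R traces wrapped as DeltaTrace pair."""
    if events is None:
        events = v.sample_events(cfg)
    tr = v.render_traces(events, cfg)
    return (
        events,
        v.DeltaTrace(tr.time_s, tr.dRR_A, baseline_R0=1.0, compartment="A"),
        v.DeltaTrace(tr.time_s, tr.dRR_P, baseline_R0=1.0, compartment="P"),
    )
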