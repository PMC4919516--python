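import numpy as np
import pytest

from aobt import GeneratorConfig, simulate_session
from aobt.session import Session, SpikeTrain, StimulusEvent, StimulusPanel


def make_events(stimuli, n_repeats, inter_onset=20.0, duration=4.0, lead_in=10.0):
    """Deterministic round-robin trial table (no randomization)."""
    events = []
    k = 0
    for rep in range(1, n_repeats + 1):
        for s in stimuli:
            onset = lead_in + k * inter_onset
            events.append(StimulusEvent(s, onset, onset + duration, rep))
            k += 1
    return events


def make_session(spike_times_by_cell, stimuli=("s1", "s2"), control="ctrl",
                 n_repeats=3, metadata=None):
    """Hand-built session with explicit spike times."""
    panel = StimulusPanel(tuple(stimuli) + (control,), control=control)
    events = make_events(panel.stimulus_ids, n_repeats)
    trains = [
        SpikeTrain(cell_id, np.asarray(times, dtype=float))
        for cell_id, times in spike_times_by_cell.items()
    ]
    meta = {"duration_s": events[-1].offset + 20.0}
    if metadata:
        meta.update(metadata)
    return Session(trains=trains, trials=events, panel=panel, metadata=meta)


@pytest.fixture
def planted_session():
    """Small simulated session with known responders (cells 0-2)."""
    cfg = GeneratorConfig(
        n_cells=6,
        stimulus_ids=["urine", "faeces"],
        effects={
            0: {"urine": 10.0},
            1: {"faeces": 10.0},
            2: {"urine": 10.0, "faeces": 10.0},
        },
        baseline_rate=1.0,
        seed=7,
    )
    return simulate_session(cfg)
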