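"""Synthetic session generator with planted ground-truth tuning.

Spike trains are drawn from a piecewise-constant-rate Poisson process: each
cell fires at its baseline rate λ0 everywhere except inside the response
window of each stimulus event, where the rate becomes ``λ0 + Δ·g`` with Δ the
planted per-cell × per-stimulus effect (Hz) and ``g`` a per-trial
multiplicative log-normal jitter with unit mean.  Trial order is a seeded
random interleave: stimuli are delivered in blocks, each stimulus exactly once
per block, mirroring randomized interleaved delivery with at least three
repeats per stimulus.

The homogeneous-rate, rectangular response profile is deliberate: every
downstream statistic uses only window spike counts, so temporal response shape
is irrelevant, while the planted Δ map gives every analysis stage an exact
parameter-recovery oracle (:func:`ground_truth_tuning`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .session import Session, SessionValidationError, SpikeTrain, StimulusEvent, StimulusPanel

logger = logging.getLogger(__name__)

#: Effects below this rate (Hz) count as non-responses in the ground truth,
#: mirroring the >1 Hz rate criterion of the significance caller.
DEFAULT_DETECTION_FLOOR = 1.0


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-session generator.

    Parameters
    ----------
    n_cells : int
        Number of simulated units.
    stimulus_ids : sequence of str
        Test stimuli (the control is added separately).
    control : str
        Id of the solvent-control stimulus; its planted effect is always 0.
    effects : mapping ``{cell_index: {stimulus_id: Hz}}`` or DataFrame
        Planted rate increases Δ.  Missing entries are 0 (non-responder).
    baseline_rate : float, sequence, or None
        Baseline rate λ0 (Hz) per cell.  A scalar applies to every cell;
        ``None`` draws each cell's λ0 uniformly from ``baseline_range``.
    baseline_range : (float, float)
        Range for drawn baselines, default 0.5-3 Hz (typical spontaneous
        rates of the recorded projection neurons).
    n_trials : int
        Repeats per stimulus (>= 3), default 5.
    stimulus_duration : float
        Stimulus epoch length in seconds, default 4 (delivery lasts 3-5 s).
    inter_onset : float
        Seconds between consecutive stimulus onsets, default 20 — long
        enough that baseline, response and peristimulus windows of
        neighbouring trials never overlap.
    jitter_sd : float
        S.d. of the multiplicative log-normal across-trial effect jitter
        (unit mean), default 0.2.  Creates realistic trial-to-trial ΔR
        variance for the t-test and d′ stages.
    seed : int
        Seed for all randomness; recorded in the session metadata.
    """

    n_cells: int
    stimulus_ids: Sequence[str]
    control: str = "ringers"
    effects: Mapping | pd.DataFrame | None = None
    baseline_rate: float | Sequence[float] | None = None
    baseline_range: tuple = (0.5, 3.0)
    n_trials: int = 5
    stimulus_duration: float = 4.0
    inter_onset: float = 20.0
    jitter_sd: float = 0.2
    lead_in: float = 10.0
    seed: int = 0
    labels: Mapping[str, str] = field(default_factory=dict)
    tags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_trials < 3:
            raise ValueError("n_trials must be >= 3 (minimum repeats rule)")
        if self.control in self.stimulus_ids:
            raise ValueError("control must not appear among test stimulus_ids")
        if self.lead_in < 10.0:
            # the first baseline + peristimulus window needs 5 s of history,
            # plus 1 s slack before the response window of trial 0
            raise ValueError("lead_in must be >= 10 s")

    # -- construction helpers -------------------------------------------
    @property
    def all_stimulus_ids(self) -> tuple:
        return tuple(self.stimulus_ids) + (self.control,)

    def panel(self) -> StimulusPanel:
        return StimulusPanel(
            stimulus_ids=self.all_stimulus_ids,
            control=self.control,
            labels=dict(self.labels),
            tags=dict(self.tags),
        )

    def effect_matrix(self) -> pd.DataFrame:
        """Planted Δ as an (n_cells × stimuli) DataFrame, control included."""
        cols = list(self.all_stimulus_ids)
        mat = pd.DataFrame(
            0.0, index=range(self.n_cells), columns=cols, dtype=float
        )
        if self.effects is None:
            pass
        elif isinstance(self.effects, pd.DataFrame):
            for col in self.effects.columns:
                if col not in cols:
                    raise ValueError(f"effect for unknown stimulus {col!r}")
                mat.loc[self.effects.index, col] = self.effects[col].astype(float)
        else:
            for cell, per_stim in self.effects.items():
                for stim, delta in per_stim.items():
                    if stim not in cols:
                        raise ValueError(f"effect for unknown stimulus {stim!r}")
                    mat.at[int(cell), stim] = float(delta)
        if (mat[self.control] != 0).any():
            raise ValueError("the control stimulus must have zero planted effect")
        return mat

    def baseline_rates(self, rng: np.random.Generator) -> np.ndarray:
        if self.baseline_rate is None:
            lo, hi = self.baseline_range
            lam = rng.uniform(lo, hi, size=self.n_cells)
        else:
            lam = np.broadcast_to(
                np.asarray(self.baseline_rate, dtype=float), (self.n_cells,)
            ).copy()
        if np.any(lam <= 0):
            raise ValueError("baseline rates must be positive")
        return lam

    # -- YAML round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        eff = self.effects
        if isinstance(eff, pd.DataFrame):
            eff = {
                i: {c: float(v) for c, v in row.items() if v != 0}
                for i, row in eff.iterrows()
            }
        # string keys so the dict survives a JSON round trip unchanged
        if eff is not None:
            eff = {str(k): dict(v) for k, v in eff.items()}
        base = self.baseline_rate
        if isinstance(base, np.ndarray):
            base = [float(b) for b in base]
        return {
            "n_cells": self.n_cells,
            "stimulus_ids": list(self.stimulus_ids),
            "control": self.control,
            "effects": eff,
            "baseline_rate": base,
            "baseline_range": list(self.baseline_range),
            "n_trials": self.n_trials,
            "stimulus_duration": self.stimulus_duration,
            "inter_onset": self.inter_onset,
            "jitter_sd": self.jitter_sd,
            "lead_in": self.lead_in,
            "seed": self.seed,
            "labels": dict(self.labels),
            "tags": dict(self.tags),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "GeneratorConfig":
        doc = dict(doc)
        if doc.get("baseline_range") is not None:
            doc["baseline_range"] = tuple(doc["baseline_range"])
        eff = doc.get("effects")
        if eff is not None and not isinstance(eff, pd.DataFrame):
            doc["effects"] = {int(k): dict(v) for k, v in eff.items()}
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _interleaved_trials(config: GeneratorConfig, rng: np.random.Generator):
    """Seeded block-randomized trial order: each stimulus once per block."""
    stimuli = list(config.all_stimulus_ids)
    events = []
    repeat = {s: 0 for s in stimuli}
    k = 0
    for _ in range(config.n_trials):
        order = rng.permutation(len(stimuli))
        for idx in order:
            s = stimuli[idx]
            repeat[s] += 1
            onset = config.lead_in + k * config.inter_onset
            events.append(
                StimulusEvent(
                    stimulus_id=s,
                    onset=onset,
                    offset=onset + config.stimulus_duration,
                    repeat_index=repeat[s],
                )
            )
            k += 1
    return events


def _piecewise_poisson(
    rng: np.random.Generator,
    duration: float,
    baseline: float,
    windows: Sequence[tuple],
) -> np.ndarray:
    """Sample a Poisson train with rate ``baseline`` outside ``windows`` and
    the per-window rate inside.  Windows must be disjoint and sorted."""
    times = []
    cursor = 0.0
    segments = []
    for (w0, w1, rate) in windows:
        if w0 > cursor:
            segments.append((cursor, w0, baseline))
        segments.append((w0, w1, rate))
        cursor = w1
    if cursor < duration:
        segments.append((cursor, duration, baseline))

    for (t0, t1, rate) in segments:
        if rate < 0:
            logger.warning("negative instantaneous rate %.3f clipped to 0", rate)
            rate = 0.0
        n = rng.poisson(rate * (t1 - t0))
        if n:
            times.append(np.sort(rng.uniform(t0, t1, size=n)))
    if not times:
        return np.empty(0)
    out = np.concatenate(times)
    # uniform draws are a.s. distinct, but enforce strict monotonicity
    keep = np.ones(out.size, dtype=bool)
    keep[1:] = np.diff(out) > 0
    return out[keep]


def simulate_session(config: GeneratorConfig) -> Session:
    """Generate a session from ``config``; ground truth goes to metadata.

    The response window of an event — where the planted effect applies — is
    the 4 s analysis window starting 1 s after onset, matching the window the
    response analysis will score.
    """
    rng = np.random.default_rng(config.seed)
    events = _interleaved_trials(config, rng)
    duration = config.lead_in + len(events) * config.inter_onset + 15.0

    lam = config.baseline_rates(rng)
    effects = config.effect_matrix()

    trains = []
    for c in range(config.n_cells):
        windows = []
        for e in events:
            delta = effects.at[c, e.stimulus_id]
            w0, w1 = e.onset + 1.0, e.onset + 5.0
            if delta == 0.0:
                continue
            g = rng.lognormal(-config.jitter_sd**2 / 2.0, config.jitter_sd)
            rate = lam[c] + delta * g
            windows.append((w0, w1, max(rate, 0.0)))
        spike_times = _piecewise_poisson(rng, duration, lam[c], windows)
        trains.append(SpikeTrain(cell_id=f"cell{c:03d}", spike_times=spike_times))

    metadata = {
        "generator": "aobt.simulate",
        "seed": int(config.seed),
        "duration_s": float(duration),
        "baseline_rates_hz": [float(x) for x in lam],
        "config": config.to_dict(),
        "ground_truth_effects_hz": {
            f"cell{c:03d}": {
                s: float(effects.at[c, s])
                for s in effects.columns
                if effects.at[c, s] != 0.0
            }
            for c in range(config.n_cells)
        },
    }
    return Session(
        trains=trains, trials=events, panel=config.panel(), metadata=metadata
    )


def ground_truth_tuning(
    session: Session, detection_floor: float = DEFAULT_DETECTION_FLOOR
) -> pd.DataFrame:
    """Planted-tuning oracle: True where the planted Δ >= ``detection_floor``.

    Only valid for sessions produced by :func:`simulate_session`; raises
    ``ValueError`` for sessions without recorded ground truth.
    """
    truth = session.metadata.get("ground_truth_effects_hz")
    if truth is None or session.metadata.get("generator") != "aobt.simulate":
        raise ValueError("session carries no generator ground truth")
    cells = session.cell_ids
    stimuli = list(session.panel.stimulus_ids)
    table = pd.DataFrame(False, index=cells, columns=stimuli)
    for cell, per_stim in truth.items():
        for stim, delta in per_stim.items():
            table.at[cell, stim] = float(delta) >= detection_floor
    return table
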