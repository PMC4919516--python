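"""Per-trial response quantification and significance calling.

The response to one stimulus delivery is scored inside a 4 s analysis window
beginning 1 s after stimulus onset (the delay allows the stimulus line's dead
volume to clear).  The change in firing rate ΔR is the window rate minus the
baseline rate in the 5 s immediately before onset.  A cell×stimulus pair is a
significant responder when (i) a two-sample Student's t-test of its per-trial
ΔR values against the solvent-control ΔR values gives p < 0.05 and (ii) the
mean rate increase in the window exceeds 1 Hz.  Peristimulus time histograms
cover 5 s before to 15 s after onset in 1 s bins, averaged across repeats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .session import Session, SpikeTrain, StimulusEvent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisWindows:
    """Analysis window geometry, in seconds relative to stimulus onset.

    Defaults: response window [onset+1, onset+5] (4 s), baseline window
    [onset-5, onset] (5 s), PSTH window [onset-5, onset+15] in 1 s bins.
    """

    response_start: float = 1.0
    response_end: float = 5.0
    baseline_duration: float = 5.0
    psth_pre: float = 5.0
    psth_post: float = 15.0
    psth_bin: float = 1.0

    @property
    def response_duration(self) -> float:
        return self.response_end - self.response_start

    @property
    def n_psth_bins(self) -> int:
        return int(round((self.psth_pre + self.psth_post) / self.psth_bin))

    def __post_init__(self) -> None:
        if self.response_end <= self.response_start:
            raise ValueError("response window must have positive length")
        if self.baseline_duration <= 0 or self.psth_bin <= 0:
            raise ValueError("window durations must be positive")


def _count_in(spike_times: np.ndarray, t0: float, t1: float) -> int:
    """Spikes in the half-open interval [t0, t1)."""
    lo, hi = np.searchsorted(spike_times, [t0, t1], side="left")
    return int(hi - lo)


def compute_psth(
    train: SpikeTrain,
    events: Sequence[StimulusEvent],
    windows: AnalysisWindows = AnalysisWindows(),
):
    """Trial-averaged peristimulus time histogram.

    Returns
    -------
    rates : ndarray, shape (n_bins,)
        Mean firing rate (Hz) per bin across events.
    sem : ndarray, shape (n_bins,)
        Across-trial standard error per bin (0 for a single event).
    """
    if not events:
        raise ValueError("compute_psth needs at least one event")
    n_bins = windows.n_psth_bins
    per_event = np.empty((len(events), n_bins))
    for i, e in enumerate(events):
        start = e.onset - windows.psth_pre
        edges = start + windows.psth_bin * np.arange(n_bins + 1)
        counts = np.diff(np.searchsorted(train.spike_times, edges, side="left"))
        per_event[i] = counts / windows.psth_bin
    rates = per_event.mean(axis=0)
    if len(events) > 1:
        sem = per_event.std(axis=0, ddof=1) / math.sqrt(len(events))
    else:
        sem = np.zeros(n_bins)
    return rates, sem


def compute_delta_r(
    train: SpikeTrain,
    event: StimulusEvent,
    windows: AnalysisWindows = AnalysisWindows(),
) -> float:
    """ΔR for one trial: response-window rate minus pre-onset baseline rate."""
    t = train.spike_times
    resp = _count_in(t, event.onset + windows.response_start,
                     event.onset + windows.response_end)
    base = _count_in(t, event.onset - windows.baseline_duration, event.onset)
    return resp / windows.response_duration - base / windows.baseline_duration


def _window_rates(train, event, windows):
    t = train.spike_times
    resp = _count_in(t, event.onset + windows.response_start,
                     event.onset + windows.response_end)
    base = _count_in(t, event.onset - windows.baseline_duration, event.onset)
    return (resp / windows.response_duration,
            base / windows.baseline_duration)


@dataclass(frozen=True)
class ResponseCall:
    """Outcome of the two-criterion significance rule for one cell×stimulus."""

    significant: Optional[bool]
    p_value: float
    t_test_pass: Optional[bool]
    rate_pass: Optional[bool]
    mean_delta_r: float
    n_trials: int
    reason: str = ""


def call_response(
    responses: Sequence[float],
    control_responses: Sequence[float],
    alpha: float = 0.05,
    rate_threshold: float = 1.0,
    equal_var: bool = True,
    criterion: str = "delta_r",
    window_rates: Optional[Sequence[float]] = None,
) -> ResponseCall:
    """Significance call for one cell×stimulus.

    ``criterion='delta_r'`` (default) applies the rate rule to the mean ΔR
    (rate increase over baseline); ``criterion='window_rate'`` applies it to
    the mean absolute rate inside the response window (requires
    ``window_rates``).  Fewer than 3 trials in either group marks the pair
    unanalyzable (``significant is None``) rather than non-responsive.
    """
    x = np.asarray(responses, dtype=float)
    y = np.asarray(control_responses, dtype=float)
    mean_dr = float(x.mean()) if x.size else float("nan")
    if x.size < 3 or y.size < 3:
        return ResponseCall(None, float("nan"), None, None, mean_dr,
                            int(x.size), reason="insufficient trials")
    if np.allclose(x, x[0]) and np.allclose(y, y[0]) and math.isclose(
        x[0], y[0]
    ):
        p = 1.0
    else:
        p = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)
        if math.isnan(p):  # zero variance in both groups, equal means
            p = 1.0
    t_pass = p < alpha
    if criterion == "delta_r":
        rate_stat = mean_dr
    elif criterion == "window_rate":
        if window_rates is None:
            raise ValueError("criterion='window_rate' needs window_rates")
        rate_stat = float(np.mean(window_rates))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    rate_pass = rate_stat > rate_threshold
    return ResponseCall(bool(t_pass and rate_pass), p, bool(t_pass),
                        bool(rate_pass), mean_dr, int(x.size))


def call_control_response(
    control_responses: Sequence[float],
    alpha: float = 0.05,
    rate_threshold: float = 1.0,
) -> ResponseCall:
    """Did the cell respond to the solvent control itself?

    The two-sample rule cannot compare the control with itself, so the
    control is tested against zero: one-sample t-test on its ΔR values plus
    the same >1 Hz mean-increase rule.
    """
    y = np.asarray(control_responses, dtype=float)
    mean_dr = float(y.mean()) if y.size else float("nan")
    if y.size < 3:
        return ResponseCall(None, float("nan"), None, None, mean_dr,
                            int(y.size), reason="insufficient trials")
    if np.allclose(y, y[0]):
        p = 1.0 if math.isclose(y[0], 0.0) else 0.0
    else:
        p = float(stats.ttest_1samp(y, 0.0).pvalue)
    t_pass = p < alpha
    rate_pass = mean_dr > rate_threshold
    return ResponseCall(bool(t_pass and rate_pass), p, bool(t_pass),
                        bool(rate_pass), mean_dr, int(y.size))


def normalize_tuning(mean_delta_r: Sequence[float]) -> np.ndarray:
    """Scale a cell's mean-ΔR vector by its maximum absolute response.

    The divisor is max |ΔR| so the strongest response maps to ±1 and
    inhibitory responses cannot exceed magnitude 1.  All-zero vectors are an
    error (such a cell should already have been excluded).
    """
    v = np.asarray(mean_delta_r, dtype=float)
    m = np.max(np.abs(v))
    if m == 0:
        raise ValueError("cannot normalize an all-zero tuning vector")
    return v / m


def compute_dff(
    stack_means: Sequence[float], stim_onset_index: int, n_stacks: int = 3
) -> float:
    """Fluorescence response ratio for imaging series.

    The mean intensity of ``n_stacks`` stacks from ``stim_onset_index``
    onward divided by the mean of the ``n_stacks`` stacks immediately before
    it, as literally defined for the GCaMP3 stack series.
    """
    x = np.asarray(stack_means, dtype=float)
    i = int(stim_onset_index)
    if i < n_stacks or i + n_stacks > x.size:
        raise ValueError(f"need {n_stacks} stacks on each side of the onset")
    pre = x[i - n_stacks:i].mean()
    post = x[i:i + n_stacks].mean()
    if pre == 0:
        raise ValueError("baseline intensity is zero")
    return float(post / pre)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class ResponseModel:
    """Stimulus-response analysis of one session.

    Parameters
    ----------
    session : Session
    windows : AnalysisWindows, optional
    alpha : float
        t-test threshold, default 0.05.
    rate_threshold : float
        Minimum mean rate increase (Hz), default 1.
    equal_var : bool
        Classical Student's t (True, default) or Welch (False).
    criterion : {'delta_r', 'window_rate'}
        Which rate the >1 Hz rule applies to (see :func:`call_response`).
    holm : bool
        Optional Holm correction of the per-cell p-values across stimuli
        (off by default: the emulated analysis uses a fixed per-comparison
        threshold).
    min_trials : int
        Complete-trial requirement per cell × stimulus, default 3.
    """

    def __init__(
        self,
        session: Session,
        windows: Optional[AnalysisWindows] = None,
        alpha: float = 0.05,
        rate_threshold: float = 1.0,
        equal_var: bool = True,
        criterion: str = "delta_r",
        holm: bool = False,
        min_trials: int = 3,
    ) -> None:
        self.session = session
        self.windows = windows or AnalysisWindows()
        self.alpha = alpha
        self.rate_threshold = rate_threshold
        self.equal_var = equal_var
        self.criterion = criterion
        self.holm = holm
        self.min_trials = min_trials

    # -- fitting ---------------------------------------------------------
    def _usable_events(self):
        """Events whose baseline+PSTH windows lie inside the recorded span."""
        w = self.windows
        span = self.session.duration
        usable, dropped = [], 0
        for e in self.session.trials:
            lo = e.onset - max(w.baseline_duration, w.psth_pre)
            hi = e.onset + max(w.response_end, w.psth_post)
            if lo < 0 or hi > span + 1e-9:
                dropped += 1
                continue
            usable.append(e)
        if dropped:
            logger.info("dropped %d events with out-of-span windows", dropped)
        return usable

    def fit(self) -> "ResponseResults":
        session = self.session
        w = self.windows
        events = self._usable_events()
        control = session.panel.control

        rows = []
        for train in session.trains:
            for e in events:
                resp_rate, base_rate = _window_rates(train, e, w)
                rows.append(
                    (
                        train.cell_id,
                        e.stimulus_id,
                        e.repeat_index,
                        resp_rate - base_rate,
                        resp_rate,
                        base_rate,
                    )
                )
        responses = pd.DataFrame(
            rows,
            columns=[
                "cell_id",
                "stimulus_id",
                "repeat_index",
                "delta_r",
                "window_rate",
                "baseline_rate",
            ],
        )

        tuning_rows = []
        inclusion_rows = []
        stimuli = list(session.panel.stimulus_ids)
        test_stimuli = [s for s in stimuli if s != control]
        by_cell = dict(tuple(responses.groupby("cell_id", sort=False)))
        for train in session.trains:
            cell = train.cell_id
            sub = by_cell.get(
                cell,
                responses.iloc[0:0],
            )
            per_stim = {
                s: g for s, g in sub.groupby("stimulus_id", sort=False)
            }
            ctrl_dr = per_stim.get(control)
            ctrl_vals = (
                ctrl_dr["delta_r"].to_numpy() if ctrl_dr is not None else np.empty(0)
            )
            ctrl_call = call_control_response(
                ctrl_vals, self.alpha, self.rate_threshold
            )

            calls = {}
            for s in test_stimuli:
                g = per_stim.get(s)
                vals = g["delta_r"].to_numpy() if g is not None else np.empty(0)
                wrates = g["window_rate"].to_numpy() if g is not None else None
                calls[s] = call_response(
                    vals,
                    ctrl_vals,
                    self.alpha,
                    self.rate_threshold,
                    self.equal_var,
                    self.criterion,
                    window_rates=wrates,
                )

            if self.holm:
                tested = [s for s in test_stimuli if calls[s].significant is not None]
                ps = np.array([calls[s].p_value for s in tested])
                if ps.size:
                    order = np.argsort(ps)
                    adj = np.empty_like(ps)
                    running = 0.0
                    for rank, idx in enumerate(order):
                        running = max(running, ps[idx] * (ps.size - rank))
                        adj[idx] = min(running, 1.0)
                    for s, p_adj in zip(tested, adj):
                        c = calls[s]
                        calls[s] = ResponseCall(
                            bool((p_adj < self.alpha) and c.rate_pass),
                            float(p_adj),
                            bool(p_adj < self.alpha),
                            c.rate_pass,
                            c.mean_delta_r,
                            c.n_trials,
                        )

            # inclusion: >=3 complete trials for every tested stimulus,
            # no control response, >=1 significant test stimulus
            unanalyzable = [
                s
                for s in test_stimuli
                if calls[s].significant is None
            ] + ([control] if ctrl_call.significant is None else [])
            n_sig = sum(bool(calls[s].significant) for s in test_stimuli)
            if unanalyzable:
                included, reason = False, "insufficient trials"
            elif ctrl_call.significant:
                included, reason = False, "control responsive"
            elif n_sig == 0:
                included, reason = False, "no response"
            else:
                included, reason = True, ""
            inclusion_rows.append((cell, included, reason))

            mean_dr = {
                s: (
                    per_stim[s]["delta_r"].mean()
                    if s in per_stim
                    else float("nan")
                )
                for s in stimuli
            }
            divisor = max(
                (abs(mean_dr[s]) for s in test_stimuli if not math.isnan(mean_dr[s])),
                default=float("nan"),
            )
            for s in stimuli:
                c = calls[s] if s != control else ctrl_call
                norm = (
                    mean_dr[s] / divisor
                    if divisor and not math.isnan(mean_dr[s]) and divisor > 0
                    else float("nan")
                )
                tuning_rows.append(
                    (
                        cell,
                        s,
                        s == control,
                        mean_dr[s],
                        norm,
                        c.p_value,
                        c.significant,
                        c.n_trials,
                    )
                )

        tuning = pd.DataFrame(
            tuning_rows,
            columns=[
                "cell_id",
                "stimulus_id",
                "is_control",
                "mean_delta_r",
                "normalized_delta_r",
                "p_value",
                "significant",
                "n_trials",
            ],
        )
        inclusion = pd.DataFrame(
            inclusion_rows, columns=["cell_id", "included", "reason"]
        )
        return ResponseResults(self, responses, tuning, inclusion, events)


class ResponseResults:
    """Fitted per-trial responses, tuning table and cell inclusion calls."""

    def __init__(self, model, responses, tuning, inclusion, events) -> None:
        self.model = model
        self.session = model.session
        self.responses = responses
        self.tuning = tuning
        self.inclusion = inclusion
        self.events = events

    # -- convenience views ----------------------------------------------
    @property
    def included_cells(self) -> list:
        return self.inclusion.loc[self.inclusion["included"], "cell_id"].tolist()

    def significance_table(self, included_only: bool = True) -> pd.DataFrame:
        """Binary cell × stimulus responder table (control column included)."""
        tab = self.tuning.pivot(
            index="cell_id", columns="stimulus_id", values="significant"
        )[list(self.session.panel.stimulus_ids)]
        tab = tab.reindex(self.session.cell_ids)
        if included_only:
            tab = tab.loc[self.included_cells]
        return tab.fillna(False).astype(bool)

    def tuning_matrix(
        self, normalized: bool = True, included_only: bool = True,
        drop_control: bool = True,
    ) -> pd.DataFrame:
        value = "normalized_delta_r" if normalized else "mean_delta_r"
        mat = self.tuning.pivot(
            index="cell_id", columns="stimulus_id", values=value
        )[list(self.session.panel.stimulus_ids)]
        mat = mat.reindex(self.session.cell_ids)
        if included_only:
            mat = mat.loc[self.included_cells]
        if drop_control:
            mat = mat.drop(columns=[self.session.panel.control])
        return mat

    def trial_delta_r(self, cell_id: str, stimulus_id: str) -> np.ndarray:
        sub = self.responses
        mask = (sub["cell_id"] == cell_id) & (sub["stimulus_id"] == stimulus_id)
        return sub.loc[mask, "delta_r"].to_numpy()

    def psth(self, cell_id: str, stimulus_id: str):
        events = [e for e in self.events if e.stimulus_id == stimulus_id]
        return compute_psth(self.session.train(cell_id), events, self.model.windows)

    def psth_table(self) -> pd.DataFrame:
        """Long-form PSTH for all cell × stimulus pairs."""
        rows = []
        w = self.model.windows
        for cell in self.session.cell_ids:
            for s in self.session.panel.stimulus_ids:
                events = [e for e in self.events if e.stimulus_id == s]
                if not events:
                    continue
                rates, sem = self.psth(cell, s)
                for b, (r, se) in enumerate(zip(rates, sem)):
                    rows.append(
                        (cell, s, b, -w.psth_pre + b * w.psth_bin, r, se)
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id", "stimulus_id", "bin", "bin_start_s", "rate_hz",
                "sem_hz",
            ],
        )

    def summary(self) -> str:
        n_cells = len(self.session.cell_ids)
        n_inc = len(self.included_cells)
        reasons = self.inclusion.loc[~self.inclusion["included"], "reason"]
        lines = [
            "Stimulus-response analysis",
            "=" * 40,
            f"cells analysed:        {n_cells}",
            f"cells included:        {n_inc}",
        ]
        for reason, count in reasons.value_counts().items():
            lines.append(f"  excluded ({reason}): {count}")
        sig = self.significance_table(included_only=True)
        lines.append("responders per stimulus (included cells):")
        for s in self.session.panel.stimulus_ids:
            tag = " (control)" if s == self.session.panel.control else ""
            if s in sig.columns:
                lines.append(f"  {s:<16} {int(sig[s].sum())}{tag}")
        return "\n".join(lines)
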