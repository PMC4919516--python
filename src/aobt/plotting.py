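"""Figures: raster + PSTH, tuning heat maps, overlap bars, d′ histograms."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_raster_psth(results, cell_id: str, stimulus_id: str, ax_pair=None):
    """Raster (top) and trial-averaged PSTH (bottom) for one cell × stimulus."""
    w = results.model.windows
    events = [e for e in results.events if e.stimulus_id == stimulus_id]
    if ax_pair is None:
        fig, (ax_r, ax_p) = plt.subplots(
            2, 1, sharex=True, figsize=(5, 4),
            gridspec_kw={"height_ratios": [1, 2]},
        )
    else:
        ax_r, ax_p = ax_pair
        fig = ax_r.figure
    train = results.session.train(cell_id)
    for i, e in enumerate(events):
        rel = train.spike_times - e.onset
        rel = rel[(rel >= -w.psth_pre) & (rel <= w.psth_post)]
        ax_r.vlines(rel, i + 0.6, i + 1.4, color="k", lw=0.7)
    ax_r.set_ylabel("trial")
    ax_r.set_title(f"{cell_id} / {stimulus_id}")

    rates, sem = results.psth(cell_id, stimulus_id)
    centers = -w.psth_pre + w.psth_bin * (np.arange(len(rates)) + 0.5)
    ax_p.bar(centers, rates, width=w.psth_bin * 0.95, color="0.4")
    ax_p.errorbar(centers, rates, yerr=sem, fmt="none", ecolor="k", lw=0.8)
    ax_p.axvspan(w.response_start, w.response_end, color="tab:orange", alpha=0.2)
    ax_p.set_xlabel("time from onset (s)")
    ax_p.set_ylabel("rate (Hz)")
    return fig


def plot_tuning_heatmap(matrix: pd.DataFrame, labels=None, cluster_labels=None,
                        ax=None):
    """Normalized-ΔR heat map; thin black lines divide clusters if given."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 6))
    else:
        fig = ax.figure
    mat = matrix.copy()
    if cluster_labels is not None:
        order = np.argsort(np.asarray(cluster_labels), kind="stable")
        mat = mat.iloc[order]
    im = ax.imshow(
        mat.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1,
        interpolation="nearest",
    )
    if cluster_labels is not None:
        sorted_labs = np.asarray(cluster_labels)[order]
        for b in np.nonzero(np.diff(sorted_labs))[0]:
            ax.axhline(b + 0.5, color="k", lw=0.8)
    ax.set_xticks(range(mat.shape[1]))
    ax.set_xticklabels(labels or list(mat.columns), rotation=90, fontsize=7)
    ax.set_ylabel("cell")
    fig.colorbar(im, ax=ax, label="norm. ΔR")
    return fig


def plot_overlap_regions(regions: dict, stimuli: Sequence[str], ax=None):
    """Bar chart of response-overlap region counts (Venn regions)."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 3))
    else:
        fig = ax.figure
    names, counts = [], []
    for pattern, count in sorted(regions.items(), key=lambda kv: (-sum(kv[0]), kv[0])):
        members = [s for s, m in zip(stimuli, pattern) if m]
        names.append(" ∩ ".join(members))
        counts.append(count)
    ax.bar(range(len(counts)), counts, color="0.5")
    ax.set_xticks(range(len(counts)))
    ax.set_xticklabels(names, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("cells")
    fig.tight_layout()
    return fig


def plot_dprime_histogram(result, ax=None):
    """Observed (red) vs mean-shuffled (grey) d′ histograms."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 3))
    else:
        fig = ax.figure
    if hasattr(result, "histogram"):
        edges, obs, model = result.histogram()
    else:
        from .discrimination import dprime_histogram

        edges, obs, model = dprime_histogram(result)
    centers = (edges[:-1] + edges[1:]) / 2
    width = (edges[1] - edges[0]) * 0.9
    ax.bar(centers, model, width=width, color="0.6", label="shuffled (mean)")
    ax.bar(centers, obs, width=width * 0.55, color="tab:red", label="observed")
    ax.set_xlabel("d′")
    ax.set_ylabel("cells")
    ax.legend(frameon=False, fontsize=8)
    return fig
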