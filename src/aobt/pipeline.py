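"""Pipeline orchestration: one YAML config drives simulate → analyze →
cluster → discriminate and writes a reproducible report bundle.

Outputs under the configured directory::

    session/            the (simulated or copied-through) session
    responses.csv       per-trial ΔR
    tuning.csv          per cell × stimulus calls and normalized ΔR
    psth.csv            long-form PSTHs
    inclusion.csv       per-cell inclusion + reason
    clusters.csv, similarity.csv, mds.csv
    categories_<name>.csv
    dprime.csv, shuffle_summary.json
    figures/*.png
    manifest.json       versions, seeds, config hash
    report.md           human-readable summary
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .discrimination import DiscriminationModel
from .population import (
    ConsensusClusterModel,
    TuningCategorySpec,
    classify_tuning,
    mds_embed,
    overlap_venn,
)
from .response import AnalysisWindows, ResponseModel
from .session import Session, read_session, write_session
from .simulate import GeneratorConfig, simulate_session

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Full pipeline configuration (round-trips through YAML)."""

    out_dir: str = "results"
    session_path: Optional[str] = None
    generator: Optional[dict] = None  # GeneratorConfig fields
    windows: dict = field(default_factory=dict)  # AnalysisWindows overrides
    alpha: float = 0.05
    rate_threshold: float = 1.0
    equal_var: bool = True
    criterion: str = "delta_r"
    cluster_runs: int = 500
    cluster_k_range: tuple = (2, 12)
    cluster_bandwidth: Optional[float] = None
    cluster_seed: int = 0
    mds_dims: int = 3
    categories: list = field(default_factory=list)  # dicts for TuningCategorySpec
    discriminate: Optional[dict] = None  # {stim_1, stim_2, n_model, unit}
    shuffle_seed: int = 0
    figures: bool = True

    def __post_init__(self) -> None:
        self.cluster_k_range = tuple(self.cluster_k_range)
        if self.session_path is None and self.generator is None:
            raise ValueError("config needs a session_path or a generator block")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cluster_k_range"] = list(self.cluster_k_range)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # annotate with the failing stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("session")
def _obtain_session(config: PipelineConfig, out: Path) -> Session:
    if config.generator is not None:
        gen = GeneratorConfig.from_dict(config.generator)
        session = simulate_session(gen)
    else:
        session = read_session(config.session_path)
    write_session(session, out / "session")
    return session


@_stage("response_analysis")
def _response_stage(config: PipelineConfig, session: Session, out: Path):
    windows = AnalysisWindows(**config.windows) if config.windows else AnalysisWindows()
    model = ResponseModel(
        session,
        windows=windows,
        alpha=config.alpha,
        rate_threshold=config.rate_threshold,
        equal_var=config.equal_var,
        criterion=config.criterion,
    )
    results = model.fit()
    results.responses.to_csv(out / "responses.csv", index=False)
    results.tuning.to_csv(out / "tuning.csv", index=False)
    results.inclusion.to_csv(out / "inclusion.csv", index=False)
    results.psth_table().to_csv(out / "psth.csv", index=False)
    return results


@_stage("population_analysis")
def _population_stage(config: PipelineConfig, results, out: Path):
    mat = results.tuning_matrix(normalized=True, included_only=True)
    cluster_res = None
    if len(mat) >= 2:
        cluster_res = ConsensusClusterModel(
            mat,
            n_runs=config.cluster_runs,
            k_range=config.cluster_k_range,
            bandwidth=config.cluster_bandwidth,
            seed=config.cluster_seed,
        ).fit()
        cluster_res.assignments().to_csv(out / "clusters.csv", index=False)
        cluster_res.similarity.to_csv(out / "similarity.csv")
        coords, stress = mds_embed(
            cluster_res.similarity, dims=config.mds_dims, seed=config.cluster_seed
        )
        mds_df = pd.DataFrame(
            coords, index=mat.index,
            columns=[f"dim{i + 1}" for i in range(coords.shape[1])],
        )
        mds_df["stress"] = stress
        mds_df.to_csv(out / "mds.csv")

    sig = results.significance_table(included_only=True)
    category_tables = {}
    for spec_doc in config.categories:
        spec = TuningCategorySpec(
            name_a=spec_doc["name_a"],
            set_a=tuple(spec_doc["set_a"]),
            name_b=spec_doc["name_b"],
            set_b=tuple(spec_doc["set_b"]),
        )
        name = f"{spec.name_a}_vs_{spec.name_b}"
        table = classify_tuning(sig, spec)
        table.to_csv(out / f"categories_{name}.csv")
        category_tables[name] = table
    return cluster_res, category_tables


@_stage("discrimination")
def _discrimination_stage(config: PipelineConfig, results, out: Path):
    if config.discriminate is None:
        return None
    spec = config.discriminate
    model = DiscriminationModel.from_results(
        results,
        spec["stim_1"],
        spec["stim_2"],
        normalized=spec.get("normalized", True),
        n_model=int(spec.get("n_model", 100_000)),
        unit=spec.get("unit", "trials"),
        seed=config.shuffle_seed,
    )
    disc = model.fit()
    disc.to_frame().to_csv(out / "dprime.csv", index=False)
    (out / "shuffle_summary.json").write_text(
        json.dumps(disc.shuffle_summary(), indent=2, sort_keys=True) + "\n"
    )
    return disc


def _figures(config, results, cluster_res, disc, out: Path) -> list:
    from . import plotting
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    written = []
    inc = results.included_cells
    if inc:
        cell = inc[0]
        stim = results.session.panel.test_stimulus_ids[0]
        fig = plotting.plot_raster_psth(results, cell, stim)
        fig.savefig(figdir / "raster_psth.png", dpi=120)
        plt.close(fig)
        written.append("raster_psth.png")
    mat = results.tuning_matrix()
    if len(mat) >= 2 and cluster_res is not None:
        fig = plotting.plot_tuning_heatmap(
            mat, cluster_labels=cluster_res.labels
        )
        fig.savefig(figdir / "tuning_heatmap.png", dpi=120)
        plt.close(fig)
        written.append("tuning_heatmap.png")
    if disc is not None:
        fig = plotting.plot_dprime_histogram(disc)
        fig.savefig(figdir / "dprime_histogram.png", dpi=120)
        plt.close(fig)
        written.append("dprime_histogram.png")
    return written


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns a dict of in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    session = _obtain_session(config, out)
    results = _response_stage(config, session, out)
    cluster_res, categories = _population_stage(config, results, out)
    disc = _discrimination_stage(config, results, out)
    figures = _figures(config, results, cluster_res, disc, out) if config.figures else []

    manifest = {
        "aobt_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": {
            "generator": (config.generator or {}).get("seed"),
            "cluster": config.cluster_seed,
            "shuffle": config.shuffle_seed,
        },
        "figures": figures,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )

    report = [
        "# Analysis report",
        "",
        f"aobt {__version__}, config hash `{config.config_hash()}`",
        "",
        "## Response analysis",
        "",
        "```",
        results.summary(),
        "```",
    ]
    if cluster_res is not None:
        report += ["", "## Clustering", "", "```", cluster_res.summary(), "```"]
    for name, table in categories.items():
        report += ["", f"## Tuning categories: {name}", "", table.to_markdown()]
    if disc is not None:
        report += ["", "## Discriminability", "", "```", disc.summary(), "```"]
    (out / "report.md").write_text("\n".join(report) + "\n")

    return {
        "session": session,
        "response": results,
        "clusters": cluster_res,
        "categories": categories,
        "discrimination": disc,
    }
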