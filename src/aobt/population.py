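"""Population-level tuning summaries: categories, overlap, clustering, MDS.

Tuning categories follow the convention of two-stimulus population
comparisons: within a comparison of stimulus sets A and B, a cell is
"exclusive-A" when it responds to at least one member of A and none of B
(regardless of the rest of the panel), "both" when it responds to members of
both, and "other" when it responds to neither but does respond to another
stimulus in the battery.

Consensus clustering compiles a cell × cell co-assignment similarity matrix
over many non-deterministic base clusterings (k-means with random k and
random initialization), then applies mean-shift clustering to the rows of
that matrix.  The similarity matrix can additionally be embedded with
nonmetric multidimensional scaling for 3-D visualization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans, MeanShift, estimate_bandwidth
from sklearn.exceptions import ConvergenceWarning
from sklearn.manifold import MDS

logger = logging.getLogger(__name__)


def _otsu_threshold(values: np.ndarray, nbins: int = 128) -> float:
    """Otsu's between-class-variance threshold of a 1-D sample."""
    hist, edges = np.histogram(values, bins=nbins)
    mids = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    total = w.sum()
    csum = np.cumsum(w)
    cmean = np.cumsum(w * mids)
    best_t, best_var = float(mids[0]), -1.0
    for i in range(1, nbins):
        w0 = csum[i - 1] / total
        if w0 <= 0 or w0 >= 1:
            continue
        m0 = cmean[i - 1] / csum[i - 1]
        m1 = (cmean[-1] - cmean[i - 1]) / (total - csum[i - 1])
        var = w0 * (1 - w0) * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, float(mids[i])
    return best_t


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TuningCategorySpec:
    """Two named, disjoint stimulus sets defining a population comparison."""

    name_a: str
    set_a: tuple
    name_b: str
    set_b: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "set_a", tuple(self.set_a))
        object.__setattr__(self, "set_b", tuple(self.set_b))
        if set(self.set_a) & set(self.set_b):
            raise ValueError("category stimulus sets must be disjoint")

    @property
    def category_names(self) -> tuple:
        return (
            f"{self.name_a}_only",
            f"{self.name_b}_only",
            "both",
            "other",
        )


def classify_tuning(
    table: pd.DataFrame, spec: TuningCategorySpec, include_other: bool = True
) -> pd.DataFrame:
    """Partition responder cells into exclusive/both/other categories.

    Parameters
    ----------
    table : DataFrame of bool, cells × stimuli
        Significance calls for included cells.
    spec : TuningCategorySpec
    include_other : bool
        If False, restrict to cells responding to at least one stimulus of
        the comparison (the "responder pool" convention of overlap figures)
        and omit the "other" category.

    Returns
    -------
    DataFrame indexed by category with ``count`` and ``percent`` columns;
    percentages are of the classified total, printed-style rounded to one
    decimal.
    """
    if table.empty:
        raise ValueError("empty tuning table")
    for s in spec.set_a + spec.set_b:
        if s not in table.columns:
            raise ValueError(f"stimulus {s!r} not in tuning table")
    in_a = table[list(spec.set_a)].any(axis=1)
    in_b = table[list(spec.set_b)].any(axis=1)
    cats = pd.Series("other", index=table.index)
    cats[in_a & ~in_b] = f"{spec.name_a}_only"
    cats[~in_a & in_b] = f"{spec.name_b}_only"
    cats[in_a & in_b] = "both"
    names = list(spec.category_names)
    if not include_other:
        cats = cats[cats != "other"]
        names.remove("other")
        if cats.empty:
            raise ValueError("no cells respond to either comparison set")
    counts = cats.value_counts().reindex(names, fill_value=0)
    total = int(counts.sum())
    out = pd.DataFrame({"count": counts})
    out["percent"] = [
        round_half_away(100.0 * c / total, 1) for c in counts
    ]
    return out


def overlap_venn(table: pd.DataFrame, stimuli: Sequence[str]) -> dict:
    """Region counts of the response-overlap Venn for 2 or 3 stimuli.

    Counts are over the pool of cells responding to at least one of the
    listed stimuli.  Keys are boolean membership tuples aligned with
    ``stimuli``; e.g. for two stimuli, ``(True, False)`` is the first-only
    region and ``(True, True)`` the intersection.
    """
    stimuli = list(stimuli)
    if not 2 <= len(stimuli) <= 3:
        raise ValueError("overlap_venn supports 2 or 3 stimuli")
    for s in stimuli:
        if s not in table.columns:
            raise ValueError(f"stimulus {s!r} not in tuning table")
    sub = table[stimuli].astype(bool)
    pool = sub.loc[sub.any(axis=1)]
    regions = {}
    for pattern in product([True, False], repeat=len(stimuli)):
        if not any(pattern):
            continue
        mask = np.ones(len(pool), dtype=bool)
        for s, member in zip(stimuli, pattern):
            mask &= pool[s].to_numpy() == member
        regions[pattern] = int(mask.sum())
    return regions


def pairwise_overlap(table: pd.DataFrame, stimuli: Sequence[str]) -> pd.DataFrame:
    """Pairwise co-response percentage matrix.

    Entry (r, c) is 100 × (number of cells significantly responding to both
    r and c) / (number responding to r, the row stimulus).  Diagonal is 100.
    Rows whose stimulus has no responders are undefined (NaN), not 0.
    """
    stimuli = list(stimuli)
    for s in stimuli:
        if s not in table.columns:
            raise ValueError(f"stimulus {s!r} not in tuning table")
    sub = table[stimuli].astype(bool)
    out = pd.DataFrame(index=stimuli, columns=stimuli, dtype=float)
    for r in stimuli:
        n_r = int(sub[r].sum())
        for c in stimuli:
            if n_r == 0:
                out.at[r, c] = np.nan
            else:
                out.at[r, c] = 100.0 * int((sub[r] & sub[c]).sum()) / n_r
    return out


# ---------------------------------------------------------------------------
# Consensus clustering
# ---------------------------------------------------------------------------


class ConsensusClusterModel:
    """Consensus mean-shift clustering of normalized tuning curves.

    Each of ``n_runs`` base runs clusters the rows of ``data`` with k-means
    using a random k (uniform on ``k_range``) and random initialization.
    The co-assignment frequency across runs forms a cell × cell similarity
    matrix whose rows are then clustered by mean shift (bandwidth from the
    standard quantile heuristic unless given).  Deterministic given ``seed``.

    Parameters
    ----------
    data : DataFrame or ndarray, cells × stimuli
        Normalized tuning matrix, entries in [-1, 1].
    n_runs : int
        Base clustering runs, >= 100 (typically hundreds to thousands).
    k_range : (int, int)
        Inclusive range of k for the base k-means, default (2, 12); capped
        at n_cells - 1.
    bandwidth : float, optional
        Mean-shift bandwidth on similarity rows; estimated if None.
    bandwidth_method : {'distance-gap', 'quantile'}
        How to estimate the bandwidth when not given.  'distance-gap'
        (default) takes Otsu's threshold of the pairwise row-distance
        distribution — co-assignment similarity matrices of clustered data
        have a bimodal distance distribution (small within-block, large
        between-block), and the threshold lands in the gap, which is
        exactly where a flat-kernel mean shift separates the blocks.
        'quantile' uses the standard nearest-neighbour quantile heuristic
        with ``bandwidth_quantile``.
    bandwidth_quantile : float
        Quantile for the 'quantile' heuristic, default 0.3.
    seed : int
    """

    def __init__(
        self,
        data,
        n_runs: int = 1000,
        k_range: tuple = (2, 12),
        bandwidth: Optional[float] = None,
        bandwidth_method: str = "distance-gap",
        bandwidth_quantile: float = 0.3,
        seed: int = 0,
    ) -> None:
        if n_runs < 100:
            raise ValueError("n_runs must be >= 100 for a stable consensus")
        self.data = (
            data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data))
        )
        if self.data.isna().any().any():
            raise ValueError("tuning matrix contains NaN")
        self.n_runs = n_runs
        self.k_range = k_range
        self.bandwidth = bandwidth
        if bandwidth_method not in ("distance-gap", "quantile"):
            raise ValueError(f"unknown bandwidth_method {bandwidth_method!r}")
        self.bandwidth_method = bandwidth_method
        self.bandwidth_quantile = bandwidth_quantile
        self.seed = seed

    def fit(self) -> "ClusterResults":
        X = self.data.to_numpy(dtype=float)
        n = X.shape[0]
        if n < 2:
            warnings.warn("fewer than 2 cells: returning a single cluster")
            labels = np.zeros(n, dtype=int)
            sim = np.ones((n, n))
            return ClusterResults(self, labels, sim, bandwidth=float("nan"))

        rng = np.random.default_rng(self.seed)
        k_lo = max(2, self.k_range[0])
        k_hi = max(k_lo, min(self.k_range[1], n - 1))
        co = np.zeros((n, n))
        with warnings.catch_warnings():
            # duplicate rows can make k-means return < k clusters; harmless
            warnings.simplefilter("ignore", ConvergenceWarning)
            for _ in range(self.n_runs):
                k = int(rng.integers(k_lo, k_hi + 1))
                km = KMeans(
                    n_clusters=k,
                    init="random",
                    n_init=1,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                ).fit(X)
                same = km.labels_[:, None] == km.labels_[None, :]
                co += same
        sim = co / self.n_runs
        np.fill_diagonal(sim, 1.0)

        bw = self.bandwidth
        if bw is None:
            if self.bandwidth_method == "quantile":
                bw = estimate_bandwidth(sim, quantile=self.bandwidth_quantile)
            else:
                bw = _otsu_threshold(pdist(sim))
            if not bw > 0:  # degenerate (e.g. all rows identical)
                bw = 0.1
        ms = MeanShift(bandwidth=bw).fit(sim)
        labels = _relabel_contiguous(ms.labels_)
        return ClusterResults(self, labels, sim, bandwidth=float(bw))


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..K-1 in order of first appearance."""
    mapping = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


class ClusterResults:
    """Labels + co-assignment similarity from consensus clustering."""

    def __init__(self, model, labels, similarity, bandwidth) -> None:
        self.model = model
        self.labels = np.asarray(labels, dtype=int)
        self.similarity = pd.DataFrame(
            similarity, index=model.data.index, columns=model.data.index
        )
        self.bandwidth = bandwidth
        self.n_runs = model.n_runs
        self.seed = model.seed

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.model.data.index, "cluster": self.labels}
        )

    def sorted_order(self) -> np.ndarray:
        """Row order grouping cells by cluster (for heat-map display)."""
        return np.argsort(self.labels, kind="stable")

    def summary(self) -> str:
        sizes = pd.Series(self.labels).value_counts().sort_index()
        lines = [
            "Consensus mean-shift clustering",
            "=" * 40,
            f"cells:       {len(self.labels)}",
            f"base runs:   {self.n_runs} (k in {self.model.k_range})",
            f"bandwidth:   {self.bandwidth:.3f}",
            f"clusters:    {self.n_clusters}",
        ]
        for lab, size in sizes.items():
            lines.append(f"  cluster {lab}: {size} cells")
        return "\n".join(lines)


def mds_embed(
    similarity: pd.DataFrame | np.ndarray, dims: int = 3, seed: int = 0
):
    """Nonmetric MDS of a similarity matrix (dissimilarity = 1 - similarity).

    Returns ``(coords, stress)`` where coords has one row per cell.  A
    degenerate matrix (all dissimilarities equal, or a single cell) yields a
    zero-spread embedding with a warning.
    """
    S = np.asarray(
        similarity.values if isinstance(similarity, pd.DataFrame) else similarity,
        dtype=float,
    )
    n = S.shape[0]
    if n == 1:
        return np.zeros((1, dims)), 0.0
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    off = D[~np.eye(n, dtype=bool)]
    if np.allclose(off, off[0]):
        warnings.warn("degenerate (all-equal) dissimilarities: zero-spread embedding")
        return np.zeros((n, dims)), 0.0
    mds = MDS(
        n_components=dims,
        metric_mds=False,
        metric="precomputed",
        init="random",
        random_state=seed,
        n_init=4,
        normalized_stress="auto",
        max_iter=300,
    )
    coords = mds.fit_transform(D)
    return coords, float(mds.stress_)
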