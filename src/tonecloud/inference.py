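"""Group-level inference over channel x frequency effect maps.

Signed effects (e.g. high-minus-low-power differences of a weight
component, one value per participant, channel and frequency) are tested
with a sign-flip cluster-based permutation test: per-cell paired t-values
are thresholded at two-sided p < 0.05, supra-threshold cells are grouped
into clusters over channel adjacency (and optionally neighboring
frequencies), the max-sum of t within a cluster is the cluster statistic,
clusters smaller than two cells are discarded, and the observed masses
are compared against the sign-flip null of the maximal cluster mass.

Non-negative effects from the best-of-four phase divisions cannot be
sign-flipped; their null is built by re-running the entire selection
pipeline on permuted trial-behavior pairings (so the selection bias is
present in the null), thresholding at the cell-wise 95th percentile, and
clustering as above.  Benjamini-Hochberg FDR controls across contrast
families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NeighborGraph",
    "ClusterResult",
    "grid_graph",
    "cluster_perm_test",
    "max_division_perm_test",
    "fdr_bh",
]


@dataclass
class NeighborGraph:
    """Symmetric, irreflexive channel adjacency."""

    adjacency: np.ndarray            # (n_channels, n_channels) bool
    ch_names: list = field(default_factory=list)

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(a != a.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(a, False)
        self.adjacency = a
        if not self.ch_names:
            self.ch_names = [f"ch{i:02d}" for i in range(a.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.adjacency.shape[0]

    def is_connected(self) -> bool:
        n, _ = connected_components(sparse.csr_matrix(self.adjacency))
        return n == 1

    @classmethod
    def from_edges(cls, edges, n_channels: int, ch_names=None):
        a = np.zeros((n_channels, n_channels), dtype=bool)
        for i, j in edges:
            a[i, j] = a[j, i] = True
        return cls(adjacency=a, ch_names=list(ch_names or []))

    def to_edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency))
        return list(zip(i.tolist(), j.tolist()))


def grid_graph(rows: int = 8, cols: int = 8) -> NeighborGraph:
    """4-connected grid adjacency, the default synthetic montage."""
    n = rows * cols
    a = np.zeros((n, n), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                a[i, i + 1] = a[i + 1, i] = True
            if r + 1 < rows:
                a[i, i + cols] = a[i + cols, i] = True
    return NeighborGraph(adjacency=a)


@dataclass
class ClusterResult:
    """Clusters sorted by descending |mass|, with permutation p-values."""

    clusters: list                   # dicts: cells, channels, freqs, mass, size, p
    n_perm: int
    threshold: np.ndarray | float
    null_max_mass: np.ndarray

    def significant(self, alpha: float = 0.05):
        return [c for c in self.clusters if c["p"] <= alpha]


def _cell_adjacency(graph: NeighborGraph, n_freq: int,
                    freq_adjacency: bool) -> sparse.csr_matrix:
    """Adjacency over flattened (channel, freq) cells."""
    ch_adj = sparse.csr_matrix(graph.adjacency.astype(np.int8))
    eye_f = sparse.eye(n_freq, dtype=np.int8, format="csr")
    cell = sparse.kron(ch_adj, eye_f, format="csr")
    if freq_adjacency and n_freq > 1:
        band = sparse.diags([np.ones(n_freq - 1)] * 2, offsets=[1, -1],
                            dtype=np.int8, format="csr")
        cell = cell + sparse.kron(sparse.eye(graph.n_channels, dtype=np.int8),
                                  band, format="csr")
    return cell.tocsr()


def _clusters_from_mask(mask_flat, values_flat, cell_adj, min_size):
    """Connected components of supra-threshold cells; returns (cells, mass)."""
    idx = np.flatnonzero(mask_flat)
    if idx.size == 0:
        return []
    sub = cell_adj[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    out = []
    for k in range(n_comp):
        cells = idx[labels == k]
        if cells.size >= min_size:
            out.append((cells, float(values_flat[cells].sum())))
    return out


def _signed_clusters(tmap_flat, t_crit, cell_adj, min_size):
    out = []
    for sign in (+1, -1):
        m = sign * tmap_flat > t_crit
        out += _clusters_from_mask(m, tmap_flat, cell_adj, min_size)
    return out


def _t_maps(effects_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t for many sign-flip assignments.

    ``effects_flat`` is (n_subj, n_cells); ``signs`` is (n_draws, n_subj).
    Sign flips leave per-cell sums of squares unchanged, so only the mean
    needs recomputing per draw.
    """
    n = effects_flat.shape[0]
    ssq = (effects_flat ** 2).sum(axis=0)
    mean = signs @ effects_flat / n
    var = (ssq / n - mean ** 2) * n / (n - 1)
    var = np.maximum(var, np.finfo(float).tiny)
    return mean / np.sqrt(var / n)


def cluster_perm_test(effects: np.ndarray, graph: NeighborGraph,
                      n_perm: int = 2000, t_thresh_p: float = 0.05,
                      min_size: int = 2, seed=None,
                      freq_adjacency: bool = True) -> ClusterResult:
    """Sign-flip cluster permutation test of participant x channel x freq effects."""
    effects = np.asarray(effects, dtype=float)
    if effects.ndim != 3:
        raise ValueError("effects must be (participants, channels, freqs)")
    n_subj, n_ch, n_freq = effects.shape
    if n_subj < 5:
        raise ValueError(f"need >= 5 participants, got {n_subj}")
    if n_ch != graph.n_channels:
        raise ValueError("graph does not cover the data channels")
    if not graph.is_connected():
        raise ValueError("neighbor graph is disconnected")

    flat = effects.reshape(n_subj, -1)
    t_crit = float(t_dist.ppf(1 - t_thresh_p / 2.0, df=n_subj - 1))
    cell_adj = _cell_adjacency(graph, n_freq, freq_adjacency)

    t_obs = _t_maps(flat, np.ones((1, n_subj)))[0]
    obs_clusters = _signed_clusters(t_obs, t_crit, cell_adj, min_size)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    t_null = _t_maps(flat, signs)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        cl = _signed_clusters(t_null[i], t_crit, cell_adj, min_size)
        if cl:
            null_max[i] = max(abs(m) for _, m in cl)

    clusters = []
    for cells, mass in sorted(obs_clusters, key=lambda c: -abs(c[1])):
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        ch_idx, f_idx = np.unravel_index(cells, (n_ch, n_freq))
        clusters.append({"cells": [(int(c), int(f)) for c, f in zip(ch_idx, f_idx)],
                         "channels": sorted(set(int(c) for c in ch_idx)),
                         "freq_indices": sorted(set(int(f) for f in f_idx)),
                         "mass": mass, "size": int(cells.size), "p": float(p)})
    return ClusterResult(clusters=clusters, n_perm=n_perm,
                         threshold=t_crit, null_max_mass=null_max)


def reduce_max_division(effects: np.ndarray) -> np.ndarray:
    """Group map: per-cell max over divisions, then mean over participants."""
    return np.asarray(effects, dtype=float).max(axis=-1).mean(axis=0)


def max_division_perm_test(effects: np.ndarray, null_sampler,
                           graph: NeighborGraph, n_perm: int = 2000,
                           percentile: float = 95.0, min_size: int = 2,
                           seed=None, freq_adjacency: bool = True) -> ClusterResult:
    """Permutation test for max-over-phase-division (non-negative) effects.

    ``effects`` is (participants, channels, freqs, n_divisions) of
    absolute differences; ``null_sampler(rng) -> same-shape array`` must
    recompute the effects under a permutation of the trial-behavior
    alignment, so the max-selection bias is present in the null.  Cells
    whose group-mean max-effect exceeds the cell-wise ``percentile`` of
    the null are clustered; the cluster statistic is the sum of null-
    standardized effects, compared to the null maximum cluster mass.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.ndim != 4:
        raise ValueError("effects must be (participants, channels, freqs, divisions)")
    rng = np.random.default_rng(seed)
    null = np.stack([reduce_max_division(np.asarray(null_sampler(rng), dtype=float))
                     for _ in range(n_perm)])
    return max_division_from_null(effects, null, graph, percentile=percentile,
                                  min_size=min_size, freq_adjacency=freq_adjacency)


def max_division_from_null(effects: np.ndarray, null_group_maps: np.ndarray,
                           graph: NeighborGraph, percentile: float = 95.0,
                           min_size: int = 2,
                           freq_adjacency: bool = True) -> ClusterResult:
    """Max-over-division cluster test given precomputed null group maps.

    ``null_group_maps`` is (n_perm, channels, freqs), each the reduced
    (max-over-division, mean-over-participant) map of one permuted-
    alignment recomputation; sharing one set of null maps across several
    effect families avoids recomputing the expensive null pipeline.
    """
    effects = np.asarray(effects, dtype=float)
    if np.any(effects < 0):
        raise ValueError("max-division effects must be non-negative")
    _, n_ch, n_freq, _ = effects.shape
    obs = reduce_max_division(effects)
    null = np.asarray(null_group_maps, dtype=float)
    n_perm = null.shape[0]

    thresh = np.percentile(null, percentile, axis=0)
    mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
    sd = np.maximum(sd, np.finfo(float).tiny)
    z_obs = ((obs - mu) / sd).ravel()
    cell_adj = _cell_adjacency(graph, n_freq, freq_adjacency)
    obs_clusters = _clusters_from_mask((obs > thresh).ravel(), z_obs,
                                       cell_adj, min_size)

    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        z_i = ((null[i] - mu) / sd).ravel()
        cl = _clusters_from_mask((null[i] > thresh).ravel(), z_i,
                                 cell_adj, min_size)
        if cl:
            null_max[i] = max(m for _, m in cl)

    clusters = []
    for cells, mass in sorted(obs_clusters, key=lambda c: -c[1]):
        p = (1.0 + np.sum(null_max >= mass)) / (1.0 + n_perm)
        ch_idx, f_idx = np.unravel_index(cells, (n_ch, n_freq))
        clusters.append({"cells": [(int(c), int(f)) for c, f in zip(ch_idx, f_idx)],
                         "channels": sorted(set(int(c) for c in ch_idx)),
                         "freq_indices": sorted(set(int(f) for f in f_idx)),
                         "mass": mass, "size": int(cells.size), "p": float(p)})
    return ClusterResult(clusters=clusters, n_perm=n_perm,
                         threshold=thresh, null_max_mass=null_max)


def fdr_bh(pvals, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(pvals.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(pvals.shape)
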