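"""Empirical edge-centric measures: edge time series, eFC, RSS, binary edges.

The edge time series of a node pair (i, j) is the element-wise product of
their z-scored signals, c_ij(t) = z_i(t) z_j(t); its time average is the
Pearson correlation r_ij.  The edge functional connectivity (eFC) is the
E x E matrix of normalised inner products between edge time series, with
E = N(N-1)/2.  The per-frame root-sum-of-squares (RSS) over edges measures
the total instantaneous cofluctuation; including all N^2 ordered pairs it
equals the squared Euclidean norm of the z-scored frame exactly, while the
published upper-triangular form is approximated by ||z(t)||^2 / sqrt(2)
with an error controlled by the kurtosis ratio diagnostic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .bold import BoldMatrix, as_zscored
from .correlation import CorrelationModel
from .errors import DegenerateEdgeError, InvalidInputError

RSS_CONVENTIONS = ("upper_triangular", "all_pairs")


class EdgeSet:
    """The ordered set of E = N(N-1)/2 node pairs (i < j), lexicographic."""

    def __init__(self, n_nodes: int) -> None:
        n = int(n_nodes)
        if n < 2:
            raise InvalidInputError("an edge set needs at least 2 nodes")
        self.n_nodes = n
        self.i_idx, self.j_idx = np.triu_indices(n, k=1)

    @property
    def n_edges(self) -> int:
        return self.i_idx.size

    def __len__(self) -> int:
        return self.n_edges

    def index(self, i: int, j: int) -> int:
        """Edge index of the unordered pair {i, j}."""
        if i == j:
            raise InvalidInputError("self-pairs are not edges")
        i, j = (i, j) if i < j else (j, i)
        n = self.n_nodes
        if not 0 <= i < j < n:
            raise InvalidInputError(f"pair ({i}, {j}) out of range for {n} nodes")
        return i * (2 * n - i - 1) // 2 + (j - i - 1)

    def pair(self, e: int) -> tuple[int, int]:
        if not 0 <= e < self.n_edges:
            raise InvalidInputError(f"edge index {e} out of range")
        return int(self.i_idx[e]), int(self.j_idx[e])

    def pairs(self) -> np.ndarray:
        """E x 2 array of (i, j) pairs in edge order."""
        return np.column_stack([self.i_idx, self.j_idx])


@dataclasses.dataclass
class EdgeTimeSeriesMatrix:
    """E x T matrix with row e = c_ij(t) for the e-th edge (i, j)."""

    values: np.ndarray
    edge_set: EdgeSet

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class EdgeFCMatrix:
    """E x E symmetric edge-FC matrix with entries in [-1, 1]."""

    values: np.ndarray
    edge_set: EdgeSet
    provenance: str = "empirical"  # or "predicted"


@dataclasses.dataclass
class RssSeries:
    """Per-frame RSS values under a stated convention."""

    values: np.ndarray
    convention: str = "upper_triangular"


@dataclasses.dataclass
class BinaryEdgeMatrix:
    """E x T binary cofluctuation-sign matrix; exact zeros counted as ties."""

    values: np.ndarray
    edge_set: EdgeSet
    tie_count: int


def edge_time_series(z: BoldMatrix) -> EdgeTimeSeriesMatrix:
    """Element-wise products z_i(t) z_j(t) for every pair i < j."""
    zb = as_zscored(z)
    es = EdgeSet(zb.n_nodes)
    values = zb.values[es.i_idx] * zb.values[es.j_idx]
    return EdgeTimeSeriesMatrix(values=values, edge_set=es)


def edge_fc(ets: EdgeTimeSeriesMatrix) -> EdgeFCMatrix:
    """Normalised inner products between all pairs of edge time series."""
    V = ets.values
    if V.shape[1] < 2:
        raise InvalidInputError("edge FC needs at least T=2 frames")
    norms = np.sqrt(np.einsum("et,et->e", V, V))
    if np.any(norms == 0.0):
        e = int(np.argmin(norms))
        i, j = ets.edge_set.pair(e)
        raise DegenerateEdgeError(f"edge ({i}, {j}) has an identically zero time series")
    M = (V @ V.T) / np.outer(norms, norms)
    M = np.clip((M + M.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(M, 1.0)
    return EdgeFCMatrix(values=M, edge_set=ets.edge_set, provenance="empirical")


def rss(z: BoldMatrix, convention: str = "upper_triangular") -> RssSeries:
    """Per-frame root-sum-of-squares of the edge time series.

    ``upper_triangular``: sqrt(sum_{i<j} c_ij^2) (the published measure).
    ``all_pairs``: sum over all N^2 ordered pairs, which collapses exactly
    to ||z(t)||^2.
    """
    if convention not in RSS_CONVENTIONS:
        raise InvalidInputError(f"unknown RSS convention {convention!r}")
    zb = as_zscored(z)
    s2 = np.einsum("it,it->t", zb.values, zb.values)  # ||z(t)||^2
    if convention == "all_pairs":
        values = s2
    else:
        s4 = np.einsum("it,it,it,it->t", zb.values, zb.values, zb.values, zb.values)
        values = np.sqrt(np.clip((s2 * s2 - s4) / 2.0, 0.0, None))
    return RssSeries(values=values, convention=convention)


def kurtosis_ratio_check(z: BoldMatrix) -> float:
    """Validity diagnostic for RSS(t) ~ ||z(t)||^2 / sqrt(2).

    Returns (sum_i mean_t z_i^4) / (mean_t ||z(t)||^4) in [0, 1]; the
    approximation is accurate when this is small (it is bounded by
    sum_i Kurt[z_i] / N^2, about 3/N for Gaussian signals).
    """
    zb = as_zscored(z)
    z2 = zb.values**2
    num = float(np.mean(np.sum(z2 * z2, axis=0)))
    den = float(np.mean(np.sum(z2, axis=0) ** 2))
    return num / den


def binarize_edges(ets: EdgeTimeSeriesMatrix) -> BinaryEdgeMatrix:
    """1 where the cofluctuation is positive, 0 otherwise.

    Exact zeros (measure zero under the null) binarise to 0 and are counted
    in ``tie_count`` so Bernoulli comparisons stay honest.
    """
    positive = ets.values > 0.0
    ties = int(np.count_nonzero(ets.values == 0.0))
    return BinaryEdgeMatrix(
        values=positive.astype(np.uint8), edge_set=ets.edge_set, tie_count=ties
    )


def matrix_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of the strict upper triangles of two N x N matrices."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InvalidInputError("matrix similarity requires two square matrices of equal shape")
    iu = np.triu_indices(a.shape[0], k=1)
    return float(stats.pearsonr(a[iu], b[iu]).statistic)


@dataclasses.dataclass
class FrameSortedSimilarity:
    """nFC reconstruction quality from RSS-sorted frame subsets."""

    fractions: np.ndarray
    descending: np.ndarray  # similarity using the top-RSS frames
    ascending: np.ndarray  # similarity using the bottom-RSS frames


def frame_sorted_reconstruction(
    z: BoldMatrix,
    r: CorrelationModel,
    fractions,
    rss_convention: str = "upper_triangular",
) -> FrameSortedSimilarity:
    """Similarity between the nFC and FC averaged over RSS-extreme frames.

    For each fraction f, frames are ranked by RSS (ties broken by frame
    index) and the mean outer product z(t) z(t)^T over the top (descending)
    or bottom (ascending) f*T frames is correlated (upper triangle, Pearson)
    with the nFC.  With f = 1 the mean outer product *is* the nFC under the
    population z-score convention, so both similarities equal 1.
    """
    zb = as_zscored(z)
    fr = np.atleast_1d(np.asarray(fractions, dtype=float))
    if np.any((fr <= 0.0) | (fr > 1.0)):
        raise InvalidInputError("fractions must lie in (0, 1]")
    T = zb.n_frames
    amp = rss(zb, rss_convention).values
    order_desc = np.argsort(-amp, kind="stable")
    R = r.matrix

    def _sim(selected: np.ndarray) -> float:
        zs = zb.values[:, selected]
        avg = (zs @ zs.T) / selected.size
        return matrix_similarity(avg, R)

    desc = np.empty(fr.size)
    asc = np.empty(fr.size)
    for idx, f in enumerate(fr):
        k = int(round(f * T))
        if k == 0:
            raise InvalidInputError(f"fraction {f} selects zero frames (T={T})")
        desc[idx] = _sim(order_desc[:k])
        asc[idx] = _sim(order_desc[::-1][:k])
    return FrameSortedSimilarity(fractions=fr, descending=desc, ascending=asc)
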