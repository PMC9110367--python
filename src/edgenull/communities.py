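"""Edge communities from eFC clustering and node-level cluster similarity.

Edges are clustered by k-means on the rows of the (empirical or predicted)
eFC matrix.  Because k-means labels are arbitrary, assignments from
different runs/subjects are compared after solving the optimal label
permutation (assignment problem on the contingency table), and a consensus
labelling takes the per-edge mode across aligned runs.  The node-level
"edge cluster similarity" of nodes i and j counts the fraction of common
targets m whose edges (i, m) and (j, m) share a label.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import mode as _mode
from sklearn.cluster import KMeans

from .edges import EdgeFCMatrix, EdgeSet
from .errors import InvalidInputError


@dataclasses.dataclass
class CommunityLabels:
    """Per-edge community assignment with labels in 1..k."""

    labels: np.ndarray
    k: int
    n_nodes: int
    seed: int | None = None
    inertia: float | None = None
    consensus: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        es = EdgeSet(self.n_nodes)
        if self.labels.shape != (es.n_edges,):
            raise InvalidInputError(
                f"expected {es.n_edges} edge labels for {self.n_nodes} nodes, "
                f"got {self.labels.shape}"
            )
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise InvalidInputError(f"labels must lie in 1..{self.k}")

    def label_matrix(self) -> np.ndarray:
        """N x N matrix of edge labels with -1 on the diagonal."""
        es = EdgeSet(self.n_nodes)
        L = -np.ones((self.n_nodes, self.n_nodes), dtype=int)
        L[es.i_idx, es.j_idx] = self.labels
        L[es.j_idx, es.i_idx] = self.labels
        return L


@dataclasses.dataclass
class EdgeClusterSimilarity:
    """N x N fraction of co-clustered shared-target edges; values in [0, 1]."""

    values: np.ndarray
    source: str = "empirical"  # or "predicted_from_eFC", "predicted_from_nFC"


def _efc_values(efc: EdgeFCMatrix | np.ndarray) -> tuple[np.ndarray, int]:
    if isinstance(efc, EdgeFCMatrix):
        return efc.values, efc.edge_set.n_nodes
    M = np.asarray(efc, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise InvalidInputError("eFC must be a square matrix")
    E = M.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
    if n * (n - 1) // 2 != E:
        raise InvalidInputError(f"eFC size {E} is not N(N-1)/2 for any integer N")
    return M, n


def cluster_edges(
    efc: EdgeFCMatrix | np.ndarray,
    k: int = 10,
    n_restarts: int = 20,
    seed: int | None = None,
) -> CommunityLabels:
    """k-means (Euclidean, plus-plus seeding) on the rows of the eFC.

    Best of ``n_restarts`` initialisations by inertia; deterministic given
    ``seed``.
    """
    M, n_nodes = _efc_values(efc)
    k = int(k)
    if k < 2:
        raise InvalidInputError("k must be at least 2")
    if k > M.shape[0]:
        raise InvalidInputError(f"k={k} exceeds the number of edges E={M.shape[0]}")
    km = KMeans(n_clusters=k, n_init=int(n_restarts), random_state=seed)
    raw = km.fit_predict(M)
    # Relabel to 1..k in order of first appearance so equal inputs give
    # identical labels regardless of centroid ordering.
    _, first = np.unique(raw, return_index=True)
    appearance = raw[np.sort(first)]
    remap = np.zeros(k, dtype=int)
    remap[appearance] = np.arange(1, appearance.size + 1)
    return CommunityLabels(
        labels=remap[raw],
        k=k,
        n_nodes=n_nodes,
        seed=seed,
        inertia=float(km.inertia_),
    )


def match_labels(a: CommunityLabels, b: CommunityLabels) -> tuple[np.ndarray, float]:
    """Optimal label permutation of ``b`` onto ``a`` and matched agreement.

    Solves the assignment problem on the k x k contingency table, so the
    agreement fraction does not depend on arbitrary label order.  Returns
    ``(perm, agreement)`` where ``perm[label_b - 1]`` is the matched label
    in ``a``'s scheme.
    """
    if a.n_nodes != b.n_nodes or a.labels.size != b.labels.size:
        raise InvalidInputError("label sets cover different edge sets")
    if a.k != b.k:
        raise InvalidInputError(f"cluster counts differ: {a.k} vs {b.k}")
    k = a.k
    contingency = np.zeros((k, k), dtype=np.int64)
    np.add.at(contingency, (b.labels - 1, a.labels - 1), 1)
    rows, cols = linear_sum_assignment(-contingency)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols + 1
    agreement = contingency[rows, cols].sum() / a.labels.size
    return perm, float(agreement)


def apply_permutation(labels: CommunityLabels, perm: np.ndarray) -> CommunityLabels:
    return dataclasses.replace(labels, labels=np.asarray(perm)[labels.labels - 1])


def consensus_labels(runs: Sequence[CommunityLabels]) -> CommunityLabels:
    """Per-edge modal label across runs after alignment to the first run.

    Ties break to the lowest label.  All runs must share k and edge set.
    """
    if len(runs) == 0:
        raise InvalidInputError("need at least one labelling")
    ref = runs[0]
    aligned = [ref.labels]
    for other in runs[1:]:
        perm, _ = match_labels(ref, other)
        aligned.append(apply_permutation(other, perm).labels)
    stacked = np.vstack(aligned)
    modal = _mode(stacked, axis=0).mode  # smallest value on ties
    return CommunityLabels(
        labels=np.asarray(modal, dtype=int),
        k=ref.k,
        n_nodes=ref.n_nodes,
        consensus=True,
    )


def edge_cluster_similarity(
    labels: CommunityLabels, source: str = "empirical"
) -> EdgeClusterSimilarity:
    """Fraction of shared targets whose edges from i and j are co-clustered.

    Entry (i, j) compares rows i and j of the N x N edge-label matrix over
    the N-2 columns m not in {i, j} (self-edge labels are undefined and
    excluded).  The diagonal is 1.
    """
    n = labels.n_nodes
    if n < 3:
        raise InvalidInputError("edge cluster similarity needs at least 3 nodes")
    L = labels.label_matrix()
    # The diagonal sentinel -1 never equals a real label, so the m == i and
    # m == j columns drop out of the match count automatically.
    matches = (L[:, None, :] == L[None, :, :]).sum(axis=2)
    S = matches / (n - 2)
    np.fill_diagonal(S, 1.0)
    return EdgeClusterSimilarity(values=S, source=source)
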