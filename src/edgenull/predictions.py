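"""Closed-form null-model predictions derived from the nFC alone.

Under the static Gaussian null (i.i.d. frames from N(0, R)) every
edge-centric quantity has a closed form in the entries of R:

* eFC entry for edges (j,k) and (l,m):
  (r_jk r_lm + r_jl r_km + r_jm r_kl) /
  (sqrt(1 + 2 r_jk^2) sqrt(1 + 2 r_lm^2))    (Isserlis / Wick pairing).
* the sign of a cofluctuation is a Bernoulli draw with success probability
  p_jk = 1/2 + arcsin(r_jk) / pi             (the arcsine / orthant law).
* the edge-to-edge l1 distance and the node-level distance
  d_ij proportional to sqrt(1 - r_ij), which predicts edge-cluster
  similarity without materialising the E x E matrix.
* a frame selected for seed activity z* has conditional expectation
  z* R_k, the coactivation-pattern (CAP) seed map.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .bold import BoldMatrix, as_zscored
from .correlation import CorrelationModel
from .edges import EdgeFCMatrix, EdgeSet
from .errors import DegenerateSignalError, InvalidInputError


def _as_model(r) -> CorrelationModel:
    return r if isinstance(r, CorrelationModel) else CorrelationModel(np.asarray(r, float))


@dataclasses.dataclass
class NodeDistanceMatrix:
    """Predicted node distances sqrt(1 - r_ij) (zero diagonal, range [0, sqrt(2)])."""

    values: np.ndarray
    #: Suppressed proportionality constant when known (data-derived), else None.
    scale_constant: float | None = None


def predict_efc(r: CorrelationModel | np.ndarray) -> EdgeFCMatrix:
    """Analytic eFC matrix implied by the nFC under the null.

    The diagonal is exactly 1 and, for identity R, all off-diagonal entries
    with four distinct nodes vanish.
    """
    model = _as_model(r)
    R = model.matrix
    es = EdgeSet(model.n_nodes)
    I, J = es.i_idx, es.j_idx
    rv = R[I, J]
    num = np.outer(rv, rv) + R[np.ix_(I, I)] * R[np.ix_(J, J)] + R[np.ix_(I, J)] * R[np.ix_(J, I)]
    den = np.sqrt(1.0 + 2.0 * rv**2)
    M = num / np.outer(den, den)
    M = np.clip((M + M.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(M, 1.0)
    return EdgeFCMatrix(values=M, edge_set=es, provenance="predicted")


def edge_distance(
    r: CorrelationModel | np.ndarray,
    edge_a: tuple[int, int],
    edge_b: tuple[int, int],
) -> float:
    """l1 distance between two rows of the (unnormalised) predicted eFC.

    Computed in correlation units as 3 * sum_{l,m} |r_jl r_mk - r_j'l r_mk'|
    over all ordered pairs (l, m); the (T-1)^2 inner-product scale is divided
    out because only relative distances matter for clustering.
    """
    model = _as_model(r)
    R = model.matrix
    es = EdgeSet(model.n_nodes)
    j, k = es.pair(es.index(*edge_a))
    jp, kp = es.pair(es.index(*edge_b))
    # G[l, m] = r_jl * r_mk as a rank-1 outer product over ordered pairs.
    diff = np.outer(R[j], R[:, k]) - np.outer(R[jp], R[:, kp])
    return float(3.0 * np.abs(diff).sum())


def predicted_node_distance(r: CorrelationModel | np.ndarray) -> NodeDistanceMatrix:
    """Node distance d_ij = sqrt(1 - r_ij), a monotone transform of the nFC."""
    model = _as_model(r)
    R = model.matrix
    if np.any(np.abs(R) > 1.0 + 1e-12):
        raise InvalidInputError("correlation entries must lie in [-1, 1]")
    values = np.sqrt(np.clip(1.0 - R, 0.0, None))
    np.fill_diagonal(values, 0.0)
    return NodeDistanceMatrix(values=values)


def bernoulli_probability(r_jk: float) -> float:
    """Success probability of the binary edge series: 1/2 + arcsin(r)/pi.

    Strictly increasing on [-1, 1] with p(-r) = 1 - p(r); p(0) = 1/2 and
    p(1) = 1 exactly.
    """
    r = float(r_jk)
    if not -1.0 <= r <= 1.0:
        raise InvalidInputError(f"correlation {r} outside [-1, 1]")
    return 0.5 + float(np.arcsin(r)) / np.pi


def predict_binary_nfc(r: CorrelationModel | np.ndarray) -> np.ndarray:
    """Predicted time-average of the binary edge series for every node pair.

    Applies the arcsine law elementwise; the diagonal is 1 (a node always
    agrees in sign with itself).
    """
    model = _as_model(r)
    P = 0.5 + np.arcsin(np.clip(model.matrix, -1.0, 1.0)) / np.pi
    np.fill_diagonal(P, 1.0)
    return P


def caps_expected_frame(
    r: CorrelationModel | np.ndarray, seed_node: int, seed_value: float
) -> np.ndarray:
    """Conditional expectation E[Z | Z_k = z*] = z* R_k (the CAP seed map)."""
    model = _as_model(r)
    k = int(seed_node)
    if not 0 <= k < model.n_nodes:
        raise InvalidInputError(f"seed node {k} out of range for {model.n_nodes} nodes")
    return float(seed_value) * model.matrix[:, k]


@dataclasses.dataclass
class CapsCurves:
    """Percentile-binned seed-map similarity curves.

    ``frame_similarity``: mean per-bin Pearson correlation between single
    frames (sorted by descending seed activity) and the seed column of R.
    ``cumulative_similarity``: correlation between the running average of
    all frames above each bin boundary and the seed column.
    ``coverage``: fraction of frames included at each bin boundary.
    """

    coverage: np.ndarray
    frame_similarity: np.ndarray
    cumulative_similarity: np.ndarray
    seed_node: int


def _columnwise_pearson(frames: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of ``frames`` with ``target``."""
    a = frames - frames.mean(axis=0, keepdims=True)
    b = target - target.mean()
    denom = np.sqrt(np.einsum("nt,nt->t", a, a)) * np.linalg.norm(b)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (a.T @ b) / denom
    return out


def caps_similarity_curves(
    z: BoldMatrix,
    r: CorrelationModel | np.ndarray,
    seed_node: int,
    n_bins: int = 20,
) -> CapsCurves:
    """Seed-sorted frame and running-average similarity to the seed FC map.

    Frames are sorted by descending seed activity (ties broken by frame
    index).  With a single frame the cumulative curve equals the per-frame
    curve.  Under the null the per-frame similarity decreases with the seed
    percentile, and the cumulative curve shows the rise-plateau-sharp-drop
    shape as anticorrelated frames enter the average.
    """
    model = _as_model(r)
    zb = as_zscored(z)
    k = int(seed_node)
    if not 0 <= k < zb.n_nodes:
        raise InvalidInputError(f"seed node {k} out of range")
    seed_series = zb.values[k]
    if np.ptp(seed_series) == 0.0:
        raise DegenerateSignalError(f"seed node {zb.node_ids[k]!r} has a constant series")
    T = zb.n_frames
    n_bins = int(min(max(n_bins, 1), T))
    order = np.argsort(-seed_series, kind="stable")
    sorted_frames = zb.values[:, order]
    target = model.matrix[:, k]

    per_frame = _columnwise_pearson(sorted_frames, target)
    groups = np.array_split(np.arange(T), n_bins)
    frame_curve = np.array([np.nanmean(per_frame[g]) for g in groups])
    boundaries = np.array([g[-1] + 1 for g in groups])  # frames included so far
    running = np.cumsum(sorted_frames, axis=1)[:, boundaries - 1] / boundaries
    cumulative_curve = _columnwise_pearson(running, target)
    coverage = boundaries / T
    return CapsCurves(
        coverage=coverage,
        frame_similarity=frame_curve,
        cumulative_similarity=cumulative_curve,
        seed_node=k,
    )
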