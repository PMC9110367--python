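"""Eigen-based diagnostics linking RSS peaks to the nFC spectrum.

Whitening the z-scored frame with R^(-1/2) turns the all-pairs RSS into a
weighted sum over eigen-directions,

    ||z(t)||^2 = ||w(t)||^2 * sum_i lambda_i cos^2 theta_i(t),

where theta_i(t) is the angle between the whitened frame w(t) and the i-th
nFC eigenvector.  The squared cosines sum to one per frame, which yields
the sharp bound RSS_all(t) <= lambda_max ||w(t)||^2, attained exactly when
the frame aligns with the leading eigenvector u_1 — in which case the
frame's rank-1 FC estimate is lambda_1 u_1 u_1^T (independent of sign).
These identities explain why high-RSS frames reconstruct the nFC well.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .bold import BoldMatrix, as_zscored
from .correlation import EIG_FLOOR, CorrelationModel
from .edges import EdgeSet, rss
from .errors import InvalidInputError


def whiten(z: BoldMatrix, r: CorrelationModel) -> np.ndarray:
    """W = R^(-1/2) Z using the spectral pseudo-inverse (1e-10 floor).

    If R is rank deficient and the data carry energy in the discarded
    eigenspace, a warning is issued and that energy is projected out.
    """
    zb = as_zscored(z)
    if zb.n_nodes != r.n_nodes:
        raise InvalidInputError("BOLD matrix and correlation model disagree on N")
    Z = zb.values
    if r.rank < r.n_nodes:
        U_null = r.eigenvectors[:, r.rank :]
        residual = U_null.T @ Z
        total = float(np.linalg.norm(Z))
        if total > 0 and float(np.linalg.norm(residual)) > 1e-8 * total:
            warnings.warn(
                "data have energy in the null space of R; projecting it out",
                RuntimeWarning,
            )
    return r.inv_sqrt_matrix() @ Z


def unwhiten(w: np.ndarray, r: CorrelationModel) -> np.ndarray:
    """Inverse map Z = R^(1/2) W (exact round-trip on the retained eigenspace)."""
    return r.sqrt_matrix() @ np.asarray(w, dtype=float)


@dataclasses.dataclass
class AlignmentProfile:
    """Per-frame eigen-alignment diagnostics.

    ``cos2`` is N x T with cos^2 theta_i(t); each column sums to 1 (NaN for
    zero frames, which are flagged).  ``rss_recomposed`` is the eigenvalue
    recomposition sum_i lambda_i cos^2 theta_i ||w||^2 / sqrt(2), equal to
    ||z||^2 / sqrt(2); ``rss_bound`` is lambda_max ||w||^2 / sqrt(2).
    """

    w_norm_sq: np.ndarray
    cos2: np.ndarray
    rss_recomposed: np.ndarray
    rss_bound: np.ndarray
    pc1_coefficient: np.ndarray
    zero_frames: np.ndarray


def alignment_profile(z: BoldMatrix, r: CorrelationModel) -> AlignmentProfile:
    """Whitened-space angles of every frame against every nFC eigenvector."""
    zb = as_zscored(z)
    W = whiten(zb, r)
    coords = r.eigenvectors.T @ W  # <u_i, w(t)>
    w_norm_sq = np.einsum("it,it->t", W, W)
    zero = w_norm_sq <= EIG_FLOOR
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2 = coords**2 / w_norm_sq
    cos2[:, zero] = np.nan
    lam = r.eigenvalues
    rss_recomposed = (lam @ coords**2) / np.sqrt(2.0)
    rss_bound = lam[0] * w_norm_sq / np.sqrt(2.0)
    pc1 = r.leading_eigenvector @ zb.values
    return AlignmentProfile(
        w_norm_sq=w_norm_sq,
        cos2=cos2,
        rss_recomposed=rss_recomposed,
        rss_bound=rss_bound,
        pc1_coefficient=pc1,
        zero_frames=zero,
    )


def rank1_fc(r: CorrelationModel) -> np.ndarray:
    """Leading-eigenvector FC approximation lambda_1 u_1 u_1^T.

    Sign-invariant in u_1.  A degenerate leading eigenvalue (gap below
    1e-10) makes u_1 non-unique; the deterministic sign/tie convention of
    the eigensolver is used and a warning is issued.
    """
    lam = r.eigenvalues
    if lam[0] <= EIG_FLOOR:
        raise InvalidInputError("leading eigenvalue is numerically zero")
    if lam.size > 1 and lam[0] - lam[1] < 1e-10:
        warnings.warn(
            "leading eigenvalue is degenerate; the returned eigenvector is one "
            "deterministic choice within the tied subspace",
            RuntimeWarning,
        )
    u1 = r.leading_eigenvector
    return lam[0] * np.outer(u1, u1)


def top_eigvec_similarity(z: BoldMatrix, r: CorrelationModel, k: int) -> pd.DataFrame:
    """Per-frame similarity to the leading eigenvector FC estimates.

    For each frame t, the Pearson correlation (over the E upper-triangular
    entries) between the instantaneous FC estimate z(t) z(t)^T and each
    rank-1 estimate lambda_i u_i u_i^T for i = 1..k, together with the RSS
    and the first principal-component coefficient <u_1, z(t)>.  Note the
    lambda_i weighting cancels in the Pearson similarity, so the columns are
    identical with or without it.
    """
    k = int(k)
    if not 1 <= k <= r.n_nodes:
        raise InvalidInputError(f"k must lie in [1, {r.n_nodes}]")
    zb = as_zscored(z)
    es = EdgeSet(zb.n_nodes)
    F = zb.values[es.i_idx] * zb.values[es.j_idx]  # E x T frame FC upper triangles
    V = r.eigenvectors[:, :k]
    G = (V[es.i_idx] * V[es.j_idx]) * r.eigenvalues[:k]  # E x k eigen FC estimates

    Fc = F - F.mean(axis=0, keepdims=True)
    Gc = G - G.mean(axis=0, keepdims=True)
    denom = np.outer(
        np.sqrt(np.einsum("et,et->t", Fc, Fc)), np.sqrt(np.einsum("ek,ek->k", Gc, Gc))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = (Fc.T @ Gc) / denom

    data = {
        "frame": np.arange(zb.n_frames),
        "rss": rss(zb).values,
        "pc1_coefficient": r.leading_eigenvector @ zb.values,
    }
    for i in range(k):
        data[f"sim_eig{i + 1}"] = sims[:, i]
    return pd.DataFrame(data)
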