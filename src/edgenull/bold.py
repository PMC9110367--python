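"""The BOLD matrix container and z-scoring.

A :class:`BoldMatrix` holds an N x T (nodes x frames) signal matrix.  All
edge-centric quantities are computed from the z-scored form, where each row
is centred and scaled by its *population* standard deviation (divide by T).
Under this convention the time average of an edge time series equals the
Pearson correlation of the two nodes exactly, which keeps every downstream
identity exact; the convention actually used is recorded on the object.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import DegenerateSignalError, InvalidInputError


class BoldMatrix:
    """Nodes x frames signal matrix.

    Parameters
    ----------
    values:
        N x T numeric matrix; rows are node time series.
    node_ids:
        Optional node labels (defaults to ``"0" .. "N-1"``).
    zscored:
        Whether ``values`` is already z-scored.
    mean, std:
        Per-node centring/scaling used when z-scoring produced ``values``.
    zscore_ddof:
        Delta degrees of freedom of the standard-deviation denominator
        (0 = population convention, the package default).
    """

    def __init__(
        self,
        values: np.ndarray,
        node_ids: Sequence[str] | None = None,
        *,
        zscored: bool = False,
        mean: np.ndarray | None = None,
        std: np.ndarray | None = None,
        zscore_ddof: int = 0,
    ) -> None:
        arr = np.array(values, dtype=float)
        if arr.ndim != 2:
            raise InvalidInputError(f"BOLD matrix must be 2-D, got {arr.ndim}-D")
        if arr.shape[1] < 2:
            raise InvalidInputError("BOLD matrix needs at least T=2 frames")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("BOLD matrix contains non-finite values")
        self.values = arr
        self.zscored = bool(zscored)
        self.mean = None if mean is None else np.asarray(mean, dtype=float)
        self.std = None if std is None else np.asarray(std, dtype=float)
        self.zscore_ddof = int(zscore_ddof)
        if node_ids is None:
            node_ids = tuple(str(i) for i in range(arr.shape[0]))
        elif len(node_ids) != arr.shape[0]:
            raise InvalidInputError("node_ids length does not match number of rows")
        self.node_ids = tuple(node_ids)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = "z" if self.zscored else "raw"
        return f"BoldMatrix(N={self.n_nodes}, T={self.n_frames}, {tag})"


def zscore(raw: BoldMatrix, ddof: int = 0) -> BoldMatrix:
    """Z-score each node time series (row means 0, population scale by default).

    Raises :class:`DegenerateSignalError` naming the node if any row is
    constant.  Idempotent on already z-scored input (to floating point).
    """
    x = raw.values
    mu = x.mean(axis=1)
    sigma = x.std(axis=1, ddof=ddof)
    if np.any(sigma == 0.0):
        bad = int(np.argmin(sigma))
        raise DegenerateSignalError(
            f"node {raw.node_ids[bad]!r} has a constant time series (zero variance)"
        )
    z = (x - mu[:, None]) / sigma[:, None]
    return BoldMatrix(
        z,
        node_ids=raw.node_ids,
        zscored=True,
        mean=mu,
        std=sigma,
        zscore_ddof=ddof,
    )


def as_zscored(bold: BoldMatrix) -> BoldMatrix:
    """Return ``bold`` if flagged z-scored, otherwise a z-scored copy."""
    return bold if bold.zscored else zscore(bold)
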