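"""Node correlation matrices (nFC) with their eigensystems, and generators.

The node functional connectivity (nFC) matrix ``R`` is the N x N Pearson
correlation matrix between regional time series.  Every analytic null-model
prediction in this package is a function of ``R`` alone, usually through its
eigendecomposition ``R = U diag(lambda) U^T`` with eigenvalues sorted in
descending order.  :class:`CorrelationModel` wraps the validated matrix with
a cached eigensystem and the spectral square roots used for whitening and
surrogate sampling.

:func:`build_correlation` constructs the standard test-bed matrices: the
identity (independent nodes), modular block matrices (planted functional
modules), and random factor models (generic dense correlation structure).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

#: Eigenvalues below this floor are treated as exact zeros (rank deficiency).
EIG_FLOOR = 1e-10

#: Most negative eigenvalue tolerated by the PSD repair of explicit matrices.
PSD_REPAIR_TOL = 1e-8

_KINDS = ("identity", "modular", "random_factor", "explicit")


@dataclasses.dataclass(frozen=True)
class CorrelationSpec:
    """Recipe for a synthetic node correlation matrix.

    Parameters
    ----------
    n_nodes:
        Number of nodes N.
    kind:
        One of ``identity``, ``modular``, ``random_factor``, ``explicit``.
    module_sizes:
        Block sizes for the modular kind; must sum to ``n_nodes``.
    rho_within:
        Correlation inside a module, in ``[0, 1)``.
    rho_between:
        Correlation between nodes of different modules, in ``(-1, 1)``.
    n_factors:
        Number of latent factors for the random-factor kind.
    matrix:
        Explicit symmetric matrix for the explicit kind.
    seed:
        Seed for the random-factor construction (ignored otherwise).
    """

    n_nodes: int
    kind: str = "identity"
    module_sizes: tuple[int, ...] | None = None
    rho_within: float = 0.0
    rho_between: float = 0.0
    n_factors: int = 1
    matrix: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidInputError(
                f"unknown correlation kind {self.kind!r}; expected one of {_KINDS}"
            )
        if int(self.n_nodes) < 1:
            raise InvalidInputError("n_nodes must be a positive integer")
        if self.module_sizes is not None:
            object.__setattr__(self, "module_sizes", tuple(int(m) for m in self.module_sizes))


def _fix_eigvec_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|component| entry made positive.

    ``argmax`` resolves exact ties at the lowest index.
    """
    anchor = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[anchor, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


class CorrelationModel:
    """A validated correlation matrix with its cached eigendecomposition.

    The matrix must be square, symmetric, unit-diagonal and positive
    semi-definite.  Matrices whose smallest eigenvalue lies in
    ``(-PSD_REPAIR_TOL, 0)`` are repaired by clipping the offending
    eigenvalues to zero and renormalising to unit diagonal (floating-point
    noise); anything more negative is rejected.
    """

    def __init__(
        self,
        matrix: np.ndarray,
        node_ids: Sequence[str] | None = None,
        *,
        repair: bool = True,
    ) -> None:
        R = np.array(matrix, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise InvalidInputError(f"correlation matrix must be square, got shape {R.shape}")
        n = R.shape[0]
        if not np.allclose(R, R.T, atol=1e-8, rtol=0.0):
            raise InvalidInputError("correlation matrix is not symmetric (tolerance 1e-8)")
        if not np.allclose(np.diag(R), 1.0, atol=1e-6, rtol=0.0):
            bad = int(np.argmax(np.abs(np.diag(R) - 1.0)))
            raise InvalidInputError(
                f"correlation matrix diagonal must be 1; entry {bad} is {R[bad, bad]:.6g}"
            )
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)

        evals = np.linalg.eigvalsh(R)
        lam_min = float(evals[0])
        if lam_min < -PSD_REPAIR_TOL:
            raise InvalidInputError(
                f"matrix is not positive semi-definite (min eigenvalue {lam_min:.3e} "
                f"< -{PSD_REPAIR_TOL:g})"
            )
        if lam_min < 0.0:
            if not repair:
                raise InvalidInputError(
                    f"matrix has a negative eigenvalue {lam_min:.3e} and repair is disabled"
                )
            w, V = np.linalg.eigh(R)
            w = np.clip(w, 0.0, None)
            R = (V * w) @ V.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
            R = (R + R.T) / 2.0
            np.fill_diagonal(R, 1.0)

        w, V = np.linalg.eigh(R)
        order = np.argsort(w)[::-1]
        self._eigenvalues = np.clip(w[order], 0.0, None)
        self._eigenvectors = _fix_eigvec_signs(V[:, order])
        self._matrix = R
        self._sqrt: np.ndarray | None = None
        self._inv_sqrt: np.ndarray | None = None
        if node_ids is None:
            node_ids = tuple(str(i) for i in range(n))
        elif len(node_ids) != n:
            raise InvalidInputError("node_ids length does not match matrix size")
        self.node_ids = tuple(node_ids)

    # -- basic accessors ---------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        """The N x N correlation matrix R."""
        return self._matrix

    @property
    def n_nodes(self) -> int:
        return self._matrix.shape[0]

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted in descending order (clipped at zero)."""
        return self._eigenvalues

    @property
    def eigenvectors(self) -> np.ndarray:
        """Orthonormal eigenvectors as columns, matching ``eigenvalues`` order."""
        return self._eigenvectors

    @property
    def leading_eigenvector(self) -> np.ndarray:
        return self._eigenvectors[:, 0]

    @property
    def rank(self) -> int:
        """Number of eigenvalues above the numerical floor."""
        return int(np.sum(self._eigenvalues > EIG_FLOOR))

    @property
    def is_degenerate(self) -> bool:
        """True when some retained eigenvalue gap is below 1e-10 (non-unique
        eigenvectors within the tied block)."""
        lam = self._eigenvalues[: self.rank]
        return bool(lam.size > 1 and np.any(np.abs(np.diff(lam)) < 1e-10))

    # -- spectral square roots --------------------------------------------
    def sqrt_matrix(self) -> np.ndarray:
        """R^(1/2) = U diag(sqrt(lambda)) U^T (symmetric square root)."""
        if self._sqrt is None:
            lam, U = self._eigenvalues, self._eigenvectors
            self._sqrt = (U * np.sqrt(lam)) @ U.T
        return self._sqrt

    def inv_sqrt_matrix(self) -> np.ndarray:
        """Spectral pseudo-inverse square root with the ``EIG_FLOOR`` cutoff."""
        if self._inv_sqrt is None:
            lam, U = self._eigenvalues, self._eigenvectors
            inv = np.where(lam > EIG_FLOOR, 1.0 / np.sqrt(np.where(lam > EIG_FLOOR, lam, 1.0)), 0.0)
            self._inv_sqrt = (U * inv) @ U.T
        return self._inv_sqrt

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_bold(cls, bold) -> "CorrelationModel":
        """Estimate the nFC from a BOLD matrix (Pearson correlation)."""
        from .bold import as_zscored

        z = as_zscored(bold).values
        T = z.shape[1]
        R = (z @ z.T) / T
        np.fill_diagonal(R, 1.0)
        return cls(R, node_ids=bold.node_ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CorrelationModel(n_nodes={self.n_nodes}, rank={self.rank})"


def _modular_matrix(spec: CorrelationSpec) -> np.ndarray:
    if spec.module_sizes is None:
        raise InvalidInputError("modular kind requires module_sizes")
    sizes = spec.module_sizes
    if any(m < 1 for m in sizes):
        raise InvalidInputError("module sizes must be positive")
    if sum(sizes) != spec.n_nodes:
        raise InvalidInputError(
            f"module sizes {sizes} sum to {sum(sizes)}, expected n_nodes={spec.n_nodes}"
        )
    if not 0.0 <= spec.rho_within < 1.0:
        raise InvalidInputError("rho_within must lie in [0, 1)")
    if not -1.0 < spec.rho_between < 1.0:
        raise InvalidInputError("rho_between must lie in (-1, 1)")
    n = spec.n_nodes
    R = np.full((n, n), spec.rho_between, dtype=float)
    start = 0
    for m in sizes:
        R[start : start + m, start : start + m] = spec.rho_within
        start += m
    np.fill_diagonal(R, 1.0)
    return R


def _random_factor_matrix(spec: CorrelationSpec) -> np.ndarray:
    if spec.n_factors < 1:
        raise InvalidInputError("n_factors must be a positive integer")
    rng = np.random.default_rng(spec.seed)
    loadings = rng.standard_normal((spec.n_nodes, spec.n_factors))
    S = loadings @ loadings.T + np.eye(spec.n_nodes)  # unit idiosyncratic variance
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def build_correlation(spec: CorrelationSpec) -> CorrelationModel:
    """Construct the correlation model described by ``spec``.

    Explicit matrices are validated (and PSD-repaired within tolerance);
    generated kinds are PSD by construction up to floating-point noise.
    """
    if spec.kind == "identity":
        mat = np.eye(spec.n_nodes)
    elif spec.kind == "modular":
        mat = _modular_matrix(spec)
    elif spec.kind == "random_factor":
        mat = _random_factor_matrix(spec)
    else:  # explicit
        if spec.matrix is None:
            raise InvalidInputError("explicit kind requires a matrix")
        mat = np.asarray(spec.matrix, dtype=float)
        if mat.shape != (spec.n_nodes, spec.n_nodes):
            raise InvalidInputError(
                f"explicit matrix shape {mat.shape} does not match n_nodes={spec.n_nodes}"
            )
    return CorrelationModel(mat)
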