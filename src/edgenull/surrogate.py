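"""Surrogate BOLD generators realising the static Gaussian null model.

The null hypothesis states that the z-scored BOLD frames are i.i.d. draws
from N(0, R): spatial correlations are preserved, temporal ones destroyed.
:func:`sample_bold` realises exactly this, mixing standard-normal frames
with the spectral square root R^(1/2) = U diag(sqrt(lambda)) U^T so that
whitening with R^(-1/2) round-trips exactly.

A first-order autoregressive (AR(1)) variant provides a temporally
correlated contrast: innovations are scaled by sqrt(1 - a^2) so the
stationary spatial covariance stays equal to R and only the temporal
structure differs from the null.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import lfilter

from .bold import BoldMatrix
from .correlation import CorrelationModel, CorrelationSpec, build_correlation
from .errors import InvalidInputError

_TEMPORAL_MODELS = ("iid", "ar1")


@dataclasses.dataclass(frozen=True)
class SurrogateSpec:
    """Recipe for a surrogate BOLD matrix.

    ``correlation`` may be a :class:`CorrelationSpec` (built on demand) or a
    ready :class:`CorrelationModel`.  ``seed`` drives a single named numpy
    Generator; identical specs produce bit-identical surrogates.
    """

    correlation: CorrelationSpec | CorrelationModel
    n_frames: int
    temporal_model: str = "iid"
    ar_coefficient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temporal_model not in _TEMPORAL_MODELS:
            raise InvalidInputError(
                f"temporal_model must be one of {_TEMPORAL_MODELS}, got {self.temporal_model!r}"
            )
        if int(self.n_frames) < 2:
            raise InvalidInputError("n_frames must be at least 2")
        if self.temporal_model == "ar1" and not -1.0 < self.ar_coefficient < 1.0:
            raise InvalidInputError("ar_coefficient must lie in (-1, 1)")

    def correlation_model(self) -> CorrelationModel:
        if isinstance(self.correlation, CorrelationModel):
            return self.correlation
        return build_correlation(self.correlation)


def sample_bold(spec: SurrogateSpec) -> BoldMatrix:
    """Draw an N x T surrogate BOLD matrix according to ``spec``.

    iid: columns are independent N(0, R) draws.  ar1: x(t) = a x(t-1) +
    sqrt(1-a^2) R^(1/2) eps(t), initialised at stationarity, so the marginal
    distribution of every frame is still N(0, R).
    """
    model = spec.correlation_model()
    rng = np.random.default_rng(spec.seed)
    n, T = model.n_nodes, int(spec.n_frames)
    innovations = model.sqrt_matrix() @ rng.standard_normal((n, T))
    if spec.temporal_model == "iid":
        values = innovations
    else:
        a = float(spec.ar_coefficient)
        s = np.sqrt(1.0 - a * a)
        x0 = innovations[:, :1]  # stationary start: x(0) ~ N(0, R)
        rest, _ = lfilter([s], [1.0, -a], innovations[:, 1:], axis=1, zi=a * x0)
        values = np.concatenate([x0, rest], axis=1)
    return BoldMatrix(values, node_ids=model.node_ids)
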