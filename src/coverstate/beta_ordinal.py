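"""Beta-distributed cover proportions and their discretisation into ordinal classes.

Visually determined plant cover is recorded as an ordered class (e.g. a
six-class scheme with boundaries at 1%, 10%, 25%, 50% and 75% cover).  The
underlying continuous cover proportion ``p`` in a quadrat is modelled as a
beta random variable parameterised by its mean ``mu`` and a dispersion
``delta`` in (0, 1):

    p ~ Beta(mu * phi, (1 - mu) * phi),    phi = (1 - delta) / delta

so that Var(p) = delta * mu * (1 - mu).  ``delta`` is interpretable as the
intra-quadrat spatial correlation of plant occupancy, or — when small — as
the observation uncertainty of a visual cover estimate.

The probability that an observer records class ``Y`` is the beta probability
mass between the class boundaries, i.e. a difference of regularized
incomplete beta functions evaluated at the cut points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special

__all__ = [
    "DEFAULT_BOUNDARIES",
    "CutPoints",
    "BetaMeanDispersion",
    "mu_delta_to_shapes",
    "interval_probability",
    "class_probabilities",
    "classify_proportion",
]

#: Default six-class scheme: [0, 0.01], (0.01, 0.1], (0.1, 0.25], (0.25, 0.5],
#: (0.5, 0.75], (0.75, 1].
DEFAULT_BOUNDARIES: tuple[float, ...] = (0.0, 0.01, 0.1, 0.25, 0.5, 0.75, 1.0)

# Guard for extreme latent states: logit^-1 underflows for |linear predictor|
# beyond ~36, which would push the beta shapes to 0 and the incomplete beta
# function out of its numerically safe domain.
_UNIT_EPS = 1e-6


def _clip_unit(x, eps: float = _UNIT_EPS):
    """Clip a proportion-valued quantity into the open interval (0, 1)."""
    return np.clip(x, eps, 1.0 - eps)


@dataclass(frozen=True)
class CutPoints:
    """Ordered class boundaries ``d_0 < d_1 < ... < d_K`` on [0, 1].

    Class ``Y`` (1-based) covers the interval ``(d_{Y-1}, d_Y]``; class 1
    additionally includes 0, so that non-detection folds into the lowest
    class.
    """

    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 3:
            raise ValueError("cut points need at least 3 boundaries (K >= 2)")
        if not (b[0] == 0.0 and b[-1] == 1.0):
            raise ValueError("cut points must start at 0 and end at 1")
        if not np.all(np.diff(b) > 0):
            raise ValueError("cut points must be strictly increasing")
        object.__setattr__(self, "boundaries", tuple(float(x) for x in b))

    @property
    def K(self) -> int:
        """Number of ordinal classes."""
        return len(self.boundaries) - 1

    @property
    def inner(self) -> np.ndarray:
        """The K-1 interior boundaries ``d_1 .. d_{K-1}``."""
        return np.asarray(self.boundaries[1:-1], dtype=float)

    @classmethod
    def default(cls) -> "CutPoints":
        return cls(DEFAULT_BOUNDARIES)

    @classmethod
    def from_inner(cls, inner: Sequence[float]) -> "CutPoints":
        """Build from the interior boundaries only (0 and 1 are implied)."""
        return cls((0.0, *map(float, inner), 1.0))


@dataclass(frozen=True)
class BetaMeanDispersion:
    """Mean/dispersion parameterisation of a beta-distributed proportion."""

    mu: float
    delta: float

    def __post_init__(self) -> None:
        _validate_mu_delta(self.mu, self.delta)

    @property
    def shapes(self) -> tuple[float, float]:
        return mu_delta_to_shapes(self.mu, self.delta)

    @property
    def variance(self) -> float:
        return self.delta * self.mu * (1.0 - self.mu)

    def class_probabilities(self, cuts: CutPoints | None = None) -> np.ndarray:
        return class_probabilities(self.mu, self.delta, cuts)


def _validate_mu_delta(mu, delta) -> None:
    mu = np.asarray(mu, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(~np.isfinite(mu)) or np.any((mu <= 0.0) | (mu >= 1.0)):
        raise ValueError(f"mu must lie strictly in (0, 1); got {mu!r}")
    if np.any(~np.isfinite(delta)) or np.any((delta <= 0.0) | (delta >= 1.0)):
        raise ValueError(f"delta must lie strictly in (0, 1); got {delta!r}")


def mu_delta_to_shapes(mu, delta):
    """Convert (mean, dispersion) to beta shape parameters (alpha, beta).

    ``alpha = mu * (1 - delta) / delta`` and
    ``beta = (1 - mu) * (1 - delta) / delta``; their sum is the precision
    ``phi = (1 - delta) / delta``.  Broadcasts over array inputs.
    """
    _validate_mu_delta(mu, delta)
    mu = np.asarray(mu, dtype=float)
    delta = np.asarray(delta, dtype=float)
    phi = (1.0 - delta) / delta
    alpha = mu * phi
    beta = (1.0 - mu) * phi
    if alpha.ndim == 0:
        return float(alpha), float(beta)
    return alpha, beta


def interval_probability(mu, delta, x0: float, x1: float):
    """Probability that the cover proportion falls in ``(x0, x1]``.

    The beta CDF is the regularized incomplete beta function, so this is
    ``I_{x1}(alpha, beta) - I_{x0}(alpha, beta)``.
    """
    x0 = float(x0)
    x1 = float(x1)
    if not (0.0 <= x0 < x1 <= 1.0):
        raise ValueError(f"need 0 <= x0 < x1 <= 1; got x0={x0}, x1={x1}")
    alpha, beta = mu_delta_to_shapes(mu, delta)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    out = special.betainc(alpha, beta, x1) - special.betainc(alpha, beta, x0)
    out = np.clip(out, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def class_probabilities(mu, delta, cuts: CutPoints | None = None) -> np.ndarray:
    """Probability of each ordinal class under Beta(mu, delta).

    Element ``Y`` (0-based ``Y-1``) is the beta mass on ``(d_{Y-1}, d_Y]``.
    Broadcasts: for array ``mu`` the class axis is appended last, giving
    shape ``mu.shape + (K,)``.  Rows sum to 1 up to floating point error.
    """
    if cuts is None:
        cuts = CutPoints.default()
    alpha, beta = mu_delta_to_shapes(mu, delta)
    alpha = np.asarray(alpha, dtype=float)[..., None]
    beta = np.asarray(beta, dtype=float)[..., None]
    bounds = np.asarray(cuts.boundaries, dtype=float)
    cdf = special.betainc(alpha, beta, bounds)
    probs = np.clip(np.diff(cdf, axis=-1), 0.0, 1.0)
    if probs.ndim == 1:
        return probs
    return probs


def classify_proportion(p, cuts: CutPoints | None = None):
    """Map a cover proportion to its ordinal class label in {1..K}.

    Classes are left-open/right-closed, ``(d_{Y-1}, d_Y]``, with class 1
    also containing 0 (non-detection).
    """
    if cuts is None:
        cuts = CutPoints.default()
    p_arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p_arr)) or np.any((p_arr < 0.0) | (p_arr > 1.0)):
        raise ValueError(f"proportion p must lie in [0, 1]; got {p!r}")
    # side='left': p equal to a boundary stays in the lower class.
    labels = np.searchsorted(cuts.inner, p_arr, side="left") + 1
    if labels.ndim == 0:
        return int(labels)
    return labels.astype(np.int64)
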