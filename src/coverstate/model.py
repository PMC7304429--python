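"""Joint probabilistic model for cover-class panels.

The model is a hierarchical state-space model on an annual (unit-spaced)
time grid:

* System model.  A latent logit-scale cover level ``theta_t`` evolves by a
  second-order random walk, ``theta_t | theta_{t-1}, theta_{t-2} ~
  Normal(2*theta_{t-1} - theta_{t-2}, sigma_T^2)`` — equivalently an AR(2)
  process with coefficients (2, -1) that penalises curvature rather than
  level changes.  The process runs over every grid step, including calendar
  years with no survey, which is what lets the model interpolate (and
  report growing uncertainty for) unobserved years.
* Spatial effects.  At each surveyed occasion the quadrats, arranged on a
  line, carry effects ``r_{t,q}`` following a first-order random walk over
  the quadrat index, ``r_{t,q} - r_{t,q-1} ~ Normal(0, sigma_R^2)``, with a
  weakly informative Normal(0, 2.5^2) prior anchoring the first quadrat.
  The effects are centred to sum to zero within each occasion so that they
  do not compete with the temporal intercept.
* Observation model.  The recorded class for quadrat q at occasion t is
  drawn from the ordinal-beta distribution with mean
  ``mu_{t,q} = logit^-1(theta_t + r_{t,q})`` and shared dispersion delta.

Priors: theta_1, theta_2 ~ Normal(0, 2.5^2); sigma_T, sigma_R ~
HalfNormal(0, 2.5^2); delta ~ Uniform(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .beta_ordinal import CutPoints, _clip_unit, class_probabilities

__all__ = [
    "MISSING",
    "PRIOR_SCALE",
    "TimeGrid",
    "CoverPanel",
    "ModelParams",
    "center_effects",
    "log_prior",
    "log_temporal",
    "log_spatial",
    "log_likelihood",
    "log_joint",
]

#: Sentinel for an unobserved (occasion, quadrat) cell.
MISSING: int = -1

#: Standard deviation of the weakly informative normal/half-normal priors.
PRIOR_SCALE: float = 2.5


@dataclass(frozen=True)
class TimeGrid:
    """Unit-spaced model time covering the full calendar span of a survey.

    ``labels`` are consecutive calendar labels (years, or plain indices) for
    the ``T`` grid steps; ``observed_mask[t]`` is True where at least one
    quadrat was surveyed.
    """

    labels: tuple[int, ...]
    observed_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        mask = np.asarray(self.observed_mask, dtype=bool)
        if labels.size < 3:
            raise ValueError("time grid needs at least 3 steps (AR(2) needs two predecessors)")
        if labels.size != mask.size:
            raise ValueError("labels and observed_mask must have equal length")
        if not np.all(np.diff(labels) == 1):
            raise ValueError("grid labels must be consecutive integers")
        if not mask.any():
            raise ValueError("time grid must contain at least one observed step")
        object.__setattr__(self, "labels", tuple(int(x) for x in labels))
        object.__setattr__(self, "observed_mask", tuple(bool(x) for x in mask))

    @property
    def n_steps(self) -> int:
        return len(self.labels)

    @property
    def observed_steps(self) -> np.ndarray:
        """Indices of grid steps with observations, in time order."""
        return np.flatnonzero(np.asarray(self.observed_mask))

    def step_of(self, label: int) -> int:
        """Grid-step index of a calendar label."""
        idx = int(label) - self.labels[0]
        if not (0 <= idx < self.n_steps):
            raise KeyError(f"label {label} outside grid {self.labels[0]}..{self.labels[-1]}")
        return idx

    @classmethod
    def from_observed_labels(cls, observed: Sequence[int]) -> "TimeGrid":
        """Build the unit-spaced grid spanning min..max of the observed labels."""
        obs = np.unique(np.asarray(observed, dtype=np.int64))
        if obs.size == 0:
            raise ValueError("no observed labels supplied")
        lo, hi = int(obs[0]), int(obs[-1])
        if hi - lo + 1 < 3:
            hi = lo + 2  # pad so the AR(2) prior is well defined
        labels = np.arange(lo, hi + 1)
        mask = np.isin(labels, obs)
        return cls(tuple(labels), tuple(mask))


@dataclass(frozen=True)
class CoverPanel:
    """Observed class labels indexed by (survey occasion, quadrat).

    ``classes[o, q]`` is the ordinal label in {1..K} or :data:`MISSING`;
    ``occasions[o]`` maps each row to its step on the :class:`TimeGrid`.
    Quadrat index order is spatial order along the line.
    """

    classes: np.ndarray
    occasions: np.ndarray
    cuts: CutPoints = field(default_factory=CutPoints.default)

    def __post_init__(self) -> None:
        classes = np.asarray(self.classes, dtype=np.int64)
        occasions = np.asarray(self.occasions, dtype=np.int64)
        if classes.ndim != 2:
            raise ValueError("classes must be a 2-D (occasion, quadrat) array")
        if occasions.ndim != 1 or occasions.size != classes.shape[0]:
            raise ValueError("occasions must map each panel row to a grid step")
        if not np.all(np.diff(occasions) > 0):
            raise ValueError("occasions must be strictly increasing grid steps")
        valid = (classes == MISSING) | ((classes >= 1) & (classes <= self.cuts.K))
        if not valid.all():
            bad = classes[~valid]
            raise ValueError(f"class labels must be in 1..{self.cuts.K} or MISSING; got {bad[:5]}")
        object.__setattr__(self, "classes", classes)
        object.__setattr__(self, "occasions", occasions)

    @property
    def n_occasions(self) -> int:
        return self.classes.shape[0]

    @property
    def n_quadrats(self) -> int:
        return self.classes.shape[1]

    @property
    def observed_mask(self) -> np.ndarray:
        return self.classes != MISSING

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())


@dataclass(frozen=True)
class ModelParams:
    """One point in parameter space.

    ``theta`` has one entry per grid step; ``r_raw`` one row per *observed*
    occasion (spatial effects are a priori independent across occasions and
    unidentified at unobserved steps).  ``r_raw`` is the pre-centering free
    parameter; the likelihood uses the per-occasion centred version.
    """

    theta: np.ndarray
    r_raw: np.ndarray
    delta: float
    sigma_T: float
    sigma_R: float

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        r_raw = np.asarray(self.r_raw, dtype=float)
        if theta.ndim != 1 or theta.size < 3:
            raise ValueError("theta must be a vector with at least 3 steps")
        if r_raw.ndim != 2:
            raise ValueError("r_raw must be a 2-D (occasion, quadrat) array")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "r_raw", r_raw)

    @property
    def r(self) -> np.ndarray:
        """Per-occasion sum-to-zero centred spatial effects."""
        return center_effects(self.r_raw)

    @property
    def phi(self) -> np.ndarray:
        """Overall expected cover proportion per grid step, logit^-1(theta)."""
        return expit(self.theta)


def center_effects(r_raw: np.ndarray) -> np.ndarray:
    """Subtract the per-occasion (row) mean so effects sum to zero per row."""
    r_raw = np.asarray(r_raw, dtype=float)
    return r_raw - r_raw.mean(axis=1, keepdims=True)


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(stats.halfnorm.logpdf(x, scale=scale))


def log_prior(params: ModelParams) -> float:
    """Log prior: theta_1, theta_2, first-quadrat effects, sigmas, delta.

    Support violations (sigma <= 0, delta outside (0,1)) return ``-inf``;
    structural problems raise.  delta carries a Uniform(0,1) prior and so
    contributes zero on its support.
    """
    if not (np.isfinite(params.sigma_T) and np.isfinite(params.sigma_R)):
        return -np.inf
    if params.sigma_T <= 0 or params.sigma_R <= 0:
        return -np.inf
    if not (0.0 < params.delta < 1.0):
        return -np.inf
    lp = float(stats.norm.logpdf(params.theta[:2], scale=PRIOR_SCALE).sum())
    lp += float(stats.norm.logpdf(params.r_raw[:, 0], scale=PRIOR_SCALE).sum())
    lp += _halfnormal_logpdf(params.sigma_T, PRIOR_SCALE)
    lp += _halfnormal_logpdf(params.sigma_R, PRIOR_SCALE)
    return lp


def log_temporal(theta: np.ndarray, sigma_T: float) -> float:
    """Second-order random-walk log density over the full grid.

    ``sum_{t>=3} log Normal(theta_t | 2 theta_{t-1} - theta_{t-2}, sigma_T^2)``.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size < 3:
        raise ValueError("theta must have length >= 3")
    if sigma_T <= 0:
        return -np.inf
    second_diff = theta[2:] - 2.0 * theta[1:-1] + theta[:-2]
    return float(stats.norm.logpdf(second_diff, scale=sigma_T).sum())


def log_spatial(r_raw: np.ndarray, sigma_R: float) -> float:
    """First-order random-walk log density over quadrats, per occasion.

    Occasions are a priori independent; a single quadrat contributes an
    empty sum.
    """
    r_raw = np.asarray(r_raw, dtype=float)
    if r_raw.ndim != 2:
        raise ValueError("r_raw must be 2-D (occasion, quadrat)")
    if sigma_R <= 0:
        return -np.inf
    if r_raw.shape[1] < 2:
        return 0.0
    inc = np.diff(r_raw, axis=1)
    return float(stats.norm.logpdf(inc, scale=sigma_R).sum())


def cell_means(panel: CoverPanel, params: ModelParams) -> np.ndarray:
    """Mean cover proportion mu_{t,q} for every panel cell (observed or not)."""
    theta_obs = params.theta[panel.occasions]
    return _clip_unit(expit(theta_obs[:, None] + params.r))


def log_likelihood(panel: CoverPanel, params: ModelParams) -> float:
    """Ordinal-beta log likelihood summed over non-missing cells."""
    if params.theta.size <= int(panel.occasions.max()):
        raise ValueError("theta does not cover all observed occasions")
    if params.r_raw.shape != panel.classes.shape:
        raise ValueError("r_raw must match the panel's (occasion, quadrat) shape")
    if not (0.0 < params.delta < 1.0):
        return -np.inf
    obs = panel.observed_mask
    if not obs.any():
        return 0.0
    mu = cell_means(panel, params)[obs]
    y = panel.classes[obs]
    delta = _clip_unit(params.delta)
    probs = class_probabilities(mu, np.full_like(mu, delta), panel.cuts)
    p_cell = probs[np.arange(y.size), y - 1]
    return float(np.sum(np.log(np.maximum(p_cell, 1e-300))))


def log_joint(panel: CoverPanel, params: ModelParams) -> float:
    """Unnormalised posterior log density: prior + system + spatial + likelihood."""
    lp = log_prior(params)
    if not np.isfinite(lp):
        return -np.inf
    lt = log_temporal(params.theta, params.sigma_T)
    ls = log_spatial(params.r_raw, params.sigma_R)
    ll = log_likelihood(panel, params)
    return lp + lt + ls + ll
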