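"""Synthetic cover-class panels with known latent truth.

Two generating variants are provided:

* ``"paper"`` (default): the latent trend is a *first-order* random walk
  with drift on the logit scale, and the spatial quadrat effects are a
  single time-invariant random walk along the quadrat line.  This is a
  deliberately misspecified benchmark for the fitted model (which assumes
  second-order temporal differences and per-occasion spatial effects), and
  is the scenario used for the headline recovery study: 10 quadrats, 15
  occasions, theta_1 = -6, drift 0.3, innovation sd 0.5, spatial RW sd 0.5,
  delta = 0.05.
* ``"model"``: the generating process matches the fitted model exactly
  (second-order temporal differences, fresh spatial random walk per
  occasion).  Parameter-recovery tests use this variant.

Class labels are produced by drawing a beta cover proportion per cell and
binning it at the cut points; this is distributionally identical to drawing
a categorical label from the ordinal-beta class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

from .beta_ordinal import CutPoints, classify_proportion, mu_delta_to_shapes, _clip_unit
from .model import MISSING, CoverPanel, TimeGrid

__all__ = ["SimConfig", "SimOutput", "simulate_latent", "simulate_classes", "simulate", "make_real_like"]


@dataclass(frozen=True)
class SimConfig:
    """Generating conditions for a synthetic panel.

    Defaults are the benchmark scenario described in the module docstring.
    """

    n_quadrats: int = 10
    n_occasions: int = 15
    theta1: float = -6.0
    drift: float = 0.3
    sigma_theta: float = 0.5
    sigma_r: float = 0.5
    delta: float = 0.05
    cuts: CutPoints = field(default_factory=CutPoints.default)
    seed: int = 0
    variant: Literal["paper", "model"] = "paper"

    def __post_init__(self) -> None:
        if self.n_quadrats < 1:
            raise ValueError("n_quadrats must be >= 1")
        if self.n_occasions < 2:
            raise ValueError("n_occasions must be >= 2")
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie in (0, 1)")
        if self.sigma_theta < 0 or self.sigma_r < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.variant not in ("paper", "model"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class SimOutput:
    """A synthetic panel together with the latent truth that generated it."""

    panel: CoverPanel
    grid: TimeGrid
    true_theta: np.ndarray
    true_r: np.ndarray       # (n_occasions, n_quadrats), centred as used
    true_p: np.ndarray       # realised beta draws per cell
    true_classes: np.ndarray
    config: SimConfig


def simulate_latent(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw the latent trend and spatial effects for one panel.

    Returns ``(theta, r)`` with ``theta`` of length ``n_occasions`` and ``r``
    of shape ``(n_occasions, n_quadrats)``.  Under the ``"paper"`` variant
    ``r`` is a single time-invariant random walk (``r_1 = 0``) broadcast
    over occasions; under ``"model"`` each occasion gets an independent walk
    and ``r`` is returned centred per occasion.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T, Q = config.n_occasions, config.n_quadrats

    if config.variant == "paper":
        steps = rng.normal(config.drift, config.sigma_theta, size=T - 1)
        theta = config.theta1 + np.concatenate([[0.0], np.cumsum(steps)])
        inc = rng.normal(0.0, config.sigma_r, size=Q - 1)
        r_row = np.concatenate([[0.0], np.cumsum(inc)])
        r = np.tile(r_row, (T, 1))
    else:
        theta = np.empty(T)
        theta[0] = config.theta1
        theta[1] = config.theta1 + config.drift  # drift seeds the initial slope
        for t in range(2, T):
            theta[t] = rng.normal(2.0 * theta[t - 1] - theta[t - 2], config.sigma_theta)
        r = np.empty((T, Q))
        r[:, 0] = 0.0
        if Q > 1:
            inc = rng.normal(0.0, config.sigma_r, size=(T, Q - 1))
            r[:, 1:] = np.cumsum(inc, axis=1)
        r = r - r.mean(axis=1, keepdims=True)
    return theta, r


def simulate_classes(
    theta: np.ndarray,
    r: np.ndarray,
    delta: float,
    cuts: CutPoints | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Draw class labels by sampling beta cover proportions and binning them.

    Returns ``(classes, p)``: the labels and the underlying proportions.
    """
    if cuts is None:
        cuts = CutPoints.default()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    mu = _clip_unit(expit(theta[:, None] + r))
    alpha, beta = mu_delta_to_shapes(mu, np.full_like(mu, _clip_unit(delta)))
    p = rng.beta(alpha, beta)
    classes = classify_proportion(p, cuts)
    return classes, p


def simulate(config: SimConfig) -> SimOutput:
    """Generate one fully observed synthetic panel under the configuration."""
    rng = np.random.default_rng(config.seed)
    theta, r = simulate_latent(config, rng)
    classes, p = simulate_classes(theta, r, config.delta, config.cuts, rng)
    grid = TimeGrid(
        tuple(range(1, config.n_occasions + 1)),
        tuple([True] * config.n_occasions),
    )
    panel = CoverPanel(classes=classes, occasions=np.arange(config.n_occasions), cuts=config.cuts)
    return SimOutput(
        panel=panel,
        grid=grid,
        true_theta=theta,
        true_r=r,
        true_p=p,
        true_classes=classes,
        config=config,
    )


def make_real_like(
    calendar: Sequence[int],
    n_quadrats: int = 20,
    config: SimConfig | None = None,
) -> SimOutput:
    """Generate a panel shaped like a long-term survey with unobserved years.

    ``calendar`` lists the surveyed years; the grid spans min..max year with
    whole unobserved years in between (e.g. 20 surveys on a 61-step annual
    grid).  The latent trend runs over every grid step; class labels are
    emitted only for surveyed years.
    """
    years = np.unique(np.asarray(calendar, dtype=np.int64))
    if years.size == 0:
        raise ValueError("calendar must contain at least one surveyed year")
    if config is None:
        config = SimConfig()
    grid = TimeGrid.from_observed_labels(years)
    full = replace(config, n_quadrats=n_quadrats, n_occasions=grid.n_steps)
    rng = np.random.default_rng(full.seed)
    theta, r = simulate_latent(full, rng)
    classes_full, p_full = simulate_classes(theta, r, full.delta, full.cuts, rng)

    obs_steps = grid.observed_steps
    panel = CoverPanel(
        classes=classes_full[obs_steps],
        occasions=obs_steps,
        cuts=full.cuts,
    )
    return SimOutput(
        panel=panel,
        grid=grid,
        true_theta=theta,
        true_r=r[obs_steps],
        true_p=p_full[obs_steps],
        true_classes=classes_full[obs_steps],
        config=full,
    )
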