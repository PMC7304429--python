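"""Posterior predictive checks: replicated panels and rootograms.

For every retained posterior draw a replicate dataset is simulated from the
observation model at that draw's parameters.  A rootogram then compares,
per survey occasion and cover class, the observed quadrat count with the
posterior-predictive expectation and a 90% predictive interval; plotting
uses a square-root count axis so that rare classes remain visible.
Intervals on counts come from the empirical (discrete) distribution of
replicate counts, which makes them conservative at tied integer values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beta_ordinal import class_probabilities, _clip_unit
from .inference import PosteriorDraws
from .model import CoverPanel
from scipy.special import expit

__all__ = ["Rootogram", "posterior_predict", "rootogram_at", "ppc_discrepancy_report"]


@dataclass(frozen=True)
class Rootogram:
    """Observed vs posterior-predictive class counts for one occasion."""

    occasion_label: int
    observed: np.ndarray   # (K,) observed counts
    expected: np.ndarray   # (K,) posterior-predictive mean counts
    lower: np.ndarray      # (K,) 5th percentile of replicate counts
    upper: np.ndarray      # (K,) 95th percentile

    def to_frame(self) -> pd.DataFrame:
        K = self.observed.size
        return pd.DataFrame({
            "occasion_label": self.occasion_label,
            "cover_class": np.arange(1, K + 1),
            "observed": self.observed,
            "expected": self.expected,
            "lower": self.lower,
            "upper": self.upper,
        })


def posterior_predict(
    draws: PosteriorDraws,
    panel: CoverPanel,
    seed: int | np.random.Generator = 0,
    n_replicates: int | None = None,
) -> np.ndarray:
    """Simulate replicated class labels, one panel per retained draw.

    Returns an integer array ``(n_replicates, n_occasions, n_quadrats)``
    with :data:`coverstate.model.MISSING` wherever the observed panel is
    missing.  By default every retained draw produces one replicate;
    ``n_replicates`` subsamples draws evenly for speed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C, D = draws.n_chains, draws.n_draws
    theta = draws.theta.reshape(C * D, -1)
    r = draws.r.reshape(C * D, *draws.r.shape[2:])
    delta = draws.delta.ravel()
    total = C * D
    if n_replicates is None or n_replicates >= total:
        idx = np.arange(total)
    else:
        idx = np.linspace(0, total - 1, n_replicates).astype(np.int64)

    obs = panel.observed_mask
    occ_row, quad = np.nonzero(obs)
    steps = np.asarray(panel.occasions)[occ_row]
    K = panel.cuts.K

    out = np.full((idx.size, panel.n_occasions, panel.n_quadrats), -1, dtype=np.int64)
    for k, i in enumerate(idx):
        mu = _clip_unit(expit(theta[i][steps] + r[i][occ_row, quad]))
        probs = class_probabilities(mu, np.full_like(mu, _clip_unit(delta[i])),
                                    panel.cuts)
        cum = np.cumsum(probs, axis=1)
        u = rng.uniform(size=mu.size)
        labels = np.sum(u[:, None] > cum, axis=1) + 1
        out[k, occ_row, quad] = np.clip(labels, 1, K)
    return out


def rootogram_at(replicates: np.ndarray, panel: CoverPanel, occasion: int) -> Rootogram:
    """Rootogram table for one observed occasion (panel row index).

    Observed and expected counts both sum to the number of non-missing
    quadrats at that occasion; interval bounds are the 5th/95th percentiles
    of the per-replicate counts (linear interpolation).
    """
    if not (0 <= occasion < panel.n_occasions):
        raise ValueError(f"occasion {occasion} outside panel rows 0..{panel.n_occasions - 1}")
    obs_mask = panel.observed_mask[occasion]
    if not obs_mask.any():
        raise ValueError(f"occasion {occasion} has no observations")
    K = panel.cuts.K
    y = panel.classes[occasion, obs_mask]
    observed = np.bincount(y, minlength=K + 1)[1:].astype(float)

    rep = replicates[:, occasion, :][:, obs_mask]
    counts = np.stack([np.bincount(row, minlength=K + 1)[1:] for row in rep]).astype(float)
    expected = counts.mean(axis=0)
    lower, upper = np.percentile(counts, [5.0, 95.0], axis=0, method="linear")

    # grid labels are calendar labels; panel rows map through occasions
    label = panel.occasions[occasion]
    return Rootogram(
        occasion_label=int(label),
        observed=observed,
        expected=expected,
        lower=lower,
        upper=upper,
    )


def ppc_discrepancy_report(rootograms: list[Rootogram]) -> pd.DataFrame:
    """Flag (occasion, class) cells whose observed count leaves the 90% interval."""
    rows = []
    for rg in rootograms:
        outside = (rg.observed < rg.lower) | (rg.observed > rg.upper)
        for k in np.flatnonzero(outside):
            rows.append({
                "occasion_label": rg.occasion_label,
                "cover_class": int(k + 1),
                "observed": float(rg.observed[k]),
                "lower": float(rg.lower[k]),
                "upper": float(rg.upper[k]),
            })
    return pd.DataFrame(rows, columns=["occasion_label", "cover_class",
                                       "observed", "lower", "upper"])


def plot_rootogram(rootogram: Rootogram, ax=None):
    """Render a rootogram on a square-root count axis (optional figure)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    K = rootogram.observed.size
    x = np.arange(1, K + 1)
    ax.bar(x, np.sqrt(rootogram.observed), color="0.8", label="observed")
    ax.fill_between(x, np.sqrt(rootogram.lower), np.sqrt(rootogram.upper),
                    alpha=0.4, color="C1", label="90% predictive interval")
    ax.plot(x, np.sqrt(rootogram.expected), "o-", color="C1", label="expected")
    ax.set_xlabel("cover class")
    ax.set_ylabel("sqrt(count)")
    ax.set_xticks(x)
    ax.legend()
    return ax
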