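"""A self-contained No-U-Turn sampler with warmup adaptation.

Multinomial NUTS over a user-supplied log density and gradient, with
Nesterov dual-averaging step-size adaptation and windowed diagonal
(metric) adaptation during warmup, following the scheme popularised by
Stan: an initial fast interval for step size only, a sequence of doubling
"slow" windows estimating the posterior variances, and a terminal fast
interval.  After warmup the step size and metric are frozen.

The sampler is generic (it only sees ``logp_and_grad``); model specifics
live in :mod:`coverstate._posterior`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "nuts_sample"]

_MAX_DELTA_H = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class NutsResult:
    draws: np.ndarray          # (n_draws, dim)
    step_size: float
    inv_metric: np.ndarray     # diagonal variance estimate
    accept_prob: np.ndarray    # mean Metropolis acceptance per draw
    tree_depth: np.ndarray
    n_divergent: int
    logp: np.ndarray           # log density at each retained draw


class _Tree:
    """State of one trajectory-doubling pass."""

    __slots__ = ("z_minus", "p_minus", "g_minus", "z_plus", "p_plus", "g_plus",
                 "z_prop", "logp_prop", "log_sum_w", "sum_accept", "n_leapfrog",
                 "divergent", "turning")


def _leapfrog(logp_grad, z, p, g, eps, metric):
    p1 = p + 0.5 * eps * g
    z1 = z + eps * metric * p1
    logp1, g1 = logp_grad(z1)
    p1 = p1 + 0.5 * eps * g1
    return z1, p1, g1, logp1


def _hamiltonian(logp, p, metric) -> float:
    return -logp + 0.5 * float(metric @ (p * p))


def _is_turning(z_minus, p_minus, z_plus, p_plus, metric) -> bool:
    dz = z_plus - z_minus
    return (dz @ (metric * p_minus)) < 0 or (dz @ (metric * p_plus)) < 0


def _build_tree(logp_grad, z, p, g, direction, depth, eps, metric, H0, rng) -> _Tree:
    tree = _Tree()
    if depth == 0:
        z1, p1, g1, logp1 = _leapfrog(logp_grad, z, p, g, direction * eps, metric)
        if np.isfinite(logp1):
            H1 = _hamiltonian(logp1, p1, metric)
        else:
            H1 = np.inf
        delta_H = H1 - H0
        tree.divergent = (not np.isfinite(delta_H)) or delta_H > _MAX_DELTA_H
        tree.turning = False
        tree.z_minus = tree.z_plus = tree.z_prop = z1
        tree.p_minus = tree.p_plus = p1
        tree.g_minus = tree.g_plus = g1
        tree.logp_prop = logp1
        tree.log_sum_w = -delta_H if np.isfinite(delta_H) else -np.inf
        tree.sum_accept = float(min(1.0, np.exp(-delta_H))) if np.isfinite(delta_H) else 0.0
        tree.n_leapfrog = 1
        return tree

    first = _build_tree(logp_grad, z, p, g, direction, depth - 1, eps, metric, H0, rng)
    if first.divergent or first.turning:
        return first
    if direction == 1:
        second = _build_tree(logp_grad, first.z_plus, first.p_plus, first.g_plus,
                             direction, depth - 1, eps, metric, H0, rng)
        first.z_plus, first.p_plus, first.g_plus = second.z_plus, second.p_plus, second.g_plus
    else:
        second = _build_tree(logp_grad, first.z_minus, first.p_minus, first.g_minus,
                             direction, depth - 1, eps, metric, H0, rng)
        first.z_minus, first.p_minus, first.g_minus = second.z_minus, second.p_minus, second.g_minus

    first.n_leapfrog += second.n_leapfrog
    first.sum_accept += second.sum_accept
    first.divergent = second.divergent
    first.turning = second.turning or _is_turning(first.z_minus, first.p_minus,
                                                  first.z_plus, first.p_plus, metric)
    if not (first.divergent or first.turning):
        total = np.logaddexp(first.log_sum_w, second.log_sum_w)
        if np.log(rng.uniform()) < second.log_sum_w - total:
            first.z_prop = second.z_prop
            first.logp_prop = second.logp_prop
        first.log_sum_w = total
    return first


def _find_reasonable_step(logp_grad, z, g, logp, metric, rng) -> float:
    """Double/halve until the one-step acceptance crosses 0.5."""
    eps = 0.1
    p = rng.normal(size=z.size) / np.sqrt(metric)
    H0 = _hamiltonian(logp, p, metric)
    _, p1, _, logp1 = _leapfrog(logp_grad, z, p, g, eps, metric)
    dH = H0 - (_hamiltonian(logp1, p1, metric) if np.isfinite(logp1) else np.inf)
    direction = 1 if dH > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, _, logp1 = _leapfrog(logp_grad, z, p, g, eps, metric)
        dH = H0 - (_hamiltonian(logp1, p1, metric) if np.isfinite(logp1) else np.inf)
        if (direction == 1 and dH <= np.log(0.5)) or (direction == -1 and dH >= np.log(0.5)):
            break
    return float(eps)


def _adaptation_schedule(n_warmup: int):
    """(init_fast, slow_window_starts, term_fast) a la Stan."""
    if n_warmup < 40:
        return n_warmup, [], 0
    init = max(1, int(round(0.15 * n_warmup)))
    term = max(1, int(round(0.10 * n_warmup)))
    slow_total = n_warmup - init - term
    windows = []
    start = init
    size = max(10, int(round(0.05 * n_warmup)))
    while slow_total > 0:
        if slow_total < 2 * size:
            size = slow_total
        windows.append((start, start + size))
        start += size
        slow_total -= size
        size *= 2
    return init, windows, term


def nuts_sample(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    z0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    *,
    max_depth: int = 10,
    target_accept: float = 0.8,
    adapt_metric: bool = True,
    metric0: np.ndarray | None = None,
) -> NutsResult:
    """Run one NUTS chain and return post-warmup draws."""
    z = np.asarray(z0, dtype=float).copy()
    dim = z.size
    # inverse mass = posterior variance estimate
    metric = np.ones(dim) if metric0 is None else np.asarray(metric0, float).copy()
    logp, g = logp_grad(z)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_reasonable_step(logp_grad, z, g, logp, metric, rng)
    # dual averaging state
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    init_fast, slow_windows, term_fast = _adaptation_schedule(n_warmup)
    window_ends = [end for _, end in slow_windows]
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    accepts = np.empty(n_draws)
    depths = np.empty(n_draws, dtype=np.int64)
    n_divergent = 0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        p = rng.normal(size=dim) / np.sqrt(metric)
        H0 = _hamiltonian(logp, p, metric)

        z_prop, logp_prop = z, logp
        z_minus = z_plus = z
        p_minus = p_plus = p
        g_minus = g_plus = g
        log_sum_w = 0.0
        sum_accept, n_leap = 0.0, 0
        divergent = False
        depth = 0
        while depth < max_depth:
            direction = 1 if rng.uniform() < 0.5 else -1
            if direction == 1:
                sub = _build_tree(logp_grad, z_plus, p_plus, g_plus,
                                  1, depth, eps, metric, H0, rng)
                if not (sub.divergent or sub.turning):
                    z_plus, p_plus, g_plus = sub.z_plus, sub.p_plus, sub.g_plus
            else:
                sub = _build_tree(logp_grad, z_minus, p_minus, g_minus,
                                  -1, depth, eps, metric, H0, rng)
                if not (sub.divergent or sub.turning):
                    z_minus, p_minus, g_minus = sub.z_minus, sub.p_minus, sub.g_minus
            sum_accept += sub.sum_accept
            n_leap += sub.n_leapfrog
            if sub.divergent:
                divergent = True
                break
            if sub.turning:
                break
            if np.log(rng.uniform()) < sub.log_sum_w - log_sum_w:
                z_prop, logp_prop = sub.z_prop, sub.logp_prop
            log_sum_w = np.logaddexp(log_sum_w, sub.log_sum_w)
            depth += 1
            if _is_turning(z_minus, p_minus, z_plus, p_plus, metric):
                break

        if not np.array_equal(z_prop, z):
            z = z_prop
            logp = logp_prop
            _, g = logp_grad(z)
        accept_stat = sum_accept / max(n_leap, 1)

        if warming:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))

            in_slow = any(s <= it < e for s, e in slow_windows)
            if adapt_metric and in_slow:
                welford_n += 1
                d = z - welford_mean
                welford_mean += d / welford_n
                welford_m2 += d * (z - welford_mean)
            if adapt_metric and (it + 1) in window_ends and welford_n > 1:
                var = welford_m2 / (welford_n - 1)
                # regularised towards unit scale as in Stan
                metric = (welford_n / (welford_n + 5.0)) * var \
                    + 1e-3 * (5.0 / (welford_n + 5.0))
                metric = np.maximum(metric, 1e-10)
                welford_n = 0
                welford_mean[:] = 0.0
                welford_m2[:] = 0.0
                eps = _find_reasonable_step(logp_grad, z, g, logp, metric, rng)
                mu_da = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            i = it - n_warmup
            draws[i] = z
            logps[i] = logp
            accepts[i] = accept_stat
            depths[i] = depth
            n_divergent += int(divergent)

    return NutsResult(
        draws=draws,
        step_size=eps,
        inv_metric=metric,
        accept_prob=accepts,
        tree_depth=depths,
        n_divergent=n_divergent,
        logp=logps,
    )
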