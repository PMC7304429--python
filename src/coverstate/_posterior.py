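"""Unconstrained parameterisation of the joint posterior for the sampler.

The sampler works on a real-valued vector ``z`` built from:

* the latent trend: by default ``theta_1 .. theta_T`` directly (centred
  coordinates: with a survey at most occasions the likelihood informs
  every ``theta_t`` individually, so centred coordinates are far better
  conditioned for gradient-based MCMC than second-difference innovations
  would be); for a panel with no observations the standardised
  second-difference innovations are used instead (non-centred), because
  without likelihood anchoring the centred coordinates cannot traverse
  the ``sigma_T`` scale funnel,
* standardised first-quadrat effects ``u`` (``r_raw[:, 0] = 2.5 * u``) and
  standardised spatial increments ``eta``
  (``r_raw[:, q] = r_raw[:, q-1] + sigma_R * eta``) per observed occasion —
  non-centred, because a single ordinal observation per cell leaves the
  spatial effects prior-dominated,
* ``logit(delta)``, ``log(sigma_T)``, ``log(sigma_R)``.

The log-Jacobian terms of the transforms are included, so the density over
``z`` is exactly the model's joint density re-expressed in free
coordinates; any parameterisation preserving that density is a valid
sampling space.

Gradients are assembled by hand (reverse-mode through the linear
recursions).  The only non-elementary derivative — that of the regularized
incomplete beta function with respect to its shape parameters — is taken
by forward differences of the cell log-probabilities, sharing the central
evaluation.  The O(h) truncation error only shapes the Hamiltonian
proposal; the accept/reject step uses the exact density, so the invariant
distribution is untouched.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import linalg, special
from scipy.special import expit

from . import _kernels
from .beta_ordinal import _clip_unit
from .model import PRIOR_SCALE, CoverPanel, ModelParams, TimeGrid, center_effects

_LOG_2PI = float(np.log(2.0 * np.pi))
_PSI_STEP = 1e-4   # FD step on the logit-scale linear predictor
_PROB_FLOOR = 1e-300


def _softplus(x):
    return np.logaddexp(0.0, x)


class UnconstrainedPosterior:
    """Evaluable log density and gradient of the model over free reals."""

    def __init__(self, panel: CoverPanel, grid: TimeGrid, theta_param: str = "auto"):
        if theta_param not in ("auto", "centered", "noncentered"):
            raise ValueError(f"unknown theta_param {theta_param!r}")
        steps = np.asarray(panel.occasions)
        if steps.max() >= grid.n_steps:
            raise ValueError("panel occasions fall outside the time grid")
        self.panel = panel
        self.grid = grid
        self.T = grid.n_steps
        self.n_occ = panel.n_occasions
        self.Q = panel.n_quadrats
        self.K = panel.cuts.K

        obs = panel.observed_mask
        self._occ_row, self._quad = np.nonzero(obs)
        self._step = steps[self._occ_row]
        self._flat_cell = self._occ_row * self.Q + self._quad
        y = panel.classes[obs]
        bounds = np.asarray(panel.cuts.boundaries)
        self._x_hi = bounds[y]
        self._x_lo = bounds[y - 1]
        self.n_cells = y.size
        # cut points at 0 or 1 have known CDF; only interior ones need betainc
        self._hi_int = np.flatnonzero(self._x_hi < 1.0)
        self._lo_int = np.flatnonzero(self._x_lo > 0.0)
        self._n_hi = self._hi_int.size
        self._cols = np.concatenate([self._hi_int, self._lo_int])
        self._x_int = np.concatenate([self._x_hi[self._hi_int], self._x_lo[self._lo_int]])

        if theta_param == "auto":
            theta_param = "centered" if self.n_cells > 0 else "noncentered"
        self.theta_param = theta_param

        # Grid steps with data ("anchored") vs steps only the trend prior
        # touches.  Anchored steps keep centred coordinates; for gap steps
        # theta is Gaussian given the anchored values, so they are sampled
        # as standardised conditional-bridge residuals w with
        # theta_gap = A theta_anchor + sigma_T R^-1 w — exact, and the
        # residuals decouple from the data entirely.
        self._anchor = np.unique(self._step) if self.n_cells else np.arange(0)
        self._gap = np.setdiff1d(np.arange(self.T), self._anchor)
        # A gap at either of the first two steps would couple the bridge to
        # the weakly informative initial-state priors; plain centred
        # coordinates are used there instead (rare in practice).
        self.theta_bridge = (
            self.theta_param == "centered" and self._gap.size > 0
            and 0 in self._anchor and 1 in self._anchor)
        if self.theta_bridge:
            D = np.zeros((self.T - 2, self.T))
            idx = np.arange(self.T - 2)
            D[idx, idx] = 1.0
            D[idx, idx + 1] = -2.0
            D[idx, idx + 2] = 1.0
            S = D.T @ D
            S_uu = S[np.ix_(self._gap, self._gap)]
            S_uo = S[np.ix_(self._gap, self._anchor)]
            self._bridge_R = linalg.cholesky(S_uu, lower=False)
            self._bridge_A = -linalg.cho_solve((self._bridge_R, False), S_uo)
            self._bridge_logdetR = float(np.sum(np.log(np.diag(self._bridge_R))))

        # z layout offsets (the theta block holds theta at anchored steps
        # plus bridge residuals, or theta_1, theta_2 plus standardised
        # innovations in the non-centred form)
        self._i_u = self.T
        self._i_eta = self._i_u + self.n_occ
        self._i_delta = self._i_eta + self.n_occ * (self.Q - 1)
        self.dim = self._i_delta + 3

    # ------------------------------------------------------------------ pack

    def unpack(self, z: np.ndarray):
        """Split ``z`` into named natural-scale blocks."""
        z = np.asarray(z, dtype=float)
        Q, n_occ = self.Q, self.n_occ
        sigma_T_early = math.exp(min(z[self._i_delta + 1], 700.0))
        if self.theta_param == "centered":
            if self.theta_bridge:
                theta = np.empty(self.T)
                theta[self._anchor] = z[self._anchor]
                theta[self._gap] = (
                    self._bridge_A @ z[self._anchor]
                    + sigma_T_early * linalg.solve_triangular(
                        self._bridge_R, z[self._gap], lower=False))
            else:
                theta = z[:self.T].copy()
        else:
            theta = np.empty(self.T)
            theta[0], theta[1] = z[0], z[1]
            for t in range(2, self.T):
                theta[t] = (2.0 * theta[t - 1] - theta[t - 2]
                            + sigma_T_early * z[t])
        u = z[self._i_u:self._i_eta]
        eta = z[self._i_eta:self._i_delta].reshape(n_occ, Q - 1)
        z_delta, z_sT, z_sR = z[self._i_delta], z[self._i_delta + 1], z[self._i_delta + 2]
        sigma_T = math.exp(min(z_sT, 700.0))
        sigma_R = math.exp(min(z_sR, 700.0))
        delta = float(expit(z_delta))

        r_raw = np.empty((n_occ, Q))
        r_raw[:, 0] = PRIOR_SCALE * u
        if Q > 1:
            r_raw[:, 1:] = r_raw[:, [0]] + sigma_R * np.cumsum(eta, axis=1)
        return theta, r_raw, delta, sigma_T, sigma_R, u, eta, z_delta, z_sT, z_sR

    def params(self, z: np.ndarray) -> ModelParams:
        theta, r_raw, delta, sigma_T, sigma_R, *_ = self.unpack(z)
        return ModelParams(theta=theta, r_raw=r_raw, delta=delta,
                           sigma_T=sigma_T, sigma_R=sigma_R)

    # ------------------------------------------------------------ likelihood

    def _cell_logprobs(self, psi_variants: np.ndarray, delta_variants: np.ndarray) -> np.ndarray:
        """log P(Y_cell) for stacked (variant, cell) linear predictors.

        Dispatches to the compiled kernel when available; the numpy route
        evaluates betainc only at interior cut points (boundaries at 0 and
        1 contribute exact CDF values 0 and 1).
        """
        if _kernels.HAVE_KERNEL:
            out = np.empty(psi_variants.shape)
            _kernels.cell_logprobs_kernel(
                np.ascontiguousarray(psi_variants),
                np.ascontiguousarray(delta_variants),
                self._x_hi, self._x_lo, out)
            return out
        V, n = psi_variants.shape
        mu = _clip_unit(expit(psi_variants[:, self._cols]))
        delta = _clip_unit(delta_variants)[:, None]
        phi = (1.0 - delta) / delta
        a = mu * phi
        b = (1.0 - mu) * phi
        cdf_int = special.betainc(a, b, np.broadcast_to(self._x_int, (V, self._cols.size)))
        cdf_hi = np.ones((V, n))
        cdf_hi[:, self._hi_int] = cdf_int[:, :self._n_hi]
        cdf_lo = np.zeros((V, n))
        cdf_lo[:, self._lo_int] = cdf_int[:, self._n_hi:]
        prob = np.clip(cdf_hi - cdf_lo, _PROB_FLOOR, 1.0)
        return np.log(prob)

    def _loglik(self, theta, r_centered, delta) -> float:
        if self.n_cells == 0:
            return 0.0
        psi = theta[self._step] + r_centered.ravel()[self._flat_cell]
        L = self._cell_logprobs(psi[None, :], np.array([delta]))
        return float(L[0].sum())

    def _loglik_grads(self, theta, r_centered, delta):
        """Likelihood value plus d/dpsi per cell and total d/ddelta."""
        if self.n_cells == 0:
            return 0.0, np.zeros(0), 0.0
        psi = theta[self._step] + r_centered.ravel()[self._flat_cell]
        h = _PSI_STEP
        hd = 1e-6 + 1e-4 * delta * (1.0 - delta)
        delta_hi = min(delta + hd, 1.0 - 1e-9)
        psis = np.empty((3, self.n_cells))
        psis[0] = psi
        psis[1] = psi + h
        psis[2] = psi
        deltas = np.array([delta, delta, delta_hi])
        L = self._cell_logprobs(psis, deltas)
        ll = float(L[0].sum())
        g_psi = (L[1] - L[0]) / h
        g_delta = float((L[2] - L[0]).sum()) / (delta_hi - delta)
        return ll, g_psi, g_delta

    # ----------------------------------------------------------------- logp

    def _logp_base(self, z, theta, u, eta, z_delta, z_sT, z_sR, sigma_T, sigma_R) -> float:
        """Everything except the likelihood, in z coordinates."""
        s2 = PRIOR_SCALE ** 2
        T = self.T
        lp = -0.5 * (theta[0] ** 2 + theta[1] ** 2) / s2 \
            - 2.0 * math.log(PRIOR_SCALE) - _LOG_2PI
        if sigma_T <= 0 or not math.isfinite(sigma_T):
            return -np.inf
        if self.theta_param == "centered":
            d2 = theta[2:] - 2.0 * theta[1:-1] + theta[:-2]
            lp += -0.5 * float(d2 @ d2) / sigma_T ** 2 \
                - (T - 2) * math.log(sigma_T) - 0.5 * (T - 2) * _LOG_2PI
            if self.theta_bridge:
                # Jacobian of theta_gap = A theta_anchor + sigma_T R^-1 w
                lp += self._gap.size * math.log(sigma_T) - self._bridge_logdetR
        else:
            eps = z[2:T]
            lp += -0.5 * float(eps @ eps) - 0.5 * (T - 2) * _LOG_2PI
        n_std = u.size + eta.size
        lp += -0.5 * (float(u @ u) + float((eta * eta).sum())) - 0.5 * n_std * _LOG_2PI
        # sigma = exp(z): HalfNormal(2.5) prior plus log-Jacobian z
        lp += math.log(2.0 / math.pi) - 2.0 * math.log(PRIOR_SCALE) \
            - 0.5 * (sigma_T ** 2 + sigma_R ** 2) / s2 + float(z_sT) + float(z_sR)
        # delta = expit(z): Uniform(0,1) prior plus log-Jacobian log(delta(1-delta))
        lp += -float(_softplus(z_delta)) - float(_softplus(-z_delta))
        return float(lp)

    def logp(self, z: np.ndarray) -> float:
        (theta, r_raw, delta, sigma_T, sigma_R,
         u, eta, z_delta, z_sT, z_sR) = self.unpack(z)
        z = np.asarray(z, dtype=float)
        lp = self._logp_base(z, theta, u, eta, z_delta, z_sT, z_sR, sigma_T, sigma_R)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self._loglik(theta, center_effects(r_raw), delta)

    def logp_grad(self, z: np.ndarray):
        (theta, r_raw, delta, sigma_T, sigma_R,
         u, eta, z_delta, z_sT, z_sR) = self.unpack(z)
        T, Q, n_occ = self.T, self.Q, self.n_occ
        s2 = PRIOR_SCALE ** 2

        z = np.asarray(z, dtype=float)
        lp = self._logp_base(z, theta, u, eta, z_delta, z_sT, z_sR, sigma_T, sigma_R)
        if not np.isfinite(lp):
            return -np.inf, np.zeros(self.dim)
        ll, g_psi, g_delta_lik = self._loglik_grads(theta, center_effects(r_raw), delta)
        lp += ll

        # accumulate likelihood gradient onto theta and r_raw
        if self.n_cells:
            g_theta = np.bincount(self._step, weights=g_psi, minlength=T)
            g_rc = np.bincount(self._flat_cell, weights=g_psi,
                               minlength=n_occ * Q).reshape(n_occ, Q)
        else:
            g_theta = np.zeros(T)
            g_rc = np.zeros((n_occ, Q))
        g_rraw = g_rc - g_rc.mean(axis=1, keepdims=True)  # centering projection

        g_theta[0] += -theta[0] / s2
        g_theta[1] += -theta[1] / s2
        if self.theta_param == "centered":
            # temporal smoothing: adjoint of the second-difference quadratic
            d2 = theta[2:] - 2.0 * theta[1:-1] + theta[:-2]
            e = d2 / sigma_T ** 2
            g_theta[2:] -= e
            g_theta[1:-1] += 2.0 * e
            g_theta[:-2] -= e
            g_z_sT = float(d2 @ d2) / sigma_T ** 2 - (T - 2) - sigma_T ** 2 / s2 + 1.0
            if self.theta_bridge:
                # chain through theta_gap = A theta_anchor + sigma_T R^-1 w
                g_gap = g_theta[self._gap]
                g_theta_block = np.empty(T)
                g_theta_block[self._anchor] = (g_theta[self._anchor]
                                               + self._bridge_A.T @ g_gap)
                g_theta_block[self._gap] = sigma_T * linalg.solve_triangular(
                    self._bridge_R, g_gap, lower=False, trans="T")
                x = linalg.solve_triangular(self._bridge_R, z[self._gap], lower=False)
                g_z_sT += sigma_T * float(g_gap @ x) + self._gap.size
            else:
                g_theta_block = g_theta
        else:
            # reverse pass through theta_t = 2 theta_{t-1} - theta_{t-2} + sigma_T eps_t
            eps = z[2:T]
            adj = g_theta.copy()
            g_theta_block = np.empty(T)
            g_sigma_T = 0.0
            for t in range(T - 1, 1, -1):
                g_theta_block[t] = sigma_T * adj[t] - eps[t - 2]
                g_sigma_T += eps[t - 2] * adj[t]
                adj[t - 1] += 2.0 * adj[t]
                adj[t - 2] -= adj[t]
            g_theta_block[0], g_theta_block[1] = adj[0], adj[1]
            g_z_sT = sigma_T * (g_sigma_T - sigma_T / s2) + 1.0

        # reverse pass through the spatial random walk (suffix sums per row)
        suffix = np.cumsum(g_rraw[:, ::-1], axis=1)[:, ::-1]
        g_u = PRIOR_SCALE * suffix[:, 0] - u
        if Q > 1:
            g_eta = sigma_R * suffix[:, 1:] - eta
            g_sigma_R = float((eta * suffix[:, 1:]).sum())
        else:
            g_eta = np.zeros((n_occ, 0))
            g_sigma_R = 0.0

        g_z_sR = sigma_R * (g_sigma_R - sigma_R / s2) + 1.0
        g_z_delta = delta * (1.0 - delta) * g_delta_lik + (1.0 - 2.0 * delta)

        grad = np.empty(self.dim)
        grad[:T] = g_theta_block
        grad[self._i_u:self._i_eta] = g_u
        grad[self._i_eta:self._i_delta] = g_eta.ravel()
        grad[self._i_delta] = g_z_delta
        grad[self._i_delta + 1] = g_z_sT
        grad[self._i_delta + 2] = g_z_sR
        return float(lp), grad

    # ----------------------------------------------------------------- init

    def initial_z(self, rng: np.random.Generator, jitter: float = 0.1) -> np.ndarray:
        """Data-informed starting point with per-chain jitter.

        theta starts at the logit of per-occasion mean class midpoints,
        linearly interpolated over unobserved grid steps; scales start near
        0.5 and delta near 0.1.
        """
        z = np.empty(self.dim)
        if self.n_cells > 0:
            mids = 0.5 * (self._x_hi + self._x_lo)
            occ_mean = np.full(self.n_occ, np.nan)
            for i in range(self.n_occ):
                sel = self._occ_row == i
                if sel.any():
                    occ_mean[i] = mids[sel].mean()
            has = ~np.isnan(occ_mean)
            steps_obs = np.asarray(self.panel.occasions)[has]
            vals = special.logit(np.clip(occ_mean[has], 5e-3, 1.0 - 5e-3))
            theta0 = np.interp(np.arange(self.T), steps_obs, vals)
        else:
            theta0 = np.zeros(self.T)
        theta0 = theta0 + jitter * rng.normal(size=self.T)
        sigma0 = 0.5 * float(np.exp(jitter * rng.normal()))
        if self.theta_param == "centered":
            z[:self.T] = theta0
            if self.theta_bridge:
                z[self._gap] = 0.2 * rng.normal(size=self._gap.size)
        else:
            z[0], z[1] = theta0[0], theta0[1]
            z[2:self.T] = (theta0[2:] - 2.0 * theta0[1:-1] + theta0[:-2]) / sigma0
        z[self._i_u:self._i_eta] = jitter * rng.normal(size=self.n_occ)
        z[self._i_eta:self._i_delta] = jitter * rng.normal(size=self.n_occ * (self.Q - 1))
        z[self._i_delta] = special.logit(0.1) + jitter * rng.normal()
        z[self._i_delta + 1] = np.log(sigma0)
        z[self._i_delta + 2] = np.log(0.5) + jitter * rng.normal()
        return z

    def initial_metric(self) -> np.ndarray:
        """Rough diagonal scale guess used before the first adaptation window."""
        m = np.ones(self.dim)
        if self.theta_param == "centered":
            m[:self.T] = 0.25      # theta posterior sd is typically a few tenths
            if self.theta_bridge:
                m[self._gap] = 1.0  # bridge residuals are a priori standard normal
            m[self._i_delta:] = 0.25
        else:
            m[0] = m[1] = PRIOR_SCALE ** 2
            m[self._i_delta] = 3.3     # logit of a uniform variate
            m[self._i_delta + 1] = 1.2  # log of a half-normal variate
            m[self._i_delta + 2] = 1.2
        return m
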