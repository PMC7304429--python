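"""Tests of the sampling machinery: the unconstrained posterior transform,
the NUTS kernel, convergence diagnostics and posterior summaries."""

import numpy as np
import pytest
from scipy.special import expit

import arviz as az

from coverstate import _kernels
from coverstate._posterior import UnconstrainedPosterior
from coverstate.inference import (
    DrawsTable,
    SamplerConfig,
    compute_rhat,
    overall_cover_curve,
    sample_posterior,
    summarize,
)
from coverstate.model import MISSING, CoverPanel, TimeGrid, log_joint
from coverstate.nuts import nuts_sample
from coverstate.simulator import SimConfig, simulate


class TestUnconstrainedPosterior:
    def test_density_matches_log_joint_plus_jacobian(self, tiny_sim):
        """The z-space density is the model joint plus the exact
        change-of-variables terms of the non-centred/r and log/logit maps."""
        post = UnconstrainedPosterior(tiny_sim.panel, tiny_sim.grid)
        rng = np.random.default_rng(2)
        for _ in range(5):
            z = post.initial_z(rng, jitter=0.4)
            p = post.params(z)
            corr = (post.n_occ * (post.Q - 1) * np.log(p.sigma_R)   # spatial increments
                    + post.n_occ * np.log(2.5)                      # first-quadrat scale
                    + np.log(p.sigma_T) + np.log(p.sigma_R)         # log-sigma Jacobians
                    + np.log(p.delta * (1 - p.delta)))              # logit-delta Jacobian
            assert post.logp(z) == pytest.approx(
                log_joint(tiny_sim.panel, p) + corr, rel=1e-10)

    def test_gradient_matches_finite_differences(self, tiny_sim):
        post = UnconstrainedPosterior(tiny_sim.panel, tiny_sim.grid)
        rng = np.random.default_rng(4)
        z = post.initial_z(rng, jitter=0.3)
        lp, g = post.logp_grad(z)
        assert np.isfinite(lp) and np.all(np.isfinite(g))
        h = 1e-5
        for i in range(post.dim):
            zp, zm = z.copy(), z.copy()
            zp[i] += h
            zm[i] -= h
            fd = (post.logp(zp) - post.logp(zm)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=2e-3, abs=2e-3)

    def test_kernel_and_numpy_paths_agree(self, tiny_sim, monkeypatch):
        post = UnconstrainedPosterior(tiny_sim.panel, tiny_sim.grid)
        rng = np.random.default_rng(6)
        psi = rng.normal(-1, 2, size=(3, post.n_cells))
        deltas = np.array([0.2, 0.05, 0.7])
        with_kernel = post._cell_logprobs(psi, deltas)
        monkeypatch.setattr(_kernels, "HAVE_KERNEL", False)
        without = post._cell_logprobs(psi, deltas)
        np.testing.assert_allclose(with_kernel, without, rtol=1e-12, atol=1e-12)

    def test_empty_panel_reduces_to_prior_density(self):
        grid = TimeGrid((1, 2, 3, 4), (True,) * 4)
        panel = CoverPanel(classes=np.full((4, 3), MISSING),
                           occasions=np.arange(4))
        post = UnconstrainedPosterior(panel, grid)
        z = post.initial_z(np.random.default_rng(0))
        assert np.isfinite(post.logp(z))
        lp, g = post.logp_grad(z)
        assert np.all(np.isfinite(g))


class TestNuts:
    def test_recovers_standard_normal(self):
        rng = np.random.default_rng(8)

        def logp_grad(z):
            return -0.5 * float(z @ z), -z

        res = nuts_sample(logp_grad, np.zeros(5), 300, 1500, rng)
        assert abs(res.draws.mean()) < 0.1
        assert abs(res.draws.std() - 1.0) < 0.1
        assert res.n_divergent == 0

    def test_seeded_determinism(self):
        def logp_grad(z):
            return -0.5 * float(z @ z), -z

        a = nuts_sample(logp_grad, np.zeros(3), 100, 100, np.random.default_rng(1))
        b = nuts_sample(logp_grad, np.zeros(3), 100, 100, np.random.default_rng(1))
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_rejects_non_finite_start(self):
        def logp_grad(z):
            return -np.inf, z

        with pytest.raises(ValueError):
            nuts_sample(logp_grad, np.zeros(2), 10, 10, np.random.default_rng(0))


class TestRhat:
    def test_well_mixed_chains(self):
        rng = np.random.default_rng(0)
        table = DrawsTable({"x": rng.normal(size=(2, 1000))})
        assert compute_rhat(table, "x") < 1.05

    def test_disjoint_chains(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 1000)) + np.array([[0.0], [10.0]])
        assert compute_rhat(DrawsTable({"x": x}), "x") > 1.1

    def test_matches_arviz_split_variant(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(4, 500)) * np.array([[1.0], [1.3], [0.8], [1.1]])
        mine = compute_rhat(DrawsTable({"x": x}), "x")
        reference = float(az.rhat(x, method="split"))
        assert mine == pytest.approx(reference, abs=1e-6)

    def test_needs_multiple_chains(self):
        with pytest.raises(ValueError):
            compute_rhat(DrawsTable({"x": np.zeros((1, 100))}), "x")


class TestSummarize:
    def test_constant_draws(self):
        table = DrawsTable({"c": np.full((2, 50), 3.25)})
        row = summarize(table, ["c"]).iloc[0]
        assert row["mean"] == row["p2.5"] == row["p50"] == row["p97.5"] == 3.25
        assert row["rhat"] == 1.0

    def test_order_statistics_oracle(self):
        # pooled draws hold exactly 1..100: linear-interpolation percentiles
        x = np.arange(1.0, 101.0).reshape(2, 50)
        row = summarize(DrawsTable({"x": x}), ["x"]).iloc[0]
        assert row["p50"] == pytest.approx(50.5)
        assert row["p2.5"] == pytest.approx(3.475)
        assert row["p97.5"] == pytest.approx(97.525)

    def test_percentile_monotonicity(self):
        rng = np.random.default_rng(5)
        table = DrawsTable({"x": rng.exponential(size=(3, 400))})
        row = summarize(table, ["x"]).iloc[0]
        assert row["p2.5"] <= row["p50"] <= row["p97.5"]
        assert row["p2.5"] <= row["mean"] <= row["p97.5"]

    def test_unknown_parameter_errors(self, tiny_fit):
        _, draws = tiny_fit
        with pytest.raises(KeyError):
            summarize(draws, ["nonexistent"])


class TestPosteriorDraws:
    def test_named_access_and_derived_quantities(self, tiny_fit):
        _, draws = tiny_fit
        np.testing.assert_allclose(draws.get("theta[1]"), draws.theta[:, :, 0])
        np.testing.assert_allclose(draws.get("phi[2]"), expit(draws.theta[:, :, 1]))
        np.testing.assert_allclose(draws.r.sum(axis=3), 0.0, atol=1e-10)
        assert draws.get("delta").shape == (2, 300)
        with pytest.raises(KeyError):
            draws.get("theta[999]")
        with pytest.raises(KeyError):
            draws.get("r[1]")

    def test_delta_and_sigmas_respect_support(self, tiny_fit):
        _, draws = tiny_fit
        assert np.all((draws.delta > 0) & (draws.delta < 1))
        assert np.all(draws.sigma_T > 0)
        assert np.all(draws.sigma_R > 0)


class TestOverallCoverCurve:
    def test_degenerate_draws(self, tiny_fit):
        sim, draws = tiny_fit
        import dataclasses
        flat = dataclasses.replace(draws, theta=np.zeros_like(draws.theta))
        curve = overall_cover_curve(flat)
        np.testing.assert_allclose(curve["median"], 0.5)
        np.testing.assert_allclose(curve["upper"] - curve["lower"], 0.0, atol=1e-12)

    def test_matches_brute_force_quantiles(self, tiny_fit):
        _, draws = tiny_fit
        curve = overall_cover_curve(draws)
        phi = expit(draws.theta.reshape(-1, draws.theta.shape[2]))
        np.testing.assert_allclose(curve["median"], np.percentile(phi, 50, axis=0))
        np.testing.assert_allclose(curve["lower"], np.percentile(phi, 2.5, axis=0))

    def test_transform_then_quantile_commutes(self, tiny_fit):
        # logit^-1 is monotone, so quantiles commute with the transform up
        # to the linear interpolation between adjacent order statistics
        _, draws = tiny_fit
        curve = overall_cover_curve(draws)
        theta_med = np.percentile(draws.theta.reshape(-1, draws.theta.shape[2]), 50, axis=0)
        np.testing.assert_allclose(curve["median"], expit(theta_med), atol=1e-5)


class TestSamplePosterior:
    def test_reproducible_with_fixed_seed(self, tiny_sim):
        cfg = SamplerConfig(chains=2, warmup=100, draws=100, seed=3)
        a = sample_posterior(tiny_sim.panel, tiny_sim.grid, cfg)
        b = sample_posterior(tiny_sim.panel, tiny_sim.grid, cfg)
        np.testing.assert_array_equal(a.delta, b.delta)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_convergence_reported_in_diagnostics(self, tiny_fit):
        _, draws = tiny_fit
        assert "max_rhat" in draws.diagnostics
        assert isinstance(draws.diagnostics["converged"], bool)
        assert draws.diagnostics["seed"] == 5

    def test_single_class_panel_concentrates_cover_estimate(self):
        # every quadrat in class 3 at every occasion: phi should sit near
        # the class-3 interval (0.1, 0.25]
        grid = TimeGrid(tuple(range(5)), (True,) * 5)
        panel = CoverPanel(classes=np.full((5, 6), 3), occasions=np.arange(5))
        draws = sample_posterior(panel, grid,
                                 SamplerConfig(chains=2, warmup=300, draws=300, seed=21))
        med = np.median(expit(draws.theta), axis=(0, 1))
        assert np.all(med > 0.08) and np.all(med < 0.30)

    def test_chain_count_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(chains=1)

    def test_empty_panel_recovers_prior(self):
        """With no observations the posterior is the prior: delta uniform,
        sigmas half-normal(2.5)."""
        grid = TimeGrid((1, 2, 3, 4), (True,) * 4)
        panel = CoverPanel(classes=np.full((4, 3), MISSING), occasions=np.arange(4))
        draws = sample_posterior(panel, grid,
                                 SamplerConfig(chains=2, warmup=500, draws=1500, seed=13))
        halfnorm_mean = 2.5 * np.sqrt(2 / np.pi)
        assert draws.delta.mean() == pytest.approx(0.5, abs=0.05)
        assert draws.sigma_T.mean() == pytest.approx(halfnorm_mean, abs=0.25)
        assert draws.sigma_R.mean() == pytest.approx(halfnorm_mean, abs=0.25)
        assert draws.delta.std() == pytest.approx(np.sqrt(1 / 12), abs=0.05)


class TestParameterRecovery:
    def test_credible_intervals_cover_generating_values(self):
        """Fitting the model-matched generator at the benchmark scale, the
        95% intervals for delta, sigma_R, sigma_T cover the truth in at
        least 8 of 10 replicates."""
        truth = dict(delta=0.05, sigma_R=0.5, sigma_T=0.5)
        covered = {k: 0 for k in truth}
        for seed in range(10):
            out = simulate(SimConfig(seed=100 + seed, variant="model",
                                     sigma_theta=0.5, sigma_r=0.5, delta=0.05))
            draws = sample_posterior(out.panel, out.grid,
                                     SamplerConfig(chains=2, warmup=300, draws=300,
                                                   seed=seed))
            s = summarize(draws).set_index("parameter")
            for k, v in truth.items():
                if s.loc[k, "p2.5"] <= v <= s.loc[k, "p97.5"]:
                    covered[k] += 1
        for k, n in covered.items():
            assert n >= 8, f"{k}: only {n}/10 intervals covered the truth"
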