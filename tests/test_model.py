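"""Tests of the joint model: priors, temporal and spatial random-walk
densities, sum-to-zero centering and the ordinal-beta likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coverstate.beta_ordinal import CutPoints, mu_delta_to_shapes
from coverstate.model import (
    MISSING,
    CoverPanel,
    ModelParams,
    TimeGrid,
    center_effects,
    log_joint,
    log_likelihood,
    log_prior,
    log_spatial,
    log_temporal,
)
from scipy.special import expit


def make_params(theta, r_raw, delta=0.1, sigma_T=0.5, sigma_R=0.5):
    return ModelParams(theta=np.asarray(theta, float), r_raw=np.asarray(r_raw, float),
                       delta=delta, sigma_T=sigma_T, sigma_R=sigma_R)


@pytest.fixture
def toy_panel():
    classes = np.array([[1, 2, 3], [2, 2, 4], [3, MISSING, 5]])
    return CoverPanel(classes=classes, occasions=np.array([0, 1, 2]))


def cell_oracle(theta_t, r_tq, delta, y, cuts=None):
    """Independent per-cell log probability via the scipy beta CDF."""
    cuts = cuts or CutPoints.default()
    mu = expit(theta_t + r_tq)
    a, b = mu_delta_to_shapes(mu, delta)
    lo, hi = cuts.boundaries[y - 1], cuts.boundaries[y]
    return float(np.log(stats.beta.cdf(hi, a, b) - stats.beta.cdf(lo, a, b)))


class TestTimeGrid:
    def test_from_observed_labels_spans_range(self):
        grid = TimeGrid.from_observed_labels([1957, 1960, 1965])
        assert grid.n_steps == 9
        assert grid.labels[0] == 1957 and grid.labels[-1] == 1965
        np.testing.assert_array_equal(grid.observed_steps, [0, 3, 8])
        assert grid.step_of(1960) == 3
        with pytest.raises(KeyError):
            grid.step_of(1900)

    def test_rejects_non_consecutive_labels(self):
        with pytest.raises(ValueError):
            TimeGrid((1, 2, 4), (True, True, True))
        with pytest.raises(ValueError):
            TimeGrid((1, 2), (True, True))


class TestCoverPanel:
    def test_rejects_bad_labels(self):
        with pytest.raises(ValueError, match="class labels"):
            CoverPanel(classes=np.array([[7, 1]]), occasions=np.array([0]))
        with pytest.raises(ValueError, match="class labels"):
            CoverPanel(classes=np.array([[0, 1]]), occasions=np.array([0]))

    def test_counts_missing(self, toy_panel):
        assert toy_panel.n_observed == 8
        assert toy_panel.observed_mask.sum() == 8


class TestPrior:
    def test_mode_contribution_of_initial_states(self):
        # theta_1 = theta_2 = 0 contribute twice the normal density at its mode
        p0 = make_params([0.0, 0.0, 0.0], np.zeros((1, 2)))
        p1 = make_params([1.3, -0.7, 0.0], np.zeros((1, 2)))
        expected_diff = (2 * stats.norm.logpdf(0, scale=2.5)
                         - stats.norm.logpdf(1.3, scale=2.5)
                         - stats.norm.logpdf(-0.7, scale=2.5))
        assert log_prior(p0) - log_prior(p1) == pytest.approx(expected_diff)

    def test_support_violations_rejected_not_raised(self):
        base = dict(theta=np.zeros(3), r_raw=np.zeros((1, 2)))
        assert log_prior(ModelParams(**base, delta=0.1, sigma_T=-1.0, sigma_R=0.5)) == -np.inf
        assert log_prior(ModelParams(**base, delta=0.1, sigma_T=0.5, sigma_R=0.0)) == -np.inf
        assert log_prior(ModelParams(**base, delta=1.5, sigma_T=0.5, sigma_R=0.5)) == -np.inf

    def test_matches_textbook_density_sum(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(size=5)
        r_raw = rng.normal(size=(3, 4))
        p = make_params(theta, r_raw, delta=0.3, sigma_T=0.7, sigma_R=1.2)
        expected = (stats.norm.logpdf(theta[:2], scale=2.5).sum()
                    + stats.norm.logpdf(r_raw[:, 0], scale=2.5).sum()
                    + stats.halfnorm.logpdf(0.7, scale=2.5)
                    + stats.halfnorm.logpdf(1.2, scale=2.5))
        assert log_prior(p) == pytest.approx(expected, rel=1e-12)


class TestTemporal:
    def test_standard_normal_at_zero(self):
        assert log_temporal(np.zeros(3), 1.0) == pytest.approx(stats.norm.logpdf(0.0))

    def test_linear_sequence_is_maximal(self):
        t = np.arange(8, dtype=float)
        theta = -3.0 + 0.4 * t
        best = log_temporal(theta, 0.5)
        assert best == pytest.approx(6 * stats.norm.logpdf(0.0, scale=0.5))
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert log_temporal(theta + rng.normal(0, 0.3, 8), 0.5) < best

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(7)
        theta = rng.normal(size=10)
        expected = sum(
            stats.norm.logpdf(theta[t], loc=2 * theta[t - 1] - theta[t - 2], scale=0.8)
            for t in range(2, 10))
        assert log_temporal(theta, 0.8) == pytest.approx(expected, rel=1e-12)

    def test_short_series_and_bad_sigma(self):
        with pytest.raises(ValueError):
            log_temporal(np.zeros(2), 1.0)
        assert log_temporal(np.zeros(5), 0.0) == -np.inf


class TestSpatial:
    def test_constant_row(self):
        r = np.full((2, 5), 3.7)
        assert log_spatial(r, 0.6) == pytest.approx(8 * stats.norm.logpdf(0.0, scale=0.6))

    def test_single_quadrat_contributes_nothing(self):
        assert log_spatial(np.ones((4, 1)), 0.6) == 0.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(11)
        r = rng.normal(size=(3, 5))
        expected = sum(
            stats.norm.logpdf(r[i, q] - r[i, q - 1], scale=0.4)
            for i in range(3) for q in range(1, 5))
        assert log_spatial(r, 0.4) == pytest.approx(expected, rel=1e-12)


class TestCentering:
    def test_simple_row(self):
        np.testing.assert_allclose(center_effects(np.array([[1.0, 2.0, 3.0]])),
                                   [[-1.0, 0.0, 1.0]])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=8),
           st.floats(-10, 10))
    def test_idempotent_and_shift_invariant(self, row, shift):
        r = np.asarray([row])
        c = center_effects(r)
        np.testing.assert_allclose(c.sum(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(center_effects(c), c, atol=1e-12)
        np.testing.assert_allclose(center_effects(r + shift), c, atol=1e-9)


class TestLikelihood:
    def test_fully_missing_panel_contributes_zero(self):
        panel = CoverPanel(classes=np.full((2, 3), MISSING), occasions=np.array([0, 1]))
        p = make_params(np.zeros(3), np.zeros((2, 3)))
        assert log_likelihood(panel, p) == 0.0

    def test_single_cell_near_certainty(self):
        # mu deep inside class 4 (0.25, 0.5] with tiny dispersion
        panel = CoverPanel(classes=np.array([[4]]), occasions=np.array([0]))
        p = make_params([np.log(0.35 / 0.65)] * 3, np.zeros((1, 1)), delta=1e-5)
        assert log_likelihood(panel, p) == pytest.approx(0.0, abs=1e-6)

    def test_matches_cell_by_cell_oracle(self, toy_panel):
        rng = np.random.default_rng(5)
        theta = rng.normal(-1, 1, size=3)
        r_raw = rng.normal(0, 0.5, size=(3, 3))
        p = make_params(theta, r_raw, delta=0.12)
        r = center_effects(r_raw)
        expected = sum(
            cell_oracle(theta[o], r[o, q], 0.12, int(toy_panel.classes[o, q]))
            for o in range(3) for q in range(3)
            if toy_panel.classes[o, q] != MISSING)
        assert log_likelihood(toy_panel, p) == pytest.approx(expected, rel=1e-9)

    def test_deleting_observation_removes_only_its_term(self, toy_panel):
        rng = np.random.default_rng(9)
        p = make_params(rng.normal(size=3), rng.normal(size=(3, 3)), delta=0.2)
        classes2 = toy_panel.classes.copy()
        classes2[1, 2] = MISSING
        panel2 = CoverPanel(classes=classes2, occasions=toy_panel.occasions)
        r = center_effects(p.r_raw)
        removed = cell_oracle(p.theta[1], r[1, 2], 0.2, int(toy_panel.classes[1, 2]))
        assert (log_likelihood(toy_panel, p) - log_likelihood(panel2, p)
                == pytest.approx(removed, rel=1e-9))

    def test_degenerate_dispersion_separates_classes(self):
        panel_match = CoverPanel(classes=np.array([[4]]), occasions=np.array([0]))
        panel_wrong = CoverPanel(classes=np.array([[2]]), occasions=np.array([0]))
        p = make_params([np.log(0.35 / 0.65)] * 3, np.zeros((1, 1)), delta=1e-6)
        assert log_likelihood(panel_match, p) == pytest.approx(0.0, abs=1e-6)
        assert log_likelihood(panel_wrong, p) < -100


class TestJoint:
    def test_equals_sum_of_components(self, toy_panel):
        rng = np.random.default_rng(13)
        p = make_params(rng.normal(size=3), rng.normal(size=(3, 3)),
                        delta=0.15, sigma_T=0.6, sigma_R=0.9)
        total = (log_prior(p) + log_temporal(p.theta, p.sigma_T)
                 + log_spatial(p.r_raw, p.sigma_R) + log_likelihood(toy_panel, p))
        assert log_joint(toy_panel, p) == pytest.approx(total, rel=1e-12)

    def test_quadrat_order_matters(self, toy_panel):
        # RW1 across quadrats is order-sensitive
        rng = np.random.default_rng(17)
        r_raw = rng.normal(size=(3, 3))
        p = make_params(rng.normal(size=3), r_raw)
        permuted = CoverPanel(classes=toy_panel.classes[:, [2, 0, 1]],
                              occasions=toy_panel.occasions)
        p_perm = make_params(p.theta, r_raw[:, [2, 0, 1]], delta=p.delta)
        assert log_joint(toy_panel, p) != pytest.approx(log_joint(permuted, p_perm))

    def test_likelihood_invariant_to_row_shifts_of_r(self, toy_panel):
        # centering absorbs per-occasion constants; only the RW/prior terms move
        rng = np.random.default_rng(19)
        p = make_params(rng.normal(size=3), rng.normal(size=(3, 3)))
        shifted = make_params(p.theta, p.r_raw + np.array([[1.0], [-2.0], [0.5]]),
                              delta=p.delta)
        assert log_likelihood(toy_panel, p) == pytest.approx(
            log_likelihood(toy_panel, shifted), rel=1e-12)

    def test_support_violation_propagates(self, toy_panel):
        p = make_params(np.zeros(3), np.zeros((3, 3)), sigma_T=-0.5)
        assert log_joint(toy_panel, p) == -np.inf
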