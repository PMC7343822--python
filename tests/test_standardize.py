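"""The three standardisation functions: diameter assignment, small-tree
expansion, and the AGB 10–20 cm correction model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from forestagb.distributions import WeibullDBHModel
from forestagb.standardize import (
    CorrectionModel,
    assign_diameter,
    assign_species_pro_rata,
    compute_shape_metrics,
    expand_small_trees,
    expected_total,
    fit_correction_model,
    predict_agb_10_20,
)


@pytest.fixture(scope="module")
def model():
    return WeibullDBHModel()


class TestAssignDiameter:
    def test_u_zero_returns_lower_bound(self, model):
        assert float(assign_diameter(30.0, 40.0, model, u=0.0)) == pytest.approx(30.0)

    def test_conditional_mean_matches_quadrature_oracle(self, model):
        rng = np.random.default_rng(5)
        draws = assign_diameter(30.0, 40.0, model, rng=rng, size=200_000)
        p = model.class_prob(30.0, 40.0)
        num, _ = integrate.quad(lambda x: x * model.trunc_pdf(x), 30.0, 40.0)
        oracle = num / p
        se = draws.std() / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(oracle, abs=3 * se)

    def test_open_class_draws_bounded_and_pass_ks(self, model):
        rng = np.random.default_rng(6)
        draws = assign_diameter(150.0, None, model, rng=rng, size=10_000)
        assert np.all((draws >= 150.0) & (draws <= 400.0))
        span = model.cdf(400.0) - model.cdf(150.0)
        cdf = lambda x: (model.cdf(x) - model.cdf(150.0)) / span
        assert stats.kstest(draws, cdf).pvalue > 0.01

    def test_class_outside_support_rejected(self, model):
        with pytest.raises(ValueError):
            assign_diameter(380.0, 420.0, model, u=0.5)


class TestExpandSmallTrees:
    def test_fully_sampled_class_unchanged(self):
        assert expand_small_trees(7, 1.0) == 7

    def test_nothing_observed_nothing_expanded(self):
        rng = np.random.default_rng(0)
        assert expand_small_trees(0, 0.3, rng) == 0

    def test_mean_matches_r_over_p(self):
        # oracle: analytic E[r + X] = r/p for NegBin(r, p)
        rng = np.random.default_rng(8)
        totals = np.array([expand_small_trees(10, 0.5, rng) for _ in range(100_000)])
        se = totals.std() / np.sqrt(totals.size)
        assert totals.mean() == pytest.approx(20.0, abs=3 * se)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, p):
        with pytest.raises(ValueError):
            expand_small_trees(5, p, np.random.default_rng(0))

    def test_expansion_inverts_binomial_thinning(self):
        # unbiasedness: thin n trees at p, expand back; mean total == n
        rng = np.random.default_rng(9)
        n, p, reps = 200, 0.3, 10_000
        r = rng.binomial(n, p, size=reps)
        totals = np.where(r > 0, r + rng.negative_binomial(np.maximum(r, 1), p), 0)
        se = totals.std() / np.sqrt(reps)
        assert totals.mean() == pytest.approx(n, abs=3 * se)

    def test_expected_total_deterministic(self):
        assert expected_total(10, 0.5) == 20
        assert expected_total(0, 0.25) == 0


class TestProRataSpecies:
    def test_single_taxon_gets_everything(self):
        rng = np.random.default_rng(1)
        labels = assign_species_pro_rata(10, {"A": 4}, rng)
        assert labels == ["A"] * 10

    def test_frequencies_match_multinomial_oracle(self):
        rng = np.random.default_rng(2)
        labels = assign_species_pro_rata(100_000, {"A": 3, "B": 1}, rng)
        freq = labels.count("A") / len(labels)
        se = np.sqrt(0.75 * 0.25 / len(labels))
        assert freq == pytest.approx(0.75, abs=3 * se)

    def test_zero_new_trees(self):
        assert assign_species_pro_rata(0, {"A": 1}, np.random.default_rng(0)) == []

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            assign_species_pro_rata(3, {}, np.random.default_rng(0))


class TestShapeMetrics:
    def test_constant_class_agb_hand_algebra(self):
        # each class holds A: y = (A/10)x - 2A, so S = A/10, I = -2A
        A = 12.5
        m = compute_shape_metrics({lo: A for lo in (20.0, 30.0, 40.0, 50.0, 60.0)})
        assert m.S == pytest.approx(A / 10.0)
        assert m.I == pytest.approx(-2.0 * A)

    def test_all_zero_classes(self):
        m = compute_shape_metrics({lo: 0.0 for lo in (20.0, 30.0, 40.0, 50.0, 60.0)})
        assert (m.S, m.I) == (0.0, 0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 500.0), min_size=5, max_size=5))
    def test_matches_normal_equations_oracle(self, agbs):
        class_agb = dict(zip((20.0, 30.0, 40.0, 50.0, 60.0), agbs))
        m = compute_shape_metrics(class_agb)
        x = np.array([30.0, 40.0, 50.0, 60.0, 70.0])
        y = np.cumsum(agbs)
        X = np.column_stack([np.ones(5), x])
        coef = np.linalg.solve(X.T @ X, X.T @ y)  # independent normal equations
        assert m.I == pytest.approx(coef[0], abs=1e-8 + 1e-8 * abs(coef[0]))
        assert m.S == pytest.approx(coef[1], abs=1e-10 + 1e-8 * abs(coef[1]))

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            compute_shape_metrics({20.0: 1.0, 30.0: 1.0})


class TestCorrectionModel:
    @staticmethod
    def _design(n, rng):
        agb_ge20 = rng.uniform(100, 500, size=n)
        s = rng.uniform(0.5, 5.0, size=n)
        i = rng.uniform(-100, 0, size=n)
        return agb_ge20, s, i

    def test_noise_free_recovery_to_six_digits(self):
        rng = np.random.default_rng(21)
        a, b, c, d = 12.0, 0.05, 3.0, -0.2
        ge20, s, i = self._design(200, rng)
        y = a + b * ge20 + c * s + d * i
        m = fit_correction_model(y, ge20, s, i)
        for got, true in zip((m.a, m.b, m.c, m.d), (a, b, c, d)):
            assert got == pytest.approx(true, rel=1e-6)
        assert m.epsilon == pytest.approx(0.0, abs=1e-8)
        assert m.r2_calib == pytest.approx(1.0)

    def test_residual_sd_recovered_from_noisy_data(self):
        rng = np.random.default_rng(22)
        sigma = 7.0
        ge20, s, i = self._design(10_000, rng)
        y = 10.0 + 0.08 * ge20 + 2.0 * s - 0.1 * i + rng.normal(0, sigma, size=10_000)
        m = fit_correction_model(y, ge20, s, i)
        assert m.epsilon == pytest.approx(sigma, rel=0.03)

    def test_rank_deficient_design_rejected(self):
        n = 50
        ge20 = np.full(n, 300.0)
        s = np.full(n, 2.0)
        i = np.full(n, -50.0)
        with pytest.raises(ValueError):
            fit_correction_model(np.ones(n), ge20, s, i)

    def test_prediction_branches(self):
        m = CorrectionModel(a=5.0, b=0.1, c=2.0, d=-0.5, epsilon=4.0)
        det = float(predict_agb_10_20(200.0, 3.0, -20.0, m))
        assert det == pytest.approx(5.0 + 0.1 * 200.0 + 2.0 * 3.0 - 0.5 * -20.0)
        # far-negative mean is floored at zero
        floored = CorrectionModel(a=-1e4, b=0.0, c=0.0, d=0.0, epsilon=0.0)
        assert float(predict_agb_10_20(100.0, 1.0, 1.0, floored)) == 0.0

    def test_error_draw_sd_matches_epsilon(self):
        m = CorrectionModel(a=500.0, b=0.0, c=0.0, d=0.0, epsilon=4.0)
        rng = np.random.default_rng(23)
        draws = predict_agb_10_20(np.zeros(100_000), 0.0, 0.0, m, rng=rng, with_error=True)
        # mean 500 >> 3 sd: clipping never bites
        assert draws.std() == pytest.approx(4.0, rel=0.02)
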