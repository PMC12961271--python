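import numpy as np
import pytest

from tagine import (LogisticFit, aic, compare_models, fit_logistic,
                    wald_pvalues)
from tagine.stats import _fit_design

from _reference import sm_aic, sm_logit


def logistic_labels(rng, eta):
    return (rng.random(eta.size) < 1 / (1 + np.exp(-eta))).astype(float)


class TestFitLogistic:
    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.ones((4, 1)), [0, 0, 1, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.arange(4.0)[:, None], [1, 1, 1, 1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_logistic(np.empty((4, 0)), [0, 1, 0, 1])

    def test_orthogonal_predictor_gives_null_likelihood(self):
        # y balanced and x orthogonal to it: slope ~ 0, ll ~ n ln(1/2)
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        x = np.array([1, 1, -1, -1, 1, 1, -1, -1], dtype=float)[:, None]
        fit = fit_logistic(x, y)
        assert fit.converged
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-6)
        assert fit.log_likelihood == pytest.approx(8 * np.log(0.5), abs=1e-8)

    def test_perfect_separation_flagged_like_reference_divergence(self):
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])[:, None]
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        fit = fit_logistic(x, y)
        assert fit.separation_detected
        # the reference GLM also diverges on the same 6 points: its
        # likelihood runs to 0 and coefficients explode
        ref = sm_logit(x, y)
        assert abs(ref.llf) < 1e-3 or np.abs(ref.params[1]) > 20

    def test_matches_reference_mle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 3))
        y = logistic_labels(rng, 0.3 + X @ np.array([1.0, -0.5, 0.0]))
        fit = fit_logistic(X, y)
        ref = sm_logit(X, y)
        assert fit.converged and not fit.separation_detected
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)
        assert fit.coefficients == pytest.approx(ref.params, abs=1e-6)
        assert fit.standard_errors == pytest.approx(ref.bse, rel=1e-5)

    def test_replicated_data_doubles_likelihood(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 2))
        y = logistic_labels(rng, X @ np.array([1.0, 0.5]))
        fit1 = fit_logistic(X, y)
        fit2 = fit_logistic(np.vstack([X, X]), np.concatenate([y, y]))
        assert fit2.log_likelihood == pytest.approx(2 * fit1.log_likelihood,
                                                    abs=1e-8)
        assert fit2.coefficients == pytest.approx(fit1.coefficients, abs=1e-6)


class TestAic:
    def test_formula(self):
        fit = LogisticFit(np.zeros(3), np.ones(3), -10.0, 3, True, False, 50)
        assert aic(fit) == 26.0

    def test_intercept_only_closed_form(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        fit = _fit_design(np.ones((4, 1)), y, col_sd=np.empty(0))
        assert aic(fit) == pytest.approx(2 + 8 * np.log(2), abs=1e-8)

    def test_near_zero_signal_column_adds_two(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=200)
        y = logistic_labels(rng, 1.2 * x)
        z = rng.normal(size=200) * 1e-8  # numerically inert extra predictor
        a1 = aic(fit_logistic(x[:, None], y))
        a2 = aic(fit_logistic(np.column_stack([x, z]), y))
        assert a2 - a1 == pytest.approx(2.0, abs=1e-3)


class TestWaldPvalues:
    def test_normal_quantile(self):
        fit = LogisticFit(np.array([0.0, 1.96]), np.array([1.0, 1.0]),
                          -5.0, 2, True, False, 50)
        assert wald_pvalues(fit)[0] == pytest.approx(0.05, abs=1e-3)

    def test_zero_coefficient_gives_one(self):
        fit = LogisticFit(np.array([0.3, 0.0]), np.array([1.0, 2.0]),
                          -5.0, 2, True, False, 50)
        assert wald_pvalues(fit)[0] == 1.0

    def test_infinite_se_is_conservative(self):
        fit = LogisticFit(np.array([0.0, 5.0]), np.array([1.0, np.inf]),
                          -5.0, 2, True, False, 50)
        assert wald_pvalues(fit)[0] == 1.0

    def test_matches_reference_glm(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(150, 4))
        y = logistic_labels(rng, X @ np.array([0.8, -0.8, 0.2, 0.0]))
        fit = fit_logistic(X, y)
        ref = sm_logit(X, y)
        assert wald_pvalues(fit) == pytest.approx(ref.pvalues[1:], abs=1e-6)


class TestCompareModels:
    def test_collinear_children_never_expand(self):
        rng = np.random.default_rng(1)
        node = rng.random(100) + 0.1
        children = np.column_stack([node / 2, node / 2])
        y = logistic_labels(rng, 2 * (node - node.mean()) / node.std())
        cmp = compare_models(node, children, y)
        assert not cmp.expand
        # identical likelihood, exactly one extra parameter in the design
        # that survives (the duplicate direction is rank-deficient)
        assert cmp.aic_expanded >= cmp.aic_collapsed

    def test_uninformative_reparameterization_costs_two_per_extra_child(self):
        # children = fixed proportions of the parent: no information added,
        # AIC difference is exactly 2(c-1) once likelihoods agree
        rng = np.random.default_rng(13)
        node = rng.random(150) + 0.1
        for c in (2, 3, 4):
            props = rng.dirichlet(np.ones(c))
            children = node[:, None] * props[None, :]
            y = logistic_labels(rng, (node - node.mean()) / node.std())
            cmp = compare_models(node, children, y)
            # rank-deficient expanded design: the fitted likelihood must
            # match the collapsed one to 1e-6
            ll_col = (2 * 2 - cmp.aic_collapsed) / 2
            ll_exp = (2 * (c + 1) - cmp.aic_expanded) / 2
            assert ll_exp == pytest.approx(ll_col, abs=1e-6)
            assert cmp.aic_expanded - cmp.aic_collapsed == \
                pytest.approx(2 * (c - 1), abs=1e-5)
            assert not cmp.expand

    def test_children_sum_contract(self):
        rng = np.random.default_rng(14)
        node = rng.random(50)
        children = rng.random((50, 2))
        with pytest.raises(ValueError, match="sum"):
            compare_models(node, children, rng.integers(0, 2, 50))

    def test_planted_child_recovered(self):
        # labels are a noisy threshold on child1 (a deterministic threshold
        # would separate the expanded model perfectly, and separation is
        # deliberately resolved by keeping the clade collapsed)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            child1 = rng.lognormal(0, 1, 200)
            child2 = rng.lognormal(0, 1, 200)
            z = (child1 - child1.mean()) / child1.std()
            y = logistic_labels(rng, 3 * z)
            cmp = compare_models(child1 + child2,
                                 np.column_stack([child1, child2]), y)
            if cmp.expand and cmp.significant_children[0] \
                    and not cmp.significant_children[1]:
                hits += 1
        assert hits >= 95

    def test_null_false_expansion_rate_bounded(self):
        # AIC admits a known null expansion rate ~ P(chi2_1 > 2) ~ 16%
        expands = 0
        for seed in range(500):
            rng = np.random.default_rng(1000 + seed)
            child1 = rng.lognormal(0, 1, 200)
            child2 = rng.lognormal(0, 1, 200)
            y = rng.integers(0, 2, 200).astype(float)
            if np.unique(y).size < 2:
                continue
            cmp = compare_models(child1 + child2,
                                 np.column_stack([child1, child2]), y)
            expands += cmp.expand
        assert expands / 500 < 0.25

    def test_nested_likelihood_dominance(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            c = int(rng.integers(2, 5))
            children = rng.lognormal(0, 1, size=(120, c))
            node = children.sum(axis=1)
            y = logistic_labels(rng, rng.normal(size=120))
            cmp = compare_models(node, children, y)
            if np.isnan(cmp.aic_expanded):
                continue
            ll_col = (2 * 2 - cmp.aic_collapsed) / 2
            ll_exp = (2 * (c + 1) - cmp.aic_expanded) / 2
            assert ll_exp >= ll_col - 1e-6

    def test_constant_children_dropped_and_pruned(self):
        rng = np.random.default_rng(22)
        child1 = rng.lognormal(0, 1, 100)
        child2 = np.zeros(100)
        y = (child1 > np.median(child1)).astype(float)
        cmp = compare_models(child1 + child2,
                             np.column_stack([child1, child2]), y)
        assert not cmp.significant_children[1]

    def test_matches_reference_aic_on_well_conditioned_input(self):
        rng = np.random.default_rng(23)
        children = rng.lognormal(0, 1, size=(150, 3))
        node = children.sum(axis=1)
        y = logistic_labels(rng, (children[:, 0] - children[:, 0].mean()))
        cmp = compare_models(node, children, y)
        assert cmp.aic_collapsed == pytest.approx(sm_aic(node, y), abs=1e-6)
        assert cmp.aic_expanded == pytest.approx(sm_aic(children, y), abs=1e-6)
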