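"""Partial credit model: probabilities, information, JMLE, fit diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from shortscreen.pcm import (
    MISSING,
    EstimationError,
    ResponseMatrix,
    category_probabilities,
    expected_score,
    fit_jmle,
    fit_statistics,
    item_information,
    residual_pca,
)
from shortscreen.pcm import test_information as information_curve
from shortscreen.synth import CohortSpec, generate_cohort

from conftest import centered_true_delta

finite_logits = st.floats(-5, 5, allow_nan=False)


class TestCategoryProbabilities:
    def test_hand_computed_three_category_case(self):
        # theta=0, delta=(-1, +1): unnormalized masses (1, e, 1)
        p = category_probabilities(0.0, [-1.0, 1.0])
        e = math.e
        np.testing.assert_allclose(p, np.array([1, e, 1]) / (2 + e), rtol=1e-12)

    def test_dichotomous_symmetry_at_threshold(self):
        np.testing.assert_allclose(category_probabilities(0.7, [0.7]), [0.5, 0.5])

    def test_dichotomous_reduces_to_logistic(self):
        theta, delta = 1.3, -0.4
        p = category_probabilities(theta, [delta])
        assert p[1] == pytest.approx(1 / (1 + math.exp(-(theta - delta))), rel=1e-12)

    @given(
        theta=finite_logits,
        delta=st.lists(finite_logits, min_size=1, max_size=5),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_normalization_and_range(self, theta, delta):
        p = category_probabilities(theta, delta)
        assert p.shape == (len(delta) + 1,)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p > 0) and np.all(p < 1)

    def test_rejects_non_finite_inputs(self):
        with pytest.raises(ValueError):
            category_probabilities(np.nan, [0.0])
        with pytest.raises(ValueError):
            category_probabilities(0.0, [np.inf])


class TestItemInformation:
    def test_dichotomous_quarter_at_threshold(self):
        assert item_information(0.5, [0.5]) == pytest.approx(0.25, abs=1e-12)

    def test_hand_computed_variance(self):
        # theta=0, delta=(-1,1): E[X]=1, E[X^2]=(e+4)/(2+e)
        info = item_information(0.0, [-1.0, 1.0])
        expected = (math.e + 4) / (2 + math.e) - 1.0
        assert info == pytest.approx(expected, rel=1e-12)

    @given(theta=finite_logits, delta=st.lists(finite_logits, min_size=1, max_size=4))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_equals_slope_of_expected_score(self, theta, delta):
        h = 1e-5
        slope = (expected_score(theta + h, delta) - expected_score(theta - h, delta)) / (
            2 * h
        )
        assert item_information(theta, delta) == pytest.approx(slope, abs=1e-6)


class TestTestInformation:
    def _params(self):
        from shortscreen.pcm import PCMParameters

        return PCMParameters(
            delta=[np.array([0.5]), np.array([-1.0, 1.0]), np.array([0.0, 0.3])],
            theta=np.zeros(2),
            item_ids=["a", "b", "c"],
        )

    def test_additivity_over_items(self):
        params = self._params()
        grid = np.linspace(-3, 3, 101)
        both = information_curve(params, grid, items=["a", "b"]).curve
        a = information_curve(params, grid, items=["a"]).curve
        b = information_curve(params, grid, items=["b"]).curve
        np.testing.assert_allclose(both, a + b, rtol=1e-12)

    def test_single_dichotomous_item_peaks_at_threshold(self):
        params = self._params()
        res = information_curve(params, items=["a"])
        assert res.theta_star == pytest.approx(0.5, abs=1e-9)

    def test_peak_stable_under_grid_refinement(self):
        params = self._params()
        coarse = information_curve(params, np.arange(-6, 6.001, 0.01))
        fine = information_curve(params, np.arange(-6, 6.0001, 0.001))
        assert abs(coarse.theta_star - fine.theta_star) <= 0.01

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            information_curve(self._params(), items=[])

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            information_curve(self._params(), np.array([0.0, 0.0, 1.0]))


def _simple_matrix(resp, m=None):
    resp = np.asarray(resp)
    if m is None:
        m = resp.max(axis=0)
    return ResponseMatrix(
        responses=resp,
        item_ids=[f"item_{j+1}" for j in range(resp.shape[1])],
        m=np.asarray(m),
    )


class TestResponseMatrix:
    def test_rejects_out_of_range_codes(self):
        with pytest.raises(ValueError):
            _simple_matrix([[0, 5], [1, 0]], m=[1, 4])

    def test_requires_two_persons_and_items(self):
        with pytest.raises(ValueError):
            _simple_matrix([[0, 1]], m=[1, 1])


class TestJMLE:
    def test_identical_items_get_identical_thresholds(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=60)
        resp = np.column_stack([col, col, rng.integers(0, 3, size=60)])
        params = fit_jmle(_simple_matrix(resp, m=[2, 2, 2]))
        np.testing.assert_allclose(params.delta[0], params.delta[1], atol=1e-6)

    def test_parameter_recovery(self, recovery_spec, recovery_cohort):
        params = fit_jmle(recovery_cohort.responses)
        true = centered_true_delta(recovery_spec)
        est = np.concatenate(params.delta)
        assert est.size == true.size  # no category collapsed at this n
        r = np.corrcoef(true, est)[0, 1]
        rmse = float(np.sqrt(np.mean((true - est) ** 2)))
        assert r > 0.95
        assert rmse < 0.3

    def test_recovery_bias_shrinks_with_n(self, recovery_spec):
        import dataclasses

        biases = []
        for n in (200, 1000, 5000):
            spec = dataclasses.replace(recovery_spec, n=n, seed=42)
            cohort = generate_cohort(spec)
            params = fit_jmle(cohort.responses)
            true = centered_true_delta(spec)
            est = np.concatenate(params.delta)
            biases.append(abs(float(np.mean(est - true))))
        assert biases[0] > biases[2]

    def test_anchoring_every_person_decomposes_per_item(self, recovery_cohort):
        """With all persons fixed, each item's thresholds solve that item's
        own likelihood; a brute-force independent maximization must agree."""
        data = recovery_cohort.responses
        theta = recovery_cohort.theta_true
        anchors = {i: float(theta[i]) for i in range(data.n_persons)}
        params = fit_jmle(data, anchors=anchors)

        for i in [0, 4, 7]:  # spot-check three items
            obs = data.responses[:, i]

            def neg_ll(delta_vec, obs=obs):
                ll = 0.0
                p = category_probabilities(theta, delta_vec)
                return -float(np.log(p[np.arange(obs.size), obs]).sum())

            res = optimize.minimize(
                neg_ll, np.zeros(data.m[i]), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 5000},
            )
            np.testing.assert_allclose(params.delta[i], res.x, atol=0.02)

    def test_anchored_thetas_returned_bit_for_bit(self, recovery_cohort):
        data = recovery_cohort.responses
        anchors = {0: 0.12345678901234567, 5: -1.9876543210987654}
        params = fit_jmle(data, anchors=anchors)
        assert params.theta[0] == anchors[0]
        assert params.theta[5] == anchors[5]
        assert params.anchored_persons == frozenset(anchors)

    def test_centering_constraint_without_anchors(self, recovery_cohort):
        params = fit_jmle(recovery_cohort.responses)
        assert abs(params.item_location.mean()) < 1e-6

    def test_extreme_persons_flagged_and_finite(self):
        rng = np.random.default_rng(3)
        resp = rng.integers(0, 3, size=(40, 4))
        resp[0] = 0
        resp[1] = 2
        params = fit_jmle(_simple_matrix(resp, m=[2, 2, 2, 2]))
        assert {0, 1} <= params.extreme_persons
        free = [i for i in range(resp.shape[0]) if i not in params.extreme_persons]
        assert params.theta[0] < params.theta[free].min()
        assert params.theta[1] > params.theta[free].max()
        assert np.all(np.isfinite(params.theta))

    def test_unobserved_intermediate_category_collapsed(self):
        rng = np.random.default_rng(5)
        resp = rng.integers(0, 3, size=(50, 3))
        resp[:, 0][resp[:, 0] == 1] = 2  # category 1 never observed
        params = fit_jmle(_simple_matrix(resp, m=[2, 2, 2]))
        assert params.delta[0].size == 1  # collapsed to dichotomous
        np.testing.assert_array_equal(params.category_maps[0], [0, 0, 1])
        assert params.delta[1].size == 2

    def test_all_extreme_data_is_an_error(self):
        resp = np.array([[0, 0], [2, 2], [0, 0], [2, 2]])
        with pytest.raises(EstimationError):
            fit_jmle(_simple_matrix(resp, m=[2, 2]))


class TestFitStatistics:
    def test_calibrated_under_the_generating_model(self, recovery_cohort):
        data = recovery_cohort.responses
        params = fit_jmle(data)
        fs = fit_statistics(data, params)
        assert np.all(fs.item_infit > 0) and np.all(fs.item_outfit > 0)
        in_band = np.sum(
            (fs.item_infit >= 0.8) & (fs.item_infit <= 1.2)
            & (fs.item_outfit >= 0.8) & (fs.item_outfit <= 1.2)
        )
        assert in_band >= 7

    def test_maximally_inconsistent_person_has_max_outfit(self, recovery_cohort):
        data = recovery_cohort.responses
        params = fit_jmle(data)
        # flip person 0's responses to the opposite extreme of expectation
        resp = data.responses.copy()
        for j in range(data.n_items):
            e = expected_score(params.theta[0], params.delta[j])
            resp[0, j] = 0 if e > data.m[j] / 2 else data.m[j]
        flipped = ResponseMatrix(responses=resp, item_ids=data.item_ids, m=data.m)
        fs = fit_statistics(flipped, params)
        assert np.argmax(fs.person_outfit) == 0

    def test_hand_computed_two_by_two(self):
        """2 persons x 2 dichotomous items with fixed parameters: statistics
        match residuals computed from the closed-form logistic expectations."""
        from shortscreen.pcm import PCMParameters

        resp = np.array([[1, 0], [0, 1]])
        data = _simple_matrix(resp, m=[1, 1])
        theta = np.array([0.5, -0.5])
        delta = [np.array([0.0]), np.array([0.2])]
        params = PCMParameters(delta=delta, theta=theta, item_ids=data.item_ids)
        fs = fit_statistics(data, params)

        p = np.array(
            [
                [1 / (1 + math.exp(-(0.5 - 0.0))), 1 / (1 + math.exp(-(0.5 - 0.2)))],
                [1 / (1 + math.exp(-(-0.5 - 0.0))), 1 / (1 + math.exp(-(-0.5 - 0.2)))],
            ]
        )
        var = p * (1 - p)
        z2 = (resp - p) ** 2 / var
        np.testing.assert_allclose(fs.person_outfit, z2.mean(axis=1), rtol=1e-10)
        np.testing.assert_allclose(fs.item_outfit, z2.mean(axis=0), rtol=1e-10)
        np.testing.assert_allclose(
            fs.item_infit, ((resp - p) ** 2).sum(axis=0) / var.sum(axis=0), rtol=1e-10
        )


class TestResidualPCA:
    def test_eigenvalues_sum_to_item_count(self, recovery_cohort):
        data = recovery_cohort.responses
        params = fit_jmle(data)
        pca = residual_pca(data, params)
        assert pca.eigenvalues.sum() == pytest.approx(data.n_items, abs=1e-6)
        assert np.all(np.diff(pca.eigenvalues) <= 1e-12)

    def test_model_true_data_near_unidimensional(self, recovery_cohort):
        data = recovery_cohort.responses
        params = fit_jmle(data)
        pca = residual_pca(data, params)
        assert pca.eigenvalues[0] <= 2.0

    def test_planted_second_dimension_loads_together(self):
        """Inject a shared nuisance dimension into items 2 and 7: their
        first-contrast loadings must dominate and share a sign."""
        rng = np.random.default_rng(9)
        n = 400
        theta = rng.normal(0, 1, n)
        nuisance = rng.normal(0, 1, n)
        resp = np.empty((n, 8), dtype=int)
        for j in range(8):
            t = theta + (1.5 * nuisance if j in (1, 6) else 0.0)
            p = 1 / (1 + np.exp(-(t - 0.0)))
            resp[:, j] = (rng.random(n) < p).astype(int)
        data = _simple_matrix(resp, m=[1] * 8)
        params = fit_jmle(data)
        pca = residual_pca(data, params)
        load = pca.first_contrast_loadings
        top2 = set(np.argsort(np.abs(load))[-2:])
        assert top2 == {1, 6}
        assert load[1] * load[6] > 0

    def test_fewer_persons_than_items_rejected(self):
        resp = np.array([[0, 1, 0], [1, 0, 1]])
        data = _simple_matrix(resp, m=[1, 1, 1])
        params = fit_jmle(data)
        with pytest.raises(ValueError):
            residual_pca(data, params)
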