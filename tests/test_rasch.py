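import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import maprkit as mk
import oracles
from maprkit.exceptions import ValidationError


class TestPreferenceProbability:
    def test_equal_values_give_fifty_fifty(self):
        assert mk.prob_prefer_own(0.3, 0.3) == pytest.approx(0.5)

    def test_closed_form(self):
        assert mk.prob_prefer_own(np.log(3), 0.0) == pytest.approx(0.75)

    def test_infinite_limits(self):
        assert mk.prob_prefer_own(np.inf, 1.0) == 1.0
        assert mk.prob_prefer_own(-np.inf, 1.0) == 0.0
        assert mk.prob_prefer_own(0.0, np.inf) == 0.0

    def test_logit_form(self):
        assert mk.preference_logit(1.5, 0.5) == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None)
    @given(theta=st.floats(-30, 30), beta=st.floats(-30, 30))
    def test_symmetry_and_monotonicity(self, theta, beta):
        p = mk.prob_prefer_own(theta, beta)
        assert p + mk.prob_prefer_own(beta, theta) == pytest.approx(1.0)
        assert mk.prob_prefer_own(theta + 0.5, beta) >= p

    @settings(max_examples=50, deadline=None)
    @given(theta=st.floats(-20, 20), beta=st.floats(-20, 20), c=st.floats(-20, 20))
    def test_translation_invariance(self, theta, beta, c):
        assert mk.prob_prefer_own(theta + c, beta + c) == pytest.approx(
            mk.prob_prefer_own(theta, beta), abs=1e-12
        )


class TestResponseMatrix:
    def test_raw_scores_recomputed_from_entries(self, rng):
        Y = rng.integers(0, 2, (7, 4))
        data = mk.ResponseMatrix([f"p{i}" for i in range(7)],
                                 [f"i{j}" for j in range(4)], Y)
        assert (data.raw_scores == Y.sum(axis=1)).all()

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            mk.ResponseMatrix(["p1"], ["a", "b"], np.array([[0, 2]]))

    def test_missing_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            mk.ResponseMatrix(["p1"], ["a", "b"], np.array([[0.0, np.nan]]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            mk.ResponseMatrix(["p1", "p1"], ["a"], np.zeros((2, 1)))


class TestElementarySymmetric:
    def test_order_zero_is_one(self):
        g, _ = mk.elementary_symmetric([0.5, 2.0, 7.0], 0)
        assert g == 1.0

    def test_definition_small_case(self):
        a, b, c = 0.5, 2.0, 3.0
        g, loo = mk.elementary_symmetric([a, b, c], 2)
        assert g == pytest.approx(a * b + a * c + b * c)
        # loo[i] = gamma_1 over the other two items
        assert loo == pytest.approx([b + c, a + c, a + b])

    def test_matches_subset_enumeration(self, rng):
        eps = rng.uniform(0.1, 10.0, 8)
        for r in range(9):
            g, _ = mk.elementary_symmetric(eps, r)
            assert g == pytest.approx(oracles.esf_enumerate(eps, r), rel=1e-12)

    def test_loo_recursion_identity(self, rng):
        # gamma_r = eps_i * gamma_{r-1}^{(i)} + gamma_r^{(i)} for every i
        eps = rng.uniform(0.1, 10.0, 6)
        for r in range(1, 6):
            g, loo = mk.elementary_symmetric(eps, r)
            for i in range(6):
                g_without = oracles.esf_enumerate(np.delete(eps, i), r)
                assert g == pytest.approx(eps[i] * loo[i] + g_without, rel=1e-10)

    def test_out_of_range_order_rejected(self):
        with pytest.raises(ValidationError):
            mk.elementary_symmetric([1.0, 2.0], 3)


class TestFitRaschCML:
    def test_identical_response_columns_get_equal_values(self, rng):
        base = (rng.random((40, 1)) < 0.5).astype(int)
        other = (rng.random((40, 2)) < [[0.3, 0.7]]).astype(int)
        Y = np.hstack([base, base, other])
        data = mk.ResponseMatrix([f"p{i}" for i in range(40)],
                                 ["a", "a2", "b", "c"], Y)
        fit = mk.fit_rasch_cml(data)
        ia, ia2 = fit.items.index("a"), fit.items.index("a2")
        assert fit.beta[ia] == pytest.approx(fit.beta[ia2], abs=1e-9)

    def test_matches_grid_search_oracle(self, small_sim):
        fit = mk.fit_rasch_cml(small_sim.data, anchor=("item", small_sim.data.items[0]))
        oracle = oracles.grid_argmax_cml(
            small_sim.data.Y[~small_sim.data.extreme_person_mask()], n_free=2
        )
        assert np.abs(fit.beta - oracle).max() < 2e-3

    def test_score_equations_hold_at_optimum(self, small_sim):
        # observed item margins equal expected conditional margins
        fit = mk.fit_rasch_cml(small_sim.data)
        from maprkit.rasch import _cml_derivs
        reduced = small_sim.data.subset(
            person_mask=~small_sim.data.extreme_person_mask())
        r_vals, m_r = np.unique(reduced.raw_scores, return_counts=True)
        _, score, _ = _cml_derivs(fit.beta, reduced.Y.sum(0).astype(float),
                                  r_vals, m_r, need_hessian=False)
        assert np.abs(score).max() < 1e-8

    def test_sum_zero_anchoring_and_reanchor(self, small_sim):
        fit = mk.fit_rasch_cml(small_sim.data)
        assert fit.beta.sum() == pytest.approx(0.0, abs=1e-10)
        ref = fit.reanchor(fit.items[1])
        assert ref.beta[1] == 0.0
        assert np.diff(ref.beta) == pytest.approx(np.diff(fit.beta), abs=1e-12)

    def test_extreme_persons_and_constant_items_dropped(self):
        rngl = np.random.default_rng(5)
        Y = (rngl.random((30, 4)) < 0.5).astype(int)
        Y[0] = 1          # extreme person
        Y[1] = 0          # extreme person
        Y[2:, 3] = 1      # constant among retained persons
        Y[:2, 3] = 1
        data = mk.ResponseMatrix([f"p{i}" for i in range(30)],
                                 ["a", "b", "c", "d"], Y)
        fit = mk.fit_rasch_cml(data)
        # p0/p1 are extreme outright; removing the constant column can make
        # further persons extreme on the remaining items (iterated reduction)
        assert {"p0", "p1"} <= set(fit.dropped_persons)
        assert fit.dropped_items == ["d"]
        assert fit.n_persons_used == 30 - len(fit.dropped_persons)

    def test_ill_conditioned_matrix_raises_with_witness(self):
        # whenever a or b is endorsed, c and d are too: the bipartition
        # ({a, b}, {c, d}) violates the partition condition even though no
        # column is constant and no row is extreme
        Y = np.array([
            [1, 0, 1, 1],
            [0, 1, 1, 1],
            [0, 0, 1, 0],
            [0, 0, 0, 1],
        ])
        data = mk.ResponseMatrix([f"p{i}" for i in range(4)],
                                 ["a", "b", "c", "d"], Y)
        ok, witness = mk.check_well_conditioned(data)
        assert not ok and set(witness[0]) | set(witness[1]) == {"a", "b", "c", "d"}
        with pytest.raises(mk.IllConditionedError) as exc:
            mk.fit_rasch_cml(data)
        assert exc.value.witness is not None

    def test_parameter_recovery_simulation(self):
        true_beta = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        sc = mk.SimulationScenario(
            item_codes=("a", "b", "c", "d", "e"),
            item_values=tuple(true_beta),
            n_persons=2000, seed=3,
            persons=mk.PersonDistribution(family="normal", loc=0.0, scale=1.0),
        )
        fit = mk.fit_rasch_cml(mk.simulate_responses(sc).data)
        assert np.abs(fit.beta - true_beta).max() < 0.15


class TestFitPersonsML:
    def test_symmetric_case_with_known_se(self):
        pf = mk.fit_persons_ml([5], np.zeros(10))
        assert pf.theta[0] == pytest.approx(0.0, abs=1e-10)
        assert pf.se_theta[0] == pytest.approx(1 / np.sqrt(10 * 0.25), abs=1e-9)

    def test_symmetric_two_items(self):
        pf = mk.fit_persons_ml([1], np.array([-1.0, 1.0]))
        assert pf.theta[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_bisection_oracle(self):
        beta = np.array([-1.0, 0.0, 1.0])
        pf = mk.fit_persons_ml([2], beta)
        assert pf.theta[0] == pytest.approx(oracles.bisect_person(2, beta), abs=1e-8)

    def test_extreme_scores_flagged_infinite(self):
        pf = mk.fit_persons_ml([0, 3], np.zeros(3))
        assert pf.theta[0] == -np.inf and pf.theta[1] == np.inf
        assert pf.extreme.all() and np.isinf(pf.se_theta).all()

    def test_theta_strictly_increasing_in_raw_score(self, rng):
        beta = rng.normal(0, 1.5, 8)
        pf = mk.fit_persons_ml(np.arange(1, 8), beta)
        assert (np.diff(pf.theta) > 0).all()

    def test_se_respects_information_bound(self, rng):
        beta = rng.normal(0, 2, 12)
        pf = mk.fit_persons_ml(np.arange(1, 12), beta)
        assert (pf.se_theta >= 1 / np.sqrt(0.25 * 12) - 1e-12).all()


class TestConditionalLoglik:
    def test_two_equally_likely_patterns(self):
        data = mk.ResponseMatrix(["p1"], ["a", "b"], np.array([[1, 0]]))
        assert mk.conditional_loglik(data, np.zeros(2)) == pytest.approx(np.log(0.5))

    def test_extreme_scores_contribute_zero(self):
        data = mk.ResponseMatrix(["p1", "p2"], ["a", "b"],
                                 np.array([[1, 1], [0, 0]]))
        assert mk.conditional_loglik(data, np.array([0.3, -0.8])) == 0.0

    def test_matches_pattern_enumeration(self, rng):
        beta = rng.normal(0, 1, 5)
        Y = (rng.random((12, 5)) < 0.5).astype(int)
        data = mk.ResponseMatrix([f"p{i}" for i in range(12)],
                                 [f"i{j}" for j in range(5)], Y)
        expected = sum(
            np.log(oracles.pattern_probability_enum(row, beta))
            for row in Y if 0 < row.sum() < 5
        )
        assert mk.conditional_loglik(data, beta) == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_scale_translation(self, small_sim):
        beta = np.array([0.2, -0.5, 0.3])
        a = mk.conditional_loglik(small_sim.data, beta)
        b = mk.conditional_loglik(small_sim.data, beta + 3.7)
        assert a == pytest.approx(b, abs=1e-9)

    def test_invariant_to_swapping_equal_score_patterns(self, small_sim):
        # sufficiency: permuting response patterns among persons with the
        # same raw score leaves the conditional likelihood unchanged
        data = small_sim.data
        r = data.raw_scores
        vals, counts = np.unique(r, return_counts=True)
        rv = vals[(counts >= 2) & (vals > 0) & (vals < data.I)][0]
        idx = np.where(r == rv)[0][:2]
        Y2 = data.Y.copy()
        Y2[idx] = Y2[idx[::-1]]
        data2 = mk.ResponseMatrix(list(data.persons), list(data.items), Y2)
        beta = np.array([0.4, -0.1, -0.3])
        assert mk.conditional_loglik(data, beta) == pytest.approx(
            mk.conditional_loglik(data2, beta), abs=1e-12
        )
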