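import numpy as np
import pytest

import maprkit as mk
import oracles
from conftest import make_random_matrix
from maprkit.exceptions import ValidationError


class TestWellConditioned:
    def test_all_zero_column_is_isolated_by_witness(self, rng):
        Y = (rng.random((10, 4)) < 0.6).astype(int)
        Y[:, 2] = 0
        Y[(Y.sum(1) == 0) | (Y.sum(1) == 4), 0] = 1  # avoid extreme rows
        data = mk.ResponseMatrix([f"p{i}" for i in range(10)],
                                 ["a", "b", "x", "c"], Y)
        ok, witness = mk.check_well_conditioned(data)
        assert not ok
        assert ["x"] in [list(w) for w in witness]

    def test_two_discordant_patterns_are_well_conditioned(self):
        data = mk.ResponseMatrix(["p1", "p2"], ["a", "b"],
                                 np.array([[1, 0], [0, 1]]))
        ok, witness = mk.check_well_conditioned(data)
        assert ok and witness is None

    def test_matches_brute_force_bipartition_enumeration(self, rng):
        mismatches = 0
        for _ in range(100):
            I = int(rng.integers(3, 8))
            P = int(rng.integers(3, 9))
            Y = (rng.random((P, I)) < rng.uniform(0.2, 0.8)).astype(int)
            r = Y.sum(axis=1)
            Y = Y[(r > 0) & (r < I)]
            if Y.shape[0] == 0:
                continue
            data = mk.ResponseMatrix([f"p{i}" for i in range(Y.shape[0])],
                                     [f"i{j}" for j in range(I)], Y)
            ok, _ = mk.check_well_conditioned(data)
            if ok != oracles.brute_force_well_conditioned(Y):
                mismatches += 1
        assert mismatches == 0

    def test_removing_witness_items_terminates(self, rng):
        # iterating witness removal reaches a well-conditioned submatrix
        Y = (rng.random((12, 6)) < 0.5).astype(int)
        Y[:, 4] = 0
        Y[:, 5] = 1
        r = Y.sum(axis=1)
        Y = Y[(r > 0) & (r < 6)]
        data = mk.ResponseMatrix([f"p{i}" for i in range(Y.shape[0])],
                                 [f"i{j}" for j in range(6)], Y)
        for _ in range(6):
            ok, witness = mk.check_well_conditioned(data)
            if ok:
                break
            drop = min(witness, key=len)
            data = data.subset(item_mask=~np.isin(data.items, drop))
        assert ok


@pytest.fixture(scope="module")
def nine_item_sim():
    beta = np.linspace(-1.5, 1.5, 9)
    sc = mk.SimulationScenario(
        item_codes=tuple(f"i{j}" for j in range(9)),
        item_values=tuple(beta - beta.mean()),
        n_persons=400, seed=17,
        persons=mk.PersonDistribution(family="normal", loc=0.0, scale=1.0),
    )
    return mk.simulate_responses(sc).data


class TestAndersen:

    def test_two_group_split_gives_items_minus_one_df(self, nine_item_sim):
        result = mk.andersen_test(nine_item_sim)
        assert result.df == 8
        assert result.statistic >= 0.0
        assert 0.0 <= result.p_value <= 1.0

    def test_invariant_to_group_relabeling(self, nine_item_sim):
        reduced = nine_item_sim.subset(
            person_mask=~nine_item_sim.extreme_person_mask())
        r = reduced.raw_scores
        labels = (r > np.median(r)).astype(int)
        a = mk.andersen_test(nine_item_sim, split=labels)
        b = mk.andersen_test(nine_item_sim, split=1 - labels)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-9)
        assert a.df == b.df

    def test_three_group_df_bookkeeping(self, nine_item_sim):
        reduced = nine_item_sim.subset(
            person_mask=~nine_item_sim.extreme_person_mask())
        r = reduced.raw_scores
        labels = np.digitize(r, np.quantile(r, [1 / 3, 2 / 3]))
        result = mk.andersen_test(nine_item_sim, split=labels)
        assert result.df == 2 * 8

    def test_single_group_rejected(self, nine_item_sim):
        reduced = nine_item_sim.subset(
            person_mask=~nine_item_sim.extreme_person_mask())
        with pytest.raises(ValidationError):
            mk.andersen_test(nine_item_sim, split=np.zeros(reduced.P, int))


class TestNestedLR:
    def test_saturated_design_gives_zero_statistic(self, rng):
        from maprkit.classification import DesignMatrix

        data = make_random_matrix(rng, 120, 4)
        rasch = mk.fit_rasch_cml(data, anchor=("item", data.items[0]))
        I = len(rasch.items)
        W = np.zeros((I, I - 1))
        W[1:, :] = np.eye(I - 1)
        dm = DesignMatrix(matrix=W, columns=tuple(f"item:{c}" for c in rasch.items[1:]),
                          states=(), system=mk.EQ5D3L)
        sub = data.subset(item_mask=np.isin(data.items, rasch.items))
        lltm = mk.fit_mapr_cml(sub, mk.EQ5D3L, design_matrix=dm)
        result = mk.lr_test_nested(rasch, lltm)
        assert result.statistic < 1e-6
        assert result.df == 0

    def test_different_data_fingerprints_rejected(self, rng):
        d1 = make_random_matrix(rng, 80, 4)
        d2 = make_random_matrix(rng, 80, 4)
        system = mk.ClassificationSystem(
            (mk.Attribute("a", 2), mk.Attribute("b", 2)))
        sc = mk.SimulationScenario(
            item_codes=("11", "21", "12", "22"), item_values=(0, -0.5, -1, -1.5),
            n_persons=80, seed=1,
            persons=mk.PersonDistribution(family="normal"),
        )
        data = mk.simulate_responses(sc).data
        rasch = mk.fit_rasch_cml(data)
        lltm = mk.fit_mapr_cml(d1, system, states=[
            mk.parse_state(c, system) for c in ("11", "21", "12", "22")])
        with pytest.raises(ValidationError, match="fingerprint"):
            mk.lr_test_nested(rasch, lltm)


class TestScalogram:
    def test_perfect_guttman_has_no_misfits(self):
        Y = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 0]])
        data = mk.ResponseMatrix([f"p{i}" for i in range(4)],
                                 ["easy", "mid", "hard"], Y)
        assert mk.guttman_scalogram(data).misfit_count == 0

    def test_single_swap_yields_two_misfit_cells(self):
        # person p1 endorses the harder item instead of the easier one
        Y = np.array([[1, 1, 1], [0, 1, 1], [1, 0, 0]])
        data = mk.ResponseMatrix(["p0", "p1", "p2"], ["a", "b", "c"], Y)
        report = mk.guttman_scalogram(data)
        assert report.misfit_count == 2
        assert set(report.misfit_cells) == {("p1", "a"), ("p1", "c")}

    def test_invariant_to_input_permutation(self, rng):
        data = make_random_matrix(rng, 15, 5)
        perm_p = rng.permutation(15)
        perm_i = rng.permutation(5)
        shuffled = mk.ResponseMatrix(
            [data.persons[i] for i in perm_p],
            [data.items[j] for j in perm_i],
            data.Y[np.ix_(perm_p, perm_i)],
        )
        assert (mk.guttman_scalogram(data).misfit_count
                == mk.guttman_scalogram(shuffled).misfit_count)


class TestPersonItemMap:
    def test_all_items_below_every_person(self, rng):
        data = make_random_matrix(rng, 50, 4)
        fit = mk.fit_rasch_cml(data)
        persons = mk.fit_persons_ml(
            data.subset(person_mask=~data.extreme_person_mask()).raw_scores,
            fit.beta)
        shifted = mk.RaschFit(
            items=fit.items, beta=fit.beta - 100.0, se_beta=fit.se_beta,
            cov_beta=fit.cov_beta, log_cl=fit.log_cl,
            n_persons_used=fit.n_persons_used)
        pim = mk.person_item_map(shifted, persons)
        assert pim.fraction_own_better == 1.0

    def test_bins_cover_joint_range(self, rng):
        data = make_random_matrix(rng, 60, 5)
        fit = mk.fit_rasch_cml(data)
        persons = mk.fit_persons_ml(
            data.subset(person_mask=~data.extreme_person_mask()).raw_scores,
            fit.beta)
        pim = mk.person_item_map(fit, persons)
        finite = persons.theta[np.isfinite(persons.theta)]
        lo = min(finite.min(), fit.beta.min())
        hi = max(finite.max(), fit.beta.max())
        assert pim.bin_edges[0] <= lo and pim.bin_edges[-1] >= hi

    def test_symmetric_fit_fraction_near_half(self):
        sc = mk.SimulationScenario(
            item_codes=tuple(f"i{j}" for j in range(6)),
            item_values=tuple(np.linspace(-1, 1, 6)),
            n_persons=800, seed=23,
            persons=mk.PersonDistribution(family="normal", loc=0.0, scale=1.0),
        )
        data = mk.simulate_responses(sc).data
        fit = mk.fit_rasch_cml(data)
        keep = ~data.extreme_person_mask()
        persons = mk.fit_persons_ml(data.subset(person_mask=keep).raw_scores,
                                    fit.beta)
        pim = mk.person_item_map(fit, persons)
        assert 0.4 < pim.fraction_own_better < 0.6
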