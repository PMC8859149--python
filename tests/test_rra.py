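import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rankmeta import (
    adjust_pvalues,
    aggregate,
    beta_score,
    exact_pvalue,
    intersect_universe,
    normalize_ranks,
    rho_score,
    run_meta,
    simulate_null_rank_matrix,
)
from rankmeta.rra import RankMatrix, _exact_pvalues, _rho_scores

from conftest import make_study


class TestIntersectUniverse:
    def test_basic_intersection(self):
        assert intersect_universe([{"a", "b", "c"}, {"b", "c", "d"}, {"b", "c"}]) == ["b", "c"]

    def test_identical_universes_unchanged(self):
        u = {"x", "y", "z"}
        assert intersect_universe([u, set(u)]) == sorted(u)

    def test_matches_brute_force_on_random_universes(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(1000)]
        universes = [set(rng.choice(genes, size=800, replace=False)) for _ in range(4)]
        expected = set(genes)
        for u in universes:
            expected = {g for g in expected if g in u}
        assert set(intersect_universe(universes)) == expected

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            intersect_universe([{"a"}, {"b"}])

    def test_single_universe_is_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            intersect_universe([{"a"}])


class TestNormalizeRanks:
    def test_first_and_last_positions(self):
        universe = [f"g{i}" for i in range(1, 11)]
        mat = normalize_ranks({"s1": universe}, universe)
        assert mat.ranks.at["g1", "s1"] == pytest.approx(0.1)
        assert mat.ranks.at["g10", "s1"] == pytest.approx(1.0)

    def test_hand_computed_positions(self):
        universe = ["a", "b", "c", "d", "e"]
        lists = {
            "s1": ["a", "b", "c", "d", "e"],
            "s2": ["e", "d", "c", "b", "a"],
            "s3": ["c", "a", "e", "b", "d"],
        }
        mat = normalize_ranks(lists, universe)
        expected = pd.DataFrame(
            {"s1": [1, 2, 3, 4, 5], "s2": [5, 4, 3, 2, 1], "s3": [2, 4, 1, 5, 3]},
            index=universe, dtype=float) / 5
        np.testing.assert_allclose(mat.ranks.to_numpy(), expected.to_numpy())
        mat.check_valid()

    def test_non_permutation_error_names_genes(self):
        with pytest.raises(ValueError, match="missing \\['c'\\]"):
            normalize_ranks({"s1": ["a", "b", "x"]}, ["a", "b", "c"])


class TestBetaScore:
    def test_single_uniform(self):
        assert beta_score(0.3, 1, 1) == pytest.approx(0.3)

    def test_all_of_two(self):
        assert beta_score(0.5, 2, 2) == pytest.approx(0.25)

    def test_at_least_one_of_two(self):
        # 1 - (1 - x)^2 by direct binomial expansion
        assert beta_score(0.5, 1, 2) == pytest.approx(0.75)

    def test_equals_beta_cdf_to_1e12(self):
        xs = np.linspace(0.0, 1.0, 101)
        for n in range(1, 9):
            for k in range(1, n + 1):
                for x in xs:
                    assert abs(beta_score(float(x), k, n)
                               - stats.beta.cdf(x, k, n - k + 1)) < 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            beta_score(1.5, 1, 2)
        with pytest.raises(ValueError):
            beta_score(0.5, 3, 2)


class TestRhoScore:
    def test_single_rank(self):
        assert rho_score([0.2]) == pytest.approx(0.2)

    def test_two_ranks_hand_computed(self):
        # min(beta_{1,2}(0.1) = 0.19, beta_{2,2}(0.2) = 0.04)
        assert rho_score([0.1, 0.2]) == pytest.approx(0.04)

    def test_all_ones(self):
        assert rho_score([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_empty_vector_error(self):
        with pytest.raises(ValueError, match="empty"):
            rho_score([])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=6),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, ranks, rnd):
        shuffled = list(ranks)
        rnd.shuffle(shuffled)
        assert rho_score(shuffled) == pytest.approx(rho_score(ranks), rel=1e-12)

    def test_vectorized_path_matches_scalar(self):
        rng = np.random.default_rng(5)
        R = rng.random((50, 4)).clip(1e-9, 1.0)
        vec = _rho_scores(R)
        for i in range(50):
            assert vec[i] == pytest.approx(rho_score(R[i]), rel=1e-10)


class TestExactPvalue:
    def test_reduces_to_identity_for_one_study(self):
        for rho in [0.001, 0.25, 0.7, 1.0]:
            assert exact_pvalue(rho, 1) == pytest.approx(rho)

    def test_upper_bound(self):
        for n in range(1, 6):
            assert exact_pvalue(1.0, n) == pytest.approx(1.0)

    def test_monotone_in_rho_and_bounded_below_by_rho(self):
        for n in (2, 3, 4, 5):
            grid = np.logspace(-6, 0, 40)
            vals = [exact_pvalue(float(r), n) for r in grid]
            assert all(b >= a - 1e-15 for a, b in zip(vals, vals[1:]))
            assert all(v >= r for v, r in zip(vals, grid))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            exact_pvalue(0.0, 3)
        with pytest.raises(ValueError):
            exact_pvalue(1.5, 3)

    def test_agrees_with_monte_carlo_null(self):
        # quick version of the calibration check (bigger run in acceptance)
        rng = np.random.default_rng(17)
        for n in (2, 3):
            rhos = _rho_scores(rng.random((200_000, n)))
            for rho in (0.01, 0.05, 0.2):
                mc = float((rhos <= rho).mean())
                se = math.sqrt(mc * (1 - mc) / len(rhos))
                assert exact_pvalue(rho, n) == pytest.approx(mc, abs=3 * se)

    def test_null_exact_p_uniform(self):
        mat = simulate_null_rank_matrix(m=2000, n=3, seed=21)
        res = aggregate(mat)
        ks = stats.kstest(res.table["exact_p"], "uniform")
        assert ks.pvalue > 0.001


class TestAdjustPvalues:
    def test_bonferroni_multiply_and_cap(self):
        np.testing.assert_allclose(adjust_pvalues([0.001], m=100), [0.1])
        np.testing.assert_allclose(adjust_pvalues([0.5], m=10), [1.0])

    def test_bh_step_up_hand_computed(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04], method="bh"),
            [0.04, 0.04, 0.04, 0.04])

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], method="holm")


class TestAggregate:
    def test_constant_top_gene_closed_form(self):
        m, n = 1000, 4
        universe = [f"g{i:04d}" for i in range(1, m + 1)]
        order = list(universe)
        mat = normalize_ranks({f"s{j}": order for j in range(n)}, universe)
        res = aggregate(mat)
        # gene ranked first everywhere: rho = beta_{4,4}(1/1000) = 1e-12
        top = res.table.index[0]
        assert top == "g0001"
        assert res.table.at[top, "rho"] == pytest.approx(1e-12, rel=1e-6)
        assert res.table.at[top, "adj_p"] < 0.05

    def test_single_study_exact_p_is_the_rank(self):
        universe = ["a", "b", "c", "d"]
        mat = normalize_ranks({"s1": ["c", "a", "d", "b"]}, universe)
        res = aggregate(mat)
        assert res.table.at["c", "exact_p"] == pytest.approx(0.25)
        assert res.table.at["b", "exact_p"] == pytest.approx(1.0)

    def test_null_matrix_familywise_control(self):
        mat = simulate_null_rank_matrix(m=500, n=4, seed=33)
        res = aggregate(mat)
        frac = len(res.robust_genes(0.05)) / 500
        assert frac <= 0.05 * (1 + 3 * math.sqrt(0.95 / (0.05 * 500)))

    def test_adj_p_never_below_exact_p(self):
        mat = simulate_null_rank_matrix(m=300, n=3, seed=4)
        res = aggregate(mat)
        assert (res.table["adj_p"] >= res.table["exact_p"] - 1e-15).all()

    def test_uninformative_extra_study_keeps_top_gene_first(self):
        m = 200
        universe = [f"g{i:03d}" for i in range(1, m + 1)]
        informative = {f"s{j}": list(universe) for j in range(3)}
        res_small = aggregate(normalize_ranks(informative, universe))
        rng = np.random.default_rng(8)
        noise = [universe[i] for i in rng.permutation(m)]
        informative["s_noise"] = noise
        res_big = aggregate(normalize_ranks(informative, universe))
        assert res_small.table.index[0] == "g001"
        assert res_big.table.index[0] == "g001"


class TestRunMeta:
    def test_planted_signal_recovered(self, planted_studies):
        studies, truth = planted_studies
        up, down = run_meta(studies)
        rec_up = set(up.robust_genes()) & set(truth.genes("up"))
        rec_down = set(down.robust_genes()) & set(truth.genes("down"))
        n_planted = len(truth.de_genes)
        assert (len(rec_up) + len(rec_down)) / n_planted >= 0.9

    def test_null_data_yields_no_robust_calls(self, null_studies):
        up, down = run_meta(null_studies)
        assert len(up.robust_genes()) + len(down.robust_genes()) == 0

    def test_label_swap_maps_up_to_down(self, planted_studies):
        studies, _ = planted_studies
        up1, down1 = run_meta(studies)
        swapped = []
        for s in studies:
            flipped = s.groups.map({"case": "control", "control": "case"})
            swapped.append(type(s)(study_id=s.study_id, matrix=s.matrix,
                                   groups=flipped))
        up2, down2 = run_meta(swapped)
        assert set(up1.robust_genes()) == set(down2.robust_genes())
        assert set(down1.robust_genes()) == set(up2.robust_genes())

    def test_requires_two_studies(self, planted_studies):
        with pytest.raises(ValueError, match="at least 2"):
            run_meta(planted_studies[0][:1])
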