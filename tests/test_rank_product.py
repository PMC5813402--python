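import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survrp.rank_product import (
    OutlyingnessMatrix,
    RankMatrix,
    rank_observations,
    rank_product,
    rp_pvalue_bounds,
    rp_pvalue_exact,
    rp_pvalue_gamma,
    rp_pvalue_permutation,
    rp_pvalues,
)
from survrp.synthetic_data import generate_null_ranks


def brute_force_p(rho, n, k):
    """Independent oracle: enumerate all n^k rank tuples."""
    cnt = sum(
        1 for t in itertools.product(range(1, n + 1), repeat=k) if math.prod(t) <= rho
    )
    return cnt / n**k


def om(Z):
    Z = np.asarray(Z, float)
    return OutlyingnessMatrix(Z, [f"s{i}" for i in range(Z.shape[0])],
                              [f"m{j}" for j in range(Z.shape[1])])


class TestRanking:
    def test_ascending_puts_most_negative_first(self):
        R = rank_observations(om([[-3.0], [-1.0], [2.0]]))
        assert R.R[:, 0].tolist() == [1.0, 2.0, 3.0]

    def test_midrank_ties(self):
        R = rank_observations(om([[0.0], [0.0], [1.0]]))
        assert R.R[:, 0].tolist() == [1.5, 1.5, 3.0]

    def test_ordinal_ties_break_by_sample_order(self):
        R = rank_observations(om([[0.0], [0.0], [1.0]]), tie_method="ordinal")
        assert R.R[:, 0].tolist() == [1.0, 2.0, 3.0]

    def test_absolute_direction_ranks_extremes_first(self):
        R = rank_observations(om([[-5.0], [0.1], [4.0]]), direction="absolute")
        assert R.R[:, 0].tolist() == [1.0, 3.0, 2.0]

    def test_rank_products_of_table_like_triples(self):
        # embed the triples (1,11,25) and (5,2,90) as rows of a valid
        # 90-observation rank matrix and check the row products
        n = 90
        cols = []
        for firsts in [(1, 5), (11, 2), (25, 90)]:
            rest = [r for r in range(1, n + 1) if r not in firsts]
            cols.append(list(firsts) + rest)
        R = RankMatrix(np.array(cols, float).T,
                       [f"s{i}" for i in range(n)], ["x", "y", "z"])
        rp, log_rp = rank_product(R)
        assert rp[0] == 275.0 and rp[1] == 900.0
        assert log_rp == pytest.approx(np.log(rp))


class TestExactPValue:
    def test_k1_closed_form(self):
        assert rp_pvalue_exact(3, 10, 1) == pytest.approx(0.3)

    def test_tiny_case_by_hand(self):
        # tuples with product <= 2 out of 3^2: (1,1),(1,2),(2,1)
        assert rp_pvalue_exact(2, 3, 2) == pytest.approx(3 / 9)

    @pytest.mark.parametrize("n,k", [(5, 2), (8, 3), (6, 2), (7, 3), (4, 3)])
    def test_matches_brute_force_everywhere(self, n, k):
        for rho in range(1, n**k + 1):
            assert rp_pvalue_exact(rho, n, k) == pytest.approx(
                brute_force_p(rho, n, k), abs=1e-12
            )

    def test_monotone_in_rho(self):
        ps = [rp_pvalue_exact(r, 517, 3) for r in [1, 10, 275, 900, 10**4, 10**6]]
        assert ps == sorted(ps)

    def test_infeasible_k_directs_elsewhere(self):
        with pytest.raises(ValueError, match="bounds|gamma"):
            rp_pvalue_exact(100, 517, 50)


class TestBoundsGM:
    def test_whole_sample_space_is_one(self):
        lo, hi, gm = rp_pvalue_bounds(5**3, 5, 3)
        assert lo == hi == gm == 1.0

    @pytest.mark.parametrize("n,k", [(5, 2), (5, 3), (20, 2), (20, 3), (20, 4), (517, 2), (517, 3), (517, 4)])
    def test_bounds_bracket_exact_on_grid(self, n, k):
        rhos = np.unique(np.geomspace(1, n**k, 40).astype(np.int64))
        for rho in rhos:
            lo, hi, gm = rp_pvalue_bounds(float(rho), n, k)
            ex = rp_pvalue_exact(float(rho), n, k)
            assert lo <= ex + 1e-12
            assert hi >= ex - 1e-12
            assert lo <= gm <= hi

    def test_small_case_brackets_exact(self):
        lo, hi, _ = rp_pvalue_bounds(2, 3, 2)
        assert lo <= 1 / 3 <= hi

    def test_gm_close_to_exact_for_moderate_k(self):
        # geometric mean of the bounds tracks the exact tail probability
        for rho in (275, 10**4, 10**6):
            _, _, gm = rp_pvalue_bounds(rho, 517, 3)
            ex = rp_pvalue_exact(rho, 517, 3)
            assert gm == pytest.approx(ex, rel=0.10)

    def test_large_k_is_finite_and_monotone(self):
        ps = [rp_pvalue_bounds(rho, 100, 20)[2] for rho in (1e3, 1e10, 1e20, 1e30)]
        assert all(0 < p <= 1 for p in ps)
        assert ps == sorted(ps)


class TestGamma:
    def test_saturated_log_rho_gives_one(self):
        assert rp_pvalue_gamma(3 * math.log(10), 10, 3) == pytest.approx(1.0)

    def test_k1_reduces_to_uniform(self):
        assert rp_pvalue_gamma(math.log(3.0), 10, 1) == pytest.approx(0.3)

    def test_poisson_sum_closed_form(self):
        n, k, rho = 517, 3, 275
        L = k * math.log(n) - math.log(rho)
        expected = math.exp(-L) * (1 + L + L * L / 2)  # independent closed form
        assert rp_pvalue_gamma(math.log(rho), n, k) == pytest.approx(expected, rel=1e-10)
        # the continuous approximation overshoots the discrete tail
        assert expected > rp_pvalue_exact(rho, n, k)

    def test_out_of_range_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert rp_pvalue_gamma(-1.0, 10, 2) <= 1.0

    def test_agreement_with_bounds_gm_outside_the_tail(self):
        for rho in np.geomspace(4e5, 1e8, 25):
            _, _, gm = rp_pvalue_bounds(float(rho), 517, 3)
            if 0.1 < gm < 0.99:
                ga = rp_pvalue_gamma(math.log(rho), 517, 3)
                assert abs(ga - gm) / gm < 0.05


class TestPermutation:
    def test_estimator_bounds_and_determinism(self):
        R = generate_null_ranks(12, 3, seed=4)
        B = 500
        p1 = rp_pvalue_permutation(R, B=B, seed=9)
        p2 = rp_pvalue_permutation(R, B=B, seed=9)
        assert np.array_equal(p1, p2)
        assert np.all(p1 >= 1 / (B + 1)) and np.all(p1 <= 1.0)

    def test_matches_exact_within_monte_carlo_error(self):
        R = generate_null_ranks(6, 2, seed=7)
        B = 20_000
        p_hat = rp_pvalue_permutation(R, B=B, seed=3)
        rp, _ = rank_product(R)
        for i, r in enumerate(rp):
            pe = rp_pvalue_exact(r, 6, 2)
            se = math.sqrt(pe * (1 - pe) / B)
            assert abs(p_hat[i] - pe) <= 3 * se + 1.5 / B

    def test_b_too_small_rejected(self):
        with pytest.raises(ValueError):
            rp_pvalue_permutation(generate_null_ranks(5, 2, 0), B=10)


class TestDispatch:
    def test_auto_uses_exact_for_small_k(self):
        res = rp_pvalues(generate_null_ranks(20, 3, 0), method="auto")
        assert {r.method for r in res} == {"exact"}

    def test_auto_uses_bounds_for_mid_k(self):
        res = rp_pvalues(generate_null_ranks(20, 6, 0), method="auto")
        assert {r.method for r in res} == {"bounds_gm"}
        assert all(r.bounds[0] <= r.p_value <= r.bounds[1] for r in res)

    def test_auto_uses_gamma_for_large_k_and_stays_finite(self):
        res = rp_pvalues(generate_null_ranks(15, 40, 0), method="auto")
        assert {r.method for r in res} == {"gamma"}
        assert all(0 < r.p_value <= 1 for r in res)

    def test_consistent_top_decile_across_100_models_is_significant(self):
        # an observation ranked in the top decile of every one of k=100
        # models has RP p-value far below 1/n (gamma tail)
        n, k = 200, 100
        rng = np.random.default_rng(0)
        log_rp = float(np.log(rng.integers(1, n // 10 + 1, size=k)).sum())
        assert rp_pvalue_gamma(log_rp, n, k) < 1.0 / n

    def test_null_calibration_of_gm_pvalues(self):
        n, k, reps = 200, 3, 2000
        rng = np.random.default_rng(123)
        rp = rng.integers(1, n + 1, size=(reps, k)).prod(axis=1)
        frac = np.mean([rp_pvalue_bounds(float(r), n, k)[2] <= 0.05 for r in rp])
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(frac - 0.05) <= 3 * se


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(2, 30), st.integers(1, 4), st.integers(0, 10**6))
def test_rank_columns_are_valid_permutations_and_pvalues_monotone(n, k, seed):
    R = generate_null_ranks(n, k, seed)
    for j in range(k):
        assert sorted(R.R[:, j]) == list(range(1, n + 1))
    rp, _ = rank_product(R)
    order = np.argsort(rp)
    p = np.array([rp_pvalue_exact(r, n, k) for r in rp])
    assert np.all(np.diff(p[order]) >= -1e-15)
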