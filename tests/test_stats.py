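"""Statistical primitives against hand and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from riptargetkit.stats import (
    bh_adjust,
    ks_one_sided,
    nb_enrichment_test,
    pearson,
    size_factors,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        c = np.tile([[5], [10], [2]], (1, 4))
        assert np.allclose(size_factors(c), 1.0)

    def test_doubled_library_doubles_factor(self):
        # hand oracle on a 2x2 matrix: ratios are constant per sample
        c = np.array([[10, 20], [30, 60]])
        sf = size_factors(c)
        assert np.isclose(sf[1] / sf[0], 2.0)
        assert np.isclose(np.exp(np.mean(np.log(sf))), 1.0)

    def test_single_sample_is_unit(self):
        assert np.allclose(size_factors(np.array([[4], [9]])), 1.0)

    def test_no_common_nonzero_gene_errors(self):
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(np.array([[0, 5], [5, 0]]))


def bh_oracle(p):
    """Definitional BH: adj_i = min over p_(j) >= p_i of min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    stepped = np.minimum(1.0, m * p[order] / np.arange(1, m + 1))
    # running minimum from the right enforces monotonicity
    adj_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBhAdjust:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_equal_values(self):
        assert np.allclose(bh_adjust([0.2]), [0.2])
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3] * 3)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_oracle(p))

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def dplus_oracle(enr, ref):
    """Brute-force sup of ECDF_ref - ECDF_enr over every pooled point."""
    best = 0.0
    for x in list(enr) + list(ref):
        fe = sum(v <= x for v in enr) / len(enr)
        fr = sum(v <= x for v in ref) / len(ref)
        best = max(best, fr - fe)
    return best


class TestKsOneSided:
    def test_identical_samples_null(self):
        r = ks_one_sided([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_full_separation(self):
        r = ks_one_sided([0.3, 0.4], [0.1, 0.2])
        assert r.statistic == 1.0
        # exact path: only 1 of C(4,2)=6 labelings reaches D+ = 1
        assert np.isclose(r.p_value, 1 / 6)

    def test_wrong_direction_gives_zero_statistic(self):
        r = ks_one_sided([0.1, 0.2], [0.5, 0.6])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_statistic_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n, m = rng.integers(1, 12, size=2)
            enr = rng.normal(size=n)
            ref = rng.normal(size=m)
            assert np.isclose(ks_one_sided(enr, ref).statistic, dplus_oracle(enr, ref))

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(9)
        for n, m in [(2, 3), (3, 3), (4, 4), (5, 3)]:
            enr = rng.normal(0.5, 1, n)
            ref = rng.normal(0, 1, m)
            r = ks_one_sided(enr, ref)
            pooled = np.concatenate([enr, ref])
            hits = total = 0
            for pick in itertools.combinations(range(n + m), n):
                mask = np.zeros(n + m, bool)
                mask[list(pick)] = True
                total += 1
                if dplus_oracle(pooled[mask], pooled[~mask]) >= r.statistic - 1e-12:
                    hits += 1
            assert np.isclose(r.p_value, hits / total)

    def test_exact_and_asymptotic_agree_moderately(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            enr = rng.normal(0.4, 1, 8)
            ref = rng.normal(0, 1, 8)
            exact = ks_one_sided(enr, ref)
            d = exact.statistic
            asym = min(1.0, math.exp(-2 * d * d * 64 / 16))
            assert abs(exact.p_value - asym) < 0.05

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            ks_one_sided([], [1.0])


class TestWilcoxon:
    def test_rank_sum_exact_enumeration_example(self):
        r = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert np.isclose(r.p_value, 0.1)  # 2 of 20 labelings as extreme

    def test_rank_sum_identical_samples(self):
        r = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value >= 0.99

    def test_rank_sum_monotone_in_shift(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        ps = [wilcoxon_rank_sum(x + shift, y).p_value for shift in (0.0, 0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_rank_sum_exact_matches_full_enumeration(self):
        # every partition of a 4+3 pooled sample, against the exact path
        rng = np.random.default_rng(8)
        pooled = rng.normal(size=7)
        ranks = pooled.argsort().argsort() + 1
        dist = [ranks[list(c)].sum() for c in itertools.combinations(range(7), 4)]
        for pick in itertools.combinations(range(7), 4):
            x = pooled[list(pick)]
            y = np.delete(pooled, list(pick))
            r = wilcoxon_rank_sum(x, y, alternative="greater")
            wx = ranks[list(pick)].sum()
            assert np.isclose(r.p_value, sum(w >= wx for w in dist) / len(dist))

    def test_signed_rank_exact_sign_pattern_enumeration(self):
        r = wilcoxon_signed_rank([1, 2, 3], 0.0, alternative="greater")
        assert np.isclose(r.p_value, 0.125)  # 1 of 2^3 sign patterns

    def test_signed_rank_symmetric_statistic(self):
        # pairwise-cancelling ranks: T+ = n(n+1)/4
        x = [-4, -3, -2, -1, 1, 2, 3, 4]
        r = wilcoxon_signed_rank(x, 0.0, alternative="greater")
        assert r.statistic == 8 * 9 / 4

    def test_signed_rank_location_equivariance(self):
        x = np.array([0.3, 1.2, 2.7, 3.1, 4.9])
        r1 = wilcoxon_signed_rank(x, 1.0)
        r2 = wilcoxon_signed_rank(x + 5.0, 6.0)
        assert r1.statistic == r2.statistic and np.isclose(r1.p_value, r2.p_value)

    def test_signed_rank_all_zero_differences(self):
        r = wilcoxon_signed_rank([2.0, 2.0], 2.0)
        assert r.p_value == 1.0


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.isclose(pearson(x, 2 * x + 1), 1.0)
        assert np.isclose(pearson(x, -x), -1.0)

    def test_hand_computed_value(self):
        assert np.isclose(pearson([1, 2, 3], [1, 3, 2]), 0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 2, 3], [5, 5, 5])


class TestNbEnrichment:
    def test_identical_groups_are_null(self):
        r = nb_enrichment_test([10, 12, 9], [10, 12, 9], dispersion=0.1)
        assert abs(r.statistic) < 1e-9 and r.p_value > 0.999

    def test_p_monotone_in_effect_size(self):
        bg = [5, 6, 5]
        ps = [
            nb_enrichment_test([int(5 * f)] * 3, bg, dispersion=1e-6).p_value
            for f in (1, 2, 4, 8, 16)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-6

    def test_all_zero_gene_flagged_untestable(self):
        r = nb_enrichment_test([0, 0, 0], [0, 0, 0], dispersion=0.1)
        assert r.p_value == 1.0 and r.statistic == 0.0
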