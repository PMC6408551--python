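import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from chromx.genodata import MISSING
from chromx.ld import (
    HaplotypeSet,
    em_haplotype_freqs,
    haplotype_assoc_test,
    ld_from_freqs,
    multiallelic_dprime,
    pairwise_ld,
    solid_spine_blocks,
    tag_snps,
)


def two_snp_likelihood_oracle(calls, is_male):
    """Direct maximum-likelihood haplotype frequencies for 2 SNPs, found with a
    general-purpose optimizer over the 4-frequency simplex (independent of the
    EM path)."""
    pair_sets = {}
    for g1 in (0, 1, 2):
        for g2 in (0, 1, 2):
            opts1 = [(0, 0)] if g1 == 0 else [(1, 1)] if g1 == 2 else [(0, 1), (1, 0)]
            opts2 = [(0, 0)] if g2 == 0 else [(1, 1)] if g2 == 2 else [(0, 1), (1, 0)]
            pairs = []
            for a in opts1:
                for b in opts2:
                    pairs.append((2 * a[0] + b[0], 2 * a[1] + b[1]))
            pair_sets[(g1, g2)] = pairs

    def negll(theta):
        f = np.exp(theta - theta.max())
        f = f / f.sum()
        ll = 0.0
        for row, male in zip(calls, is_male):
            g = tuple(int(x) for x in row)
            if male:
                ll += np.log(f[2 * g[0] + g[1]])
            else:
                ll += np.log(sum(f[h1] * f[h2] for h1, h2 in pair_sets[g]))
        return -ll

    best = None
    for s in range(5):
        rng = np.random.default_rng(s)
        res = minimize(negll, rng.normal(0, 0.5, 4), method="Nelder-Mead",
                       options=dict(maxiter=5000, xatol=1e-10, fatol=1e-12))
        if best is None or res.fun < best.fun:
            best = res
    f = np.exp(best.x - best.x.max())
    return f / f.sum()


class TestEMHaplotypes:
    def test_single_snp_equals_allele_frequency(self, rng):
        calls = np.array([0, 1, 2, 1, 0, 1, 1, 0], dtype=np.int8)[:, None]
        is_male = np.array([False] * 6 + [True] * 2)
        hs = em_haplotype_freqs(calls, is_male)
        # X-aware: females 2 alleles each, males 1
        num = calls[:6].sum() + calls[6:].sum()
        den = 12 + 2
        assert hs.freqs[1] == pytest.approx(num / den, abs=1e-9)
        assert hs.freqs.sum() == pytest.approx(1.0)

    def test_males_only_equals_direct_counting(self, rng):
        calls = rng.integers(0, 2, size=(30, 3)).astype(np.int8)
        is_male = np.ones(30, bool)
        hs = em_haplotype_freqs(calls, is_male)
        for h, hap in enumerate(hs.haplotypes):
            count = sum(1 for row in calls if tuple(row) == hap)
            assert hs.freqs[h] == pytest.approx(count / 30, abs=1e-9)

    def test_two_snp_matches_optimizer_oracle(self, rng):
        # 20 females incl. double heterozygotes (phase-ambiguous)
        calls = np.array(
            [[1, 1]] * 6 + [[2, 1]] * 3 + [[1, 0]] * 3 + [[0, 0]] * 4 + [[2, 2]] * 4,
            dtype=np.int8,
        )
        is_male = np.zeros(len(calls), bool)
        hs = em_haplotype_freqs(calls, is_male, tol=1e-12)
        want = two_snp_likelihood_oracle(calls, is_male)
        np.testing.assert_allclose(hs.freqs, want, atol=1e-4)

    def test_loglik_nondecreasing_in_iterations(self, rng):
        calls = rng.integers(0, 3, size=(40, 3)).astype(np.int8)
        is_male = np.zeros(40, bool)
        lls = [
            em_haplotype_freqs(calls, is_male, tol=0, max_iter=k).loglik
            for k in range(1, 12)
        ]
        assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))

    def test_female_dosages_sum_to_two_males_to_one(self, rng):
        calls = rng.integers(0, 2, size=(20, 2)).astype(np.int8)
        calls[:10] += rng.integers(0, 2, size=(10, 2)).astype(np.int8)
        is_male = np.array([False] * 10 + [True] * 10)
        calls[5, 0] = MISSING  # missing handled by summation
        hs = em_haplotype_freqs(calls, is_male)
        sums = hs.dosages.sum(axis=1)
        np.testing.assert_allclose(sums[:10], 2.0, atol=1e-9)
        np.testing.assert_allclose(sums[10:], 1.0, atol=1e-9)

    def test_enumeration_bound(self):
        with pytest.raises(ValueError, match="enumeration"):
            em_haplotype_freqs(np.zeros((2, 13), np.int8), np.zeros(2, bool))


class TestPairwiseLD:
    def test_independence(self):
        ld = ld_from_freqs(p_ab=0.12, p_a=0.4, p_b=0.3)
        assert ld.Dprime == pytest.approx(0.0)
        assert ld.r2 == pytest.approx(0.0)

    def test_perfect_ld_equal_freqs(self):
        ld = ld_from_freqs(p_ab=0.3, p_a=0.3, p_b=0.3)
        assert ld.Dprime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        ld = ld_from_freqs(p_ab=0.2, p_a=0.4, p_b=0.3)
        assert ld.D == pytest.approx(0.08)
        assert ld.Dprime == pytest.approx(0.08 / 0.18)
        assert ld.r2 == pytest.approx(0.0064 / (0.24 * 0.21))

    def test_monomorphic_flagged(self):
        ld = ld_from_freqs(p_ab=0.0, p_a=0.0, p_b=0.3)
        assert not ld.defined

    def test_r2_one_implies_dprime_one(self, rng):
        for _ in range(200):
            p_a, p_b = rng.uniform(0.05, 0.95, 2)
            lo, hi = max(0, p_a + p_b - 1), min(p_a, p_b)
            p_ab = rng.uniform(lo, hi)
            ld = ld_from_freqs(p_ab, p_a, p_b)
            assert -1e-12 <= ld.Dprime <= 1 + 1e-12
            assert -1e-12 <= ld.r2 <= 1 + 1e-12
            assert ld.r2 <= ld.Dprime**2 + 1e-9  # r2 cannot exceed D'^2
            if ld.r2 > 1 - 1e-9:
                assert ld.Dprime == pytest.approx(1.0)

    def test_from_em_on_phased_males(self):
        # 10 males: 4x hap 11, 3x hap 00, 2x hap 10, 1x hap 01
        calls = np.array([[1, 1]] * 4 + [[0, 0]] * 3 + [[1, 0]] * 2 + [[0, 1]],
                         dtype=np.int8)
        hs = em_haplotype_freqs(calls, np.ones(10, bool))
        ld = pairwise_ld(hs)
        assert ld.D == pytest.approx(0.4 - 0.6 * 0.5)


def spine_oracle(dp, thr):
    """Left-to-right maximal valid blocks, re-derived independently."""
    m = len(dp)
    blocks, i = [], 0
    while i < m:
        valid_js = [
            j
            for j in range(i + 1, m)
            if dp[i][j] >= thr
            and all(dp[i][k] >= thr and dp[k][j] >= thr for k in range(i + 1, j))
        ]
        if valid_js:
            j = max(valid_js)
            blocks.append(tuple(range(i, j + 1)))
            i = j + 1
        else:
            i += 1
    return blocks


class TestSolidSpine:
    def test_block_diagonal_partition(self):
        dp = np.zeros((7, 7))
        dp[np.ix_(range(3), range(3))] = 1.0
        dp[np.ix_(range(3, 7), range(3, 7))] = 1.0
        blocks = solid_spine_blocks(dp)
        assert [b.members for b in blocks] == [(0, 1, 2), (3, 4, 5, 6)]

    def test_no_ld_no_blocks(self):
        assert solid_spine_blocks(np.eye(5)) == []

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(150):
            m = int(rng.integers(2, 9))
            dp = np.round(rng.random((m, m)), 2)
            dp = np.maximum(dp, dp.T)
            np.fill_diagonal(dp, 1.0)
            got = [b.members for b in solid_spine_blocks(dp, 0.8)]
            assert got == spine_oracle(dp.tolist(), 0.8)

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError):
            solid_spine_blocks(np.zeros((2, 3)))


def _hapset_2blocks(joint_freqs):
    """Joint 2-SNP HaplotypeSet (one SNP per block) with given frequencies."""
    return HaplotypeSet(
        variant_ids=("a", "b"),
        haplotypes=((0, 0), (0, 1), (1, 0), (1, 1)),
        freqs=np.asarray(joint_freqs, float),
        dosages=np.zeros((1, 4)),
        is_male=np.zeros(1, bool),
        loglik=0.0,
        n_iter=0,
    )


class TestMultiallelicDprime:
    def test_independent_blocks(self):
        hs = _hapset_2blocks([0.36, 0.24, 0.24, 0.16])  # product of .6/.4 margins
        assert multiallelic_dprime(hs, k_a=1) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_correspondence(self):
        hs = _hapset_2blocks([0.6, 0.0, 0.0, 0.4])
        assert multiallelic_dprime(hs, k_a=1) == pytest.approx(1.0)

    def test_hand_case(self):
        # p00=.5 p01=.1 p10=.1 p11=.3 -> every component D' = .14/.24
        hs = _hapset_2blocks([0.5, 0.1, 0.1, 0.3])
        assert multiallelic_dprime(hs, k_a=1) == pytest.approx(0.14 / 0.24)

    def test_degenerate_flagged(self):
        hs = _hapset_2blocks([0.7, 0.3, 0.0, 0.0])  # block A monomorphic
        assert np.isnan(multiallelic_dprime(hs, k_a=1))


def min_cover_oracle(capt):
    """Smallest set of rows covering all columns, by exhaustive search."""
    m = len(capt)
    for size in range(1, m + 1):
        for combo in itertools.combinations(range(m), size):
            covered = set()
            for t in combo:
                covered |= set(np.nonzero(capt[t])[0])
            if len(covered) == m:
                return size
    return m


class TestTagSnps:
    def test_independent_snps_both_tags(self):
        tags, assign = tag_snps(np.eye(2))
        assert sorted(tags) == [0, 1]
        assert assign == {0: 0, 1: 1}

    def test_tight_block_single_tag(self):
        r2 = np.full((4, 4), 0.85)
        np.fill_diagonal(r2, 1.0)
        tags, assign = tag_snps(r2)
        assert len(tags) == 1
        assert set(assign) == {0, 1, 2, 3}

    def test_tie_breaks_to_lower_position(self):
        r2 = np.full((3, 3), 0.9)
        np.fill_diagonal(r2, 1.0)
        tags, _ = tag_snps(r2, positions=[300, 100, 200])
        assert tags == [1]

    def test_greedy_close_to_exhaustive_minimum(self, rng):
        for _ in range(60):
            m = int(rng.integers(2, 9))
            r2 = rng.random((m, m))
            r2 = (r2 + r2.T) / 2
            np.fill_diagonal(r2, 1.0)
            tags, assign = tag_snps(r2)
            assert set(assign) == set(range(m))  # covers all SNPs
            capt = (r2 >= 0.8)
            np.fill_diagonal(capt, True)
            assert len(tags) <= min_cover_oracle(capt) + 1


class TestHaplotypeAssoc:
    def test_single_snp_block_equals_single_snp_regression(self, rng):
        from chromx.assoc import linear_assoc

        n = 200
        is_male = np.array([False] * 120 + [True] * 80)
        calls = np.where(is_male, rng.binomial(1, 0.3, n), rng.binomial(2, 0.3, n))
        y = 0.4 * calls + rng.standard_normal(n)
        hs = em_haplotype_freqs(calls.astype(np.int8)[:, None], is_male)
        hres = haplotype_assoc_test(y, hs)
        sres = linear_assoc(y, calls.astype(float))
        assert hres.omnibus_p == pytest.approx(sres.p, rel=1e-8)

    def test_planted_haplotype_effect_recovered(self, rng):
        pool = np.array([[1, 1], [0, 0], [1, 0]], dtype=np.int8)
        freqs = np.array([0.35, 0.5, 0.15])
        hits = 0
        n_sims = 25
        for _ in range(n_sims):
            n_f, n_m = 250, 200
            idx = rng.choice(3, size=2 * n_f + n_m, p=freqs)
            bits = pool[idx]
            calls = np.vstack(
                [bits[: 2 * n_f].reshape(n_f, 2, 2).sum(axis=1), bits[2 * n_f:]]
            ).astype(np.int8)
            is_male = np.array([False] * n_f + [True] * n_m)
            target = (idx == 0).astype(float)  # dose of haplotype 11 per chromosome
            dose = np.concatenate(
                [target[: 2 * n_f].reshape(n_f, 2).sum(axis=1), target[2 * n_f:]]
            )
            y = 0.5 * dose + rng.standard_normal(n_f + n_m)
            hs = em_haplotype_freqs(calls, is_male)
            res = haplotype_assoc_test(y, hs)
            row = res.per_haplotype.set_index("haplotype").loc["11"]
            se = (row["ci_high"] - row["ci_low"]) / (2 * 1.96)
            hits += abs(row["beta"] - 0.5) <= 2 * se
        assert hits >= int(0.85 * n_sims)

    def test_one_haplotype_after_pooling_flagged(self):
        hs = _hapset_2blocks([1.0, 0.0, 0.0, 0.0])
        hs.dosages = np.full((5, 4), 0.0)
        hs.dosages[:, 0] = 2.0
        with pytest.raises(ValueError, match="pooling"):
            haplotype_assoc_test(np.zeros(5), hs)
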