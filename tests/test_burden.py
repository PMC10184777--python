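import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleopop import (
    SyntheticCohortConfig,
    burden_profile,
    compare_groups,
    find_population_unique,
    rarity_check,
    simulate_cohort,
)
from paleopop.burden import BurdenRecord, rank_sum_test
from paleopop.io import MISSING, RepresentativeSet

from conftest import make_matrix, make_samples


def brute_force_unique(calls, focal_row):
    """Set-comprehension oracle: focal carries, nobody else does."""
    n_sites = calls.shape[1]
    return {
        j for j in range(n_sites)
        if calls[focal_row, j] in (1, 2)
        and all(calls[i, j] not in (1, 2)
                for i in range(calls.shape[0]) if i != focal_row)
    }


def reps_for(geno):
    return RepresentativeSet({f"p{i}": s for i, s in enumerate(geno.sample_ids)})


class TestFindPopulationUnique:
    def test_single_carrier_definition(self):
        g = make_matrix([[1], [0], [0]])
        reps = reps_for(g)
        assert list(find_population_unique(g, reps, "s0")) == [0]
        assert list(find_population_unique(g, reps, "s1")) == []

    def test_shared_site_is_unique_to_nobody(self):
        g = make_matrix([[2], [1], [0]])
        reps = reps_for(g)
        for s in g.sample_ids:
            assert len(find_population_unique(g, reps, s)) == 0

    def test_focal_missing_excluded(self):
        g = make_matrix([[MISSING], [0], [0]])
        assert len(find_population_unique(g, reps_for(g), "s0")) == 0

    def test_other_missing_counts_as_noncarrier(self):
        g = make_matrix([[2], [MISSING], [0]])
        assert list(find_population_unique(g, reps_for(g), "s0")) == [0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n_reps = int(rng.integers(3, 12))
            n_sites = int(rng.integers(5, 120))
            calls = rng.choice([0, 1, 2, MISSING], size=(n_reps, n_sites),
                               p=[0.5, 0.2, 0.2, 0.1]).astype(np.int8)
            g = make_matrix(calls)
            reps = reps_for(g)
            for i, s in enumerate(g.sample_ids):
                got = set(find_population_unique(g, reps, s))
                assert got == brute_force_unique(calls, i)

    def test_each_site_unique_to_at_most_one_rep(self):
        rng = np.random.default_rng(13)
        calls = rng.choice([0, 1, 2], size=(8, 200)).astype(np.int8)
        g = make_matrix(calls)
        reps = reps_for(g)
        all_sites = [j for s in g.sample_ids
                     for j in find_population_unique(g, reps, s)]
        assert len(all_sites) == len(set(all_sites))

    def test_removing_a_representative_grows_unique_sets(self):
        rng = np.random.default_rng(14)
        calls = rng.choice([0, 1, 2], size=(6, 300)).astype(np.int8)
        g = make_matrix(calls)
        full = reps_for(g)
        reduced = RepresentativeSet({p: s for p, s in full if s != "s5"})
        for s in list(reduced.samples):
            before = set(find_population_unique(g, full, s))
            after = set(find_population_unique(g, reduced, s))
            assert before.issubset(after)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(15)
        calls = rng.choice([0, 1, 2], size=(5, 100)).astype(np.int8)
        g = make_matrix(calls)
        perm = rng.permutation(5)
        g2 = make_matrix(calls[perm], sample_ids=[f"s{i}" for i in perm])
        for s in g.sample_ids:
            assert np.array_equal(find_population_unique(g, reps_for(g), s),
                                  find_population_unique(g2, reps_for(g), s))


class TestBurdenProfile:
    def test_counts_and_percentages(self):
        flags = pd.DataFrame({
            "constrained": [True, True] + [False] * 8,
            "missense": [True, False, True, True] + [False] * 6})
        samples = make_samples({"s0": "p0"})
        rec = burden_profile("s0", samples, np.arange(10), flags)
        assert (rec.n_unique, rec.n_unique_constrained, rec.n_unique_missense) == (10, 2, 3)
        assert rec.pct_constrained == 0.2
        assert rec.pct_missense == 0.3

    def test_empty_unique_set_gives_zero_percentages(self):
        samples = make_samples({"s0": "p0"})
        rec = burden_profile("s0", samples, np.array([], dtype=int),
                             pd.DataFrame({"constrained": [], "missense": []}))
        assert rec.pct_constrained == 0.0 and rec.pct_missense == 0.0


class TestCompareGroups:
    def records(self, va, vb):
        recs = []
        for i, v in enumerate(va):
            recs.append(BurdenRecord(f"a{i}", f"a{i}", "working", 100, int(100 * v), 0))
        for i, v in enumerate(vb):
            recs.append(BurdenRecord(f"b{i}", f"b{i}", "breed", 100, int(100 * v), 0))
        return recs

    def test_identical_groups_p_one(self):
        recs = self.records([0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
        c = compare_groups(recs, "working", "breed")
        assert c.p_value == 1.0

    def test_exact_p_matches_permutation_enumeration(self):
        va, vb = [0.01, 0.02, 0.03], [0.04, 0.05, 0.06]
        c = compare_groups(self.records(va, vb), "working", "breed")
        # enumerate all 20 assignments of the 6 values into groups of 3
        pooled = va + vb
        obs = sum(r < v for r in va for v in vb)  # U of group A
        us = []
        for combo in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            us.append(sum(x < y for x in ga for y in gb))
        us = np.array(us)
        p_exact = np.mean(np.minimum(
            (us <= min(obs, 9 - obs)).mean() + (us >= max(obs, 9 - obs)).mean(), 1.0))
        assert c.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_welch_t_variant(self):
        recs = self.records([0.1, 0.2, 0.3], [0.4, 0.5, 0.9])
        c = compare_groups(recs, "working", "breed", test="t")
        ref = stats.ttest_ind([0.1, 0.2, 0.3], [0.4, 0.5, 0.9], equal_var=False)
        assert c.statistic == pytest.approx(ref.statistic)
        assert c.p_value == pytest.approx(ref.pvalue)

    def test_small_group_rejected(self):
        recs = self.records([0.1], [0.2, 0.3])
        with pytest.raises(ValueError, match=">=2"):
            compare_groups(recs, "working", "breed")

    def test_rank_sum_null_uniform(self):
        """Type-I calibration: p-values ~ U(0,1) for same-distribution samples."""
        rng = np.random.default_rng(21)
        ps = [rank_sum_test(rng.normal(size=40), rng.normal(size=40))[1]
              for _ in range(500)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestRarityCheck:
    def cohort(self, seed=0):
        cfg = SyntheticCohortConfig(
            n_populations=5, samples_per_population=8, n_sites=4000,
            chrom_lengths={"chr1": 10_000_000}, private_allele_freq=0.05,
            ancestral_freq_dist=(1.0, 1.0), seed=seed)
        return simulate_cohort(cfg)

    def test_planted_private_variants_detected_as_rare(self):
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            geno, _, samples, truth = self.cohort(seed)
            rep = "pop1_s1"
            focal = np.flatnonzero((truth.site_class == "private")
                                   & (truth.site_owner == "pop1"))
            res = rarity_check(geno, samples, rep, focal, seed=seed)
            assert res.computable
            hits += res.p_value < 0.01
        assert hits >= int(0.9 * n_rep)

    def test_single_member_population_not_computable(self):
        g = make_matrix([[1, 0], [0, 1]])
        samples = make_samples({"s0": "p0", "s1": "p1"})
        res = rarity_check(g, samples, "s0", np.array([0]))
        assert not res.computable

    def test_empty_focal_set_not_computable(self):
        g = make_matrix([[1, 0], [0, 1], [1, 1]],
                        sample_ids=["s0", "s1", "s2"])
        samples = make_samples({"s0": "p0", "s1": "p0", "s2": "p0"})
        res = rarity_check(g, samples, "s0", np.array([], dtype=int))
        assert not res.computable
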