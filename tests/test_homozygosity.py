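import numpy as np
import pytest
from scipy import stats

from paleopop import (
    RohParams,
    SyntheticCohortConfig,
    correlate_f,
    detect_roh,
    f_mom,
    f_roh,
    simulate_cohort,
)
from paleopop.homozygosity import InbreedingResult, assayed_length, pearson_t
from paleopop.io import MISSING

from conftest import make_matrix

RELAXED = RohParams(window_snps=5, window_max_het=1, window_max_missing=2,
                    hit_threshold=0.05, min_segment_snps=5, min_segment_kb=10,
                    min_density_kb_per_snp=50, max_gap_kb=100)


def roh_oracle(pos, calls, p: RohParams):
    """Straightforward re-implementation of the windowed caller contract."""
    L = len(pos)
    W = p.window_snps
    if L < W:
        return []
    hom_windows = []
    for i in range(L - W + 1):
        win = calls[i:i + W]
        n_het = int(np.sum(win == 1))
        n_miss = int(np.sum(win == MISSING))
        hom_windows.append(n_het <= p.window_max_het and n_miss <= p.window_max_missing)
    eligible = []
    for t in range(L):
        containing = [i for i in range(L - W + 1) if i <= t <= i + W - 1]
        rate = sum(hom_windows[i] for i in containing) / len(containing)
        eligible.append(rate >= p.hit_threshold)
    # maximal eligible runs, split at large gaps, then filtered
    segments = []
    run = []
    for t in range(L + 1):
        if t < L and eligible[t]:
            if run and pos[t] - pos[run[-1]] > p.max_gap_kb * 1000:
                segments.append(run)
                run = []
            run.append(t)
        else:
            if run:
                segments.append(run)
            run = []
    out = []
    for seg in segments:
        n_snps = len(seg)
        length = pos[seg[-1]] - pos[seg[0]] + 1
        if n_snps < p.min_segment_snps:
            continue
        if length < p.min_segment_kb * 1000:
            continue
        if length / 1000 / n_snps > p.min_density_kb_per_snp:
            continue
        out.append((int(pos[seg[0]]), int(pos[seg[-1]]), n_snps))
    return out


class TestDetectRoh:
    def test_all_het_no_segments(self):
        g = make_matrix(np.ones((1, 300), dtype=np.int8), spacing=5000)
        assert detect_roh(g, "s0", RELAXED) == []

    def test_saturated_homozygous_chromosome_single_segment(self):
        n = 5000
        g = make_matrix(np.zeros((1, n), dtype=np.int8), spacing=2000)  # 10 Mb span
        segs = detect_roh(g, "s0")  # strict defaults
        assert len(segs) == 1
        assert segs[0].start_bp == 2000
        assert segs[0].end_bp == n * 2000
        assert segs[0].n_snps == n

    def test_chromosome_shorter_than_window(self):
        g = make_matrix(np.zeros((1, 3), dtype=np.int8))
        assert detect_roh(g, "s0", RELAXED) == []

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(55)
        for _ in range(100):
            n = int(rng.integers(10, 500))
            calls = rng.choice([0, 1, 2, MISSING], size=(1, n),
                               p=[0.45, 0.1, 0.4, 0.05]).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=n, replace=False))
            g = make_matrix(calls)
            g.sites["pos"] = pos
            segs = detect_roh(g, "s0", RELAXED)
            got = [(s.start_bp, s.end_bp, s.n_snps) for s in segs]
            assert got == roh_oracle(pos, calls[0], RELAXED)

    def test_segments_sorted_and_disjoint(self):
        rng = np.random.default_rng(56)
        calls = rng.choice([0, 1, 2], size=(1, 800), p=[0.48, 0.04, 0.48]).astype(np.int8)
        g = make_matrix(calls, spacing=3000)
        segs = detect_roh(g, "s0", RELAXED)
        for a, b in zip(segs, segs[1:]):
            assert a.end_bp < b.start_bp


class TestFRoh:
    def test_no_segments_zero(self):
        assert f_roh([], 1_000_000) == 0.0

    def test_full_coverage_one(self):
        from paleopop import RohSegment
        seg = RohSegment("s", "chr1", 1, 1_000_000, 500, 0)
        assert f_roh([seg], 1_000_000) == 1.0

    def test_zero_assayed_length_rejected(self):
        with pytest.raises(ValueError):
            f_roh([], 0)


class TestFMoM:
    def test_hardy_weinberg_mean_near_zero(self):
        cfg = SyntheticCohortConfig(
            n_populations=1, samples_per_population=30, n_sites=50_000,
            chrom_lengths={"chr1": 100_000_000}, divergence_F=0.0,
            inbreeding_f=0.0, private_site_fraction=0.0,
            derived_site_fraction=0.0, seed=60)
        geno, *_ = simulate_cohort(cfg)
        fs = [f_mom(geno, s) for s in geno.sample_ids]
        assert abs(np.mean(fs)) < 0.01

    def test_planted_inbreeding_recovered(self):
        cfg = SyntheticCohortConfig(
            n_populations=1, samples_per_population=30, n_sites=50_000,
            chrom_lengths={"chr1": 100_000_000}, divergence_F=0.0,
            inbreeding_f=0.3, private_site_fraction=0.0,
            derived_site_fraction=0.0, seed=61)
        geno, *_ = simulate_cohort(cfg)
        fs = [f_mom(geno, s) for s in geno.sample_ids]
        assert abs(np.mean(fs) - 0.3) < 0.03

    def test_fully_homozygous_sample_approaches_one(self):
        rng = np.random.default_rng(62)
        others = rng.choice([0, 1, 2], size=(40, 2000), p=[0.25, 0.5, 0.25])
        focal = rng.choice([0, 2], size=(1, 2000))
        g = make_matrix(np.vstack([focal, others]).astype(np.int8))
        assert f_mom(g, "s0") > 0.9

    def test_single_sample_cohort_rejected(self):
        g = make_matrix([[0, 1, 2]])
        with pytest.raises(ValueError, match=">=2 samples"):
            f_mom(g, "s0")


class TestCorrelateF:
    def test_perfect_linear_r_one(self):
        res = [InbreedingResult(f"s{i}", 0.1 * i, 0.2 * i + 0.05) for i in range(5)]
        r, t, df, p = correlate_f(res)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_t_statistic_formula(self):
        # internal consistency of t = r*sqrt(df/(1-r^2)) at r=0.6752819, n=86
        t, df, p = pearson_t(0.6752819, 86)
        assert df == 84
        assert t == pytest.approx(8.3913, abs=5e-4)
        assert p == pytest.approx(9.958e-13, rel=5e-3)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(63)
        ps = []
        for _ in range(500):
            res = [InbreedingResult(f"s{i}", x, y)
                   for i, (x, y) in enumerate(zip(rng.normal(size=20),
                                                  rng.normal(size=20)))]
            ps.append(correlate_f(res)[3])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        res = [InbreedingResult(f"s{i}", 0.5, float(i)) for i in range(5)]
        with pytest.raises(ValueError, match="variance"):
            correlate_f(res)

    def test_too_few_samples_rejected(self):
        res = [InbreedingResult("a", 0.1, 0.2), InbreedingResult("b", 0.2, 0.1)]
        with pytest.raises(ValueError, match=">=3"):
            correlate_f(res)


def test_froh_and_fmom_positively_correlated_across_inbreeding_levels():
    """Cohorts spanning f in [0, 0.4] give correlated F_RoH and F_MoM."""
    results = []
    for i, f in enumerate(np.linspace(0.0, 0.4, 5)):
        n_planted = int(round(f * 25))  # plant f as 2Mb tracts on a 50Mb chromosome
        roh = [("pop1_s1", "chr1", 1 + 2_000_000 * (2 * k), 2_000_000 * (2 * k + 1))
               for k in range(n_planted)]
        cfg = SyntheticCohortConfig(
            n_populations=1, samples_per_population=10, n_sites=20_000,
            chrom_lengths={"chr1": 50_000_000}, divergence_F=0.0,
            inbreeding_f=f / 2, planted_roh=roh, private_site_fraction=0.0,
            derived_site_fraction=0.0, seed=70 + i)
        geno, *_ = simulate_cohort(cfg)
        segs = detect_roh(geno, "pop1_s1")
        results.append(InbreedingResult(
            f"lvl{i}", f_roh(segs, assayed_length(geno)), f_mom(geno, "pop1_s1")))
    froh = [r.f_roh for r in results]
    fmom = [r.f_mom for r in results]
    assert np.corrcoef(froh, fmom)[0, 1] > 0.5
    assert all(a <= b + 0.02 for a, b in zip(froh, froh[1:]))  # monotone in planting
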