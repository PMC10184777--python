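"""Runs of homozygosity and inbreeding coefficients.

RoH are called with the classic sliding-window scheme: a fixed-size window
of consecutive SNPs is scored homozygous when it contains at most
``window_max_het`` heterozygous and ``window_max_missing`` missing calls;
each SNP's hit rate is the fraction of windows containing it that are
homozygous, and maximal runs of SNPs whose hit rate reaches
``hit_threshold`` become segments subject to minimum-SNP, minimum-length,
density and maximum-gap filters.  Parameter defaults mirror the
widely-used window-based caller's documented defaults, since they are the
de-facto convention.

Two inbreeding coefficients:

* ``F_RoH`` — fraction of the assayed genome covered by RoH segments;
* ``F_MoM`` — method-of-moments excess homozygosity
  ``(O_hom - E_hom) / (L - E_hom)`` with the small-sample correction
  ``n/(n-1)`` on expected heterozygosity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("paleopop")


@dataclass
class RohParams:
    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    hit_threshold: float = 0.05
    min_segment_snps: int = 100
    min_segment_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0

    def __post_init__(self):
        for name in ("window_snps", "window_max_het", "window_max_missing",
                     "min_segment_snps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        if not (0 < self.hit_threshold <= 1):
            raise ValueError("hit_threshold must be in (0,1]")


@dataclass
class RohSegment:
    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class InbreedingResult:
    sample: str
    f_roh: float
    f_mom: float


def detect_roh(geno: GenotypeMatrix, sample: str,
               params: RohParams = None) -> list[RohSegment]:
    """Call RoH segments for one sample, per chromosome."""
    params = params or RohParams()
    calls = geno.row(sample)
    segments: list[RohSegment] = []
    for chrom, idx in geno.sites.groupby("chrom", sort=False).indices.items():
        pos = geno.sites["pos"].to_numpy()[idx]
        c = calls[idx]
        segments.extend(_detect_roh_chrom(sample, str(chrom), pos, c, params))
    segments.sort(key=lambda s: (s.chrom, s.start_bp))
    return segments


def _detect_roh_chrom(sample, chrom, pos, calls, p: RohParams) -> list[RohSegment]:
    L = len(pos)
    W = p.window_snps
    if L < W:
        logger.info("%s %s: %d sites < window of %d; no RoH windows", sample, chrom, L, W)
        return []
    het = (calls == 1).astype(np.int64)
    miss = (calls == MISSING).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmiss = np.concatenate([[0], np.cumsum(miss)])
    n_win = L - W + 1
    starts = np.arange(n_win)
    win_het = chet[starts + W] - chet[starts]
    win_miss = cmiss[starts + W] - cmiss[starts]
    hom_win = ((win_het <= p.window_max_het)
               & (win_miss <= p.window_max_missing)).astype(np.int64)
    chom = np.concatenate([[0], np.cumsum(hom_win)])
    t = np.arange(L)
    lo = np.maximum(0, t - W + 1)
    hi = np.minimum(t, n_win - 1)
    n_containing = hi - lo + 1
    n_hom = chom[hi + 1] - chom[lo]
    eligible = (n_hom / n_containing) >= p.hit_threshold

    segments = []
    for run in _runs(eligible):
        # split a run at gaps exceeding max_gap_kb
        for s, e in _split_at_gaps(pos, run, p.max_gap_kb * 1000):
            n_snps = e - s + 1
            length = int(pos[e] - pos[s] + 1)
            if n_snps < p.min_segment_snps:
                continue
            if length < p.min_segment_kb * 1000:
                continue
            if length / 1000.0 / n_snps > p.min_density_kb_per_snp:
                continue
            segments.append(RohSegment(sample, chrom, int(pos[s]), int(pos[e]),
                                       n_snps, int(het[s:e + 1].sum())))
    return segments


def _runs(mask):
    """Maximal runs of True as (start_idx, end_idx) inclusive."""
    out = []
    i, L = 0, len(mask)
    while i < L:
        if mask[i]:
            j = i
            while j + 1 < L and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def _split_at_gaps(pos, run, max_gap_bp):
    s, e = run
    pieces, start = [], s
    for i in range(s, e):
        if pos[i + 1] - pos[i] > max_gap_bp:
            pieces.append((start, i))
            start = i + 1
    pieces.append((start, e))
    return pieces


def assayed_length(geno: GenotypeMatrix) -> int:
    """First-to-last-site span per chromosome, summed."""
    total = 0
    for _, pos in geno.sites.groupby("chrom", sort=False)["pos"]:
        total += int(pos.iloc[-1] - pos.iloc[0] + 1)
    return total


def f_roh(segments: list[RohSegment], assayed_length_bp: int) -> float:
    """Fraction of the assayed genome inside RoH segments."""
    if assayed_length_bp <= 0:
        raise ValueError("assayed length must be > 0")
    total = sum(s.length_bp for s in segments)
    f = total / assayed_length_bp
    if f > 1:
        logger.warning("F_RoH %.3f > 1; clipped", f)
        f = 1.0
    return f


def f_mom(geno: GenotypeMatrix, sample: str) -> float:
    """Method-of-moments inbreeding coefficient against cohort frequencies.

    Over the sample's non-missing calls at cohort-polymorphic sites:
    ``F = (O_hom - E_hom) / (L - E_hom)`` where
    ``E_hom = sum_l [1 - 2 p_l (1-p_l) n_l/(n_l-1)]``, ``p_l`` the cohort
    ALT frequency and ``n_l`` the number of non-missing alleles at site l.
    """
    if geno.n_samples < 2:
        raise ValueError("need >=2 samples for cohort allele frequencies")
    calls = geno.row(sample)
    ok = calls != MISSING
    n_alleles = 2 * (geno.calls != MISSING).sum(axis=0)
    alt = np.where(geno.calls != MISSING, geno.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / n_alleles, np.nan)
    poly = ok & (n_alleles >= 2) & (p > 0) & (p < 1)
    L = int(poly.sum())
    if L == 0:
        raise ValueError(f"no usable polymorphic sites for {sample}")
    pl = p[poly]
    nl = n_alleles[poly]
    e_hom = np.sum(1.0 - 2.0 * pl * (1.0 - pl) * nl / (nl - 1.0))
    o_hom = int(((calls == 0) | (calls == 2))[poly].sum())
    denom = L - e_hom
    if denom == 0:
        raise ZeroDivisionError("L - E_hom = 0; F_MoM undefined")
    return float((o_hom - e_hom) / denom)


def pearson_t(r: float, n: int) -> tuple[float, int, float]:
    """t statistic, degrees of freedom and two-sided p for a Pearson r at size n."""
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def correlate_f(results: list[InbreedingResult]) -> tuple[float, float, int, float]:
    """Pearson correlation between F_RoH and F_MoM over samples.

    Returns (r, t, df, p) with t = r*sqrt(df/(1-r^2)), df = n-2 and a
    two-sided p from the t distribution.
    """
    if len(results) < 3:
        raise ValueError("need >=3 samples to correlate")
    x = np.array([r.f_roh for r in results])
    y = np.array([r.f_mom for r in results])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inbreeding metrics")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, np.inf if r > 0 else -np.inf, len(results) - 2, 0.0
    t, df, p = pearson_t(r, len(results))
    return r, t, df, p


def inbreeding_table(geno: GenotypeMatrix, params: RohParams = None,
                     drop_missing_samples: bool = True,
                     assayed_bp: int | None = None) -> list[InbreedingResult]:
    """F_RoH and F_MoM for every sample.

    By default samples with any missing genotype are dropped before RoH
    calling (matching the convention of pruning to complete cases for the
    homozygosity analysis); pass ``drop_missing_samples=False`` to keep them.
    """
    assayed = assayed_bp if assayed_bp is not None else assayed_length(geno)
    results = []
    for s in geno.sample_ids:
        if drop_missing_samples and (geno.row(s) == MISSING).any():
            logger.info("%s dropped from homozygosity analysis (missing calls)", s)
            continue
        segs = detect_roh(geno, s, params)
        results.append(InbreedingResult(s, f_roh(segs, assayed), f_mom(geno, s)))
    return results


def segments_to_bed(segments: list[RohSegment], path) -> None:
    """Export segments as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t{s.sample}\t"
                     f"{s.n_snps}\t{s.n_het}\n")
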