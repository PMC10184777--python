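"""Population-unique ("rare") variant burden per representative, and group tests.

A variant is population-unique to a representative when that dog carries the
ALT allele once or twice and *no other representative* carries it at all.
The burden profile of a representative is the fraction of its unique
variants that are evolutionarily constrained, and the fraction that are
missense; groups of representatives (e.g. working sled dogs vs modern
breeds) are compared on those fractions with a two-sided Wilcoxon rank-sum
test (default) or a Welch t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix, RepresentativeSet, SampleTable

logger = logging.getLogger("paleopop")


@dataclass
class BurdenRecord:
    sample: str
    population: str
    group: str
    n_unique: int
    n_unique_constrained: int
    n_unique_missense: int

    @property
    def pct_constrained(self) -> float:
        return self.n_unique_constrained / self.n_unique if self.n_unique else 0.0

    @property
    def pct_missense(self) -> float:
        return self.n_unique_missense / self.n_unique if self.n_unique else 0.0


@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    test: str
    n_a: int
    n_b: int


@dataclass
class FrequencySummary:
    """Within-population allele frequencies of a focal site set vs random sites."""

    computable: bool
    focal_freqs: np.ndarray | None = None
    random_freqs: np.ndarray | None = None
    statistic: float | None = None
    p_value: float | None = None
    alternative: str | None = None


def find_population_unique(geno: GenotypeMatrix, reps: RepresentativeSet,
                           sample: str) -> np.ndarray:
    """Indices of sites unique to ``sample`` among the representatives.

    The focal representative must carry >=1 ALT allele; every other
    representative must carry 0.  A missing call in another representative
    counts as non-carrier (logged); sites where the focal call is missing
    are excluded.
    """
    if sample not in reps.samples:
        raise ValueError(f"{sample!r} is not a representative")
    focal = geno.row(sample)
    others = [s for s in reps.samples if s != sample]
    other_calls = geno.calls[[geno.sample_index(s) for s in others]]
    carrier = (other_calls == 1) | (other_calls == 2)
    unique = ((focal == 1) | (focal == 2)) & ~carrier.any(axis=0)
    n_masked_missing = int(((other_calls == MISSING).any(axis=0) & unique).sum())
    if n_masked_missing:
        logger.info("%s: %d unique sites have missing calls in other representatives "
                    "(treated as non-carrier)", sample, n_masked_missing)
    return np.flatnonzero(unique)


def burden_profile(sample: str, samples: SampleTable, unique_sites: np.ndarray,
                   flags: pd.DataFrame) -> BurdenRecord:
    """Count constrained / missense variants among a representative's unique set.

    ``flags`` is the per-site frame from :func:`paleopop.constraint.classify_sites`
    aligned to the genotype matrix; the two flags are independent, so a
    variant can count in both categories.
    """
    n = len(unique_sites)
    if n == 0:
        logger.warning("%s has no population-unique variants", sample)
        return BurdenRecord(sample, samples.population_of(sample),
                            samples.group_of(sample), 0, 0, 0)
    sub = flags.iloc[unique_sites]
    return BurdenRecord(
        sample=sample,
        population=samples.population_of(sample),
        group=samples.group_of(sample),
        n_unique=n,
        n_unique_constrained=int(sub["constrained"].sum()),
        n_unique_missense=int(sub["missense"].sum()),
    )


def records_to_frame(records: list[BurdenRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample": r.sample, "population": r.population, "group": r.group,
        "n_unique": r.n_unique,
        "n_unique_constrained": r.n_unique_constrained,
        "n_unique_missense": r.n_unique_missense,
        "pct_constrained": r.pct_constrained,
        "pct_missense": r.pct_missense,
    } for r in records])


def rank_sum_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum via the Mann-Whitney U statistic.

    Exact null when the combined sample size is <= 20 and there are no
    ties; otherwise the normal approximation with continuity correction and
    mid-rank tie handling.  Fully tied data gives p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 20 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative=alternative,
                                 method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(records: list[BurdenRecord], group_a: str, group_b: str,
                   metric: str = "pct_constrained",
                   test: str = "wilcoxon") -> GroupComparison:
    """Two-sided comparison of a burden metric between two groups."""
    if metric not in ("pct_constrained", "pct_missense"):
        raise ValueError(f"unknown metric {metric!r}")
    va = [getattr(r, metric) for r in records if r.group == group_a]
    vb = [getattr(r, metric) for r in records if r.group == group_b]
    if len(va) < 2 or len(vb) < 2:
        raise ValueError(f"both groups need >=2 records (got {len(va)}, {len(vb)})")
    if test == "wilcoxon":
        stat, p = rank_sum_test(va, vb)
    elif test == "t":
        res = stats.ttest_ind(va, vb, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}; use 'wilcoxon' or 't'")
    return GroupComparison(metric, group_a, group_b, stat, p, test, len(va), len(vb))


def rarity_check(geno: GenotypeMatrix, samples: SampleTable, sample: str,
                 focal_sites: np.ndarray, seed: int = 0,
                 alternative: str = "less") -> FrequencySummary:
    """Are a representative's focal variants uncommon within its own population?

    Compares the within-population ALT frequencies of the focal sites to an
    equal-size random draw of sites segregating in that population (ALT
    observed at least once), with a one-sided rank-sum test (default
    alternative "less": focal frequencies are lower).  Restricting the
    random pool to segregating sites keeps the comparison fair: sites the
    population does not carry at all would otherwise dominate the draw.
    Requires at least two genotyped samples in the population.
    """
    pop = samples.population_of(sample)
    members = [m for m in samples.members(pop) if m in geno.sample_ids]
    if len(members) < 2:
        logger.warning("population %s has <2 genotyped samples; frequency check "
                       "not computable", pop)
        return FrequencySummary(computable=False)
    if len(focal_sites) == 0:
        return FrequencySummary(computable=False)
    freqs = geno.alt_freq(sample_subset=members)
    pool = np.flatnonzero(np.nan_to_num(freqs) > 0)
    if len(pool) == 0:
        return FrequencySummary(computable=False)
    rng = np.random.default_rng(seed)
    rand_idx = rng.choice(pool, size=len(focal_sites),
                          replace=len(pool) < len(focal_sites))
    focal = freqs[focal_sites]
    rand = freqs[rand_idx]
    focal = focal[~np.isnan(focal)]
    rand = rand[~np.isnan(rand)]
    if len(focal) == 0 or len(rand) == 0:
        return FrequencySummary(computable=False)
    stat, p = rank_sum_test(focal, rand, alternative=alternative)
    return FrequencySummary(True, focal, rand, stat, p, alternative)
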