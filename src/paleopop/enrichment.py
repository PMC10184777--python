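"""Homozygous-derived variants, functional filtering, and gene-set enrichment.

A homozygous-derived variant for a representative is a site where the dog
is homozygous ALT (call 2) and no outgroup sample (wolves) carries the ALT
allele.  Filtering to variants that are both highly constrained (FDR 0.01)
and missense gives a set of putatively functional variants, collapsed to
the genes they hit; hypergeometric upper-tail enrichment against a
GMT-style gene-set collection with per-sample Benjamini–Hochberg
correction, plus a pooled ranking of all (sample, set) pairs by raw p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .burden import FrequencySummary, rarity_check
from .io import MISSING, GenotypeMatrix, SampleTable

logger = logging.getLogger("paleopop")


@dataclass
class DerivedVariantSet:
    sample: str
    sites: np.ndarray           # indices of homozygous-derived sites
    functional_sites: np.ndarray  # subset: constrained (FDR 0.01) and missense
    genes_hit: frozenset

    @property
    def n_total(self) -> int:
        return len(self.sites)

    @property
    def n_functional(self) -> int:
        return len(self.functional_sites)


def find_homozygous_derived(geno: GenotypeMatrix, sample: str,
                            outgroup_samples: list[str]) -> np.ndarray:
    """Sites with call 2 in ``sample`` and zero ALT alleles in every outgroup.

    Missing outgroup calls are treated as non-carrier (logged).
    """
    if not outgroup_samples:
        raise ValueError("outgroup is empty")
    focal = geno.row(sample)
    out_calls = geno.calls[[geno.sample_index(s) for s in outgroup_samples]]
    carrier = (out_calls == 1) | (out_calls == 2)
    derived = (focal == 2) & ~carrier.any(axis=0)
    n_missing = int(((out_calls == MISSING).any(axis=0) & derived).sum())
    if n_missing:
        logger.info("%s: %d derived sites have missing outgroup calls "
                    "(treated as non-carrier)", sample, n_missing)
    return np.flatnonzero(derived)


def derived_variant_set(geno: GenotypeMatrix, sample: str,
                        outgroup_samples: list[str],
                        flags: pd.DataFrame, ann: pd.DataFrame) -> DerivedVariantSet:
    """Collapse a representative's functional homozygous-derived variants to genes.

    ``flags`` must be classified at the strict (FDR 0.01) cutoff;
    functional means constrained AND missense.  A gene counts once however
    many qualifying variants it carries.
    """
    sites = find_homozygous_derived(geno, sample, outgroup_samples)
    if len(sites) == 0:
        return DerivedVariantSet(sample, sites, sites, frozenset())
    sub = flags.iloc[sites]
    functional = sites[(sub["constrained"] & sub["missense"]).to_numpy()]
    genes = ann["gene"].iloc[functional]
    genes_hit = frozenset(g for g in genes if g is not None and pd.notna(g))
    return DerivedVariantSet(sample, sites, functional, genes_hit)


def commonness_check(geno: GenotypeMatrix, samples: SampleTable, sample: str,
                     derived_sites: np.ndarray, seed: int = 0) -> FrequencySummary:
    """Are homozygous-derived variants *common* in the dog's own population?

    Mirror of the rarity check with the opposite one-sided alternative.
    """
    return rarity_check(geno, samples, sample, derived_sites, seed=seed,
                        alternative="greater")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, frozenset]:
    """GMT format: one set per line — id, description, member genes."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(gene_sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for sid in gene_sets:
            desc = (descriptions or {}).get(sid, "na")
            fh.write("\t".join([sid, desc] + sorted(gene_sets[sid])) + "\n")


def enrich(genes_hit, gene_sets: dict, universe, sample: str = "sample",
           ) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of ``genes_hit`` in each set.

    For each set: k = hits in set, n = total hits, K = set size within the
    universe, N = universe size; p = P(X >= k) for X hypergeometric(N, K, n),
    fold = (k/n)/(K/N).  q is Benjamini–Hochberg across all sets for this
    sample.  Hits outside the universe are logged and dropped; sets are
    intersected with the universe.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    genes_hit = frozenset(genes_hit)
    outside = genes_hit - universe
    if outside:
        logger.warning("%d hit genes outside universe dropped: %s",
                       len(outside), sorted(outside)[:5])
    hits = genes_hit & universe
    N, n = len(universe), len(hits)
    set_ids = sorted(gene_sets)
    K = np.array([len(frozenset(gene_sets[s]) & universe) for s in set_ids])
    k = np.array([len(hits & frozenset(gene_sets[s])) for s in set_ids])
    p = stats.hypergeom.sf(k - 1, N, K, n)
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where((n > 0) & (K > 0), (k / max(n, 1)) / np.where(K > 0, K / N, 1.0), 0.0)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    out = pd.DataFrame({
        "sample": sample, "gene_set": set_ids, "k": k, "n": n, "K": K, "N": N,
        "fold": fold, "p": p, "q": np.maximum(q, p)})
    return out.sort_values(["p", "gene_set"], kind="mergesort").reset_index(drop=True)


def global_rank(results: pd.DataFrame) -> pd.DataFrame:
    """Pool all (sample, set) pairs and rank by p ascending, ties by ids.

    Adds ``global_rank`` (1-based) and ``n_pairs``; the pool size is
    samples x sets tested.
    """
    if results.empty:
        raise ValueError("no enrichment results to rank")
    pooled = results.sort_values(["p", "sample", "gene_set"],
                                 kind="mergesort").reset_index(drop=True)
    pooled["global_rank"] = np.arange(1, len(pooled) + 1)
    pooled["n_pairs"] = len(pooled)
    return pooled
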