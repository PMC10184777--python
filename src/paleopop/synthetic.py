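"""Synthetic multi-population cohorts with known ground truth.

The generator emulates the statistical structure of a breed-structured canid
cohort sampled one-representative-per-population: ancestral allele
frequencies drift into per-population frequencies under the Balding–Nichols
model, genotypes are drawn with an excess-homozygosity parameter f,
autozygous tracts can be planted explicitly, and per-site constraint scores
follow a neutral/constrained mixture in which a neutral score is
``-log10(U)`` for U uniform on (0,1) — i.e. the score is the -log10 p-value
of a neutrality test.

Three site classes give downstream analyses a recoverable signal:

* **shared** sites segregate in every population (Balding–Nichols drift);
* **private** sites have a low allele frequency in exactly one population
  and zero elsewhere — these are the ground truth for population-unique
  ("rare") variant discovery, and each is "deleterious" (constrained score
  plus missense consequence) with probability
  ``base_deleterious_rate * burden_shift[group]``;
* **derived** sites have a high frequency in exactly one non-wolf
  population and zero elsewhere (in particular zero in every wolf-group
  population) — the ground truth for homozygous-derived discovery, marked
  functional (highly constrained + missense) at ``derived_functional_rate``.

Everything is driven by a single integer seed; the same seed reproduces the
emitted VCF and tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    GROUPS,
    MISSING,
    GenotypeMatrix,
    SampleTable,
    SiteAnnotation,
    write_annotation,
    write_sample_table,
    write_vcf,
)


@dataclass
class SyntheticCohortConfig:
    """All distributions, effect sizes and seeds the generator uses.

    Defaults describe a 57-population cohort (one representative each) with
    moderate breed-level differentiation (F = 0.2) and mild inbreeding.
    """

    n_populations: int = 57
    samples_per_population: int = 1
    n_sites: int = 20_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 25_000_000 for i in range(1, 5)})
    ancestral_freq_dist: tuple[float, float] = (0.5, 0.5)  # Beta(a, b)
    divergence_F: float | dict[str, float] = 0.2
    inbreeding_f: float | dict[str, float] = 0.1
    planted_roh: list[tuple[str, str, int, int]] = field(default_factory=list)
    constrained_fraction: float = 0.03
    constrained_score_dist: dict = field(
        default_factory=lambda: {"kind": "shifted_neutral", "shift": 4.0})
    neutral_score_dist: dict = field(default_factory=lambda: {"kind": "neutral"})
    missense_fraction: float = 0.1
    genes_per_chrom: int = 50
    group_labels: dict[str, str] = field(default_factory=dict)
    burden_shift: dict[str, float] = field(default_factory=dict)
    depth_mean: float = 30.0
    missing_rate: float = 0.0
    # site-class structure
    private_site_fraction: float = 0.5
    private_allele_freq: float = 0.05
    base_deleterious_rate: float = 0.2
    derived_site_fraction: float = 0.1
    derived_allele_freq: float = 0.8
    derived_functional_rate: float = 0.15
    # optional enrichment plant: {"population": str, "n_genes": int, "multiplier": float}
    enrichment_plant: dict | None = None
    seed: int = 0

    def population_names(self) -> list[str]:
        width = len(str(self.n_populations))
        return [f"pop{i + 1:0{width}d}" for i in range(self.n_populations)]

    def group_of(self, population: str) -> str:
        return self.group_labels.get(population, "breed")

    def divergence_of(self, population: str) -> float:
        if isinstance(self.divergence_F, dict):
            return self.divergence_F.get(population, 0.0)
        return self.divergence_F

    def inbreeding_of(self, population: str) -> float:
        if isinstance(self.inbreeding_f, dict):
            return self.inbreeding_f.get(population, 0.0)
        return self.inbreeding_f

    def validate(self) -> None:
        if self.n_populations < 1 or self.samples_per_population < 1:
            raise ValueError("need at least one population and one sample")
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        for c, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chrom_lengths[{c!r}] must be > 0")
        for pop in self.population_names():
            F = self.divergence_of(pop)
            if not (0.0 <= F < 1.0):
                raise ValueError(f"divergence_F for {pop} must be in [0,1), got {F}")
            f = self.inbreeding_of(pop)
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"inbreeding_f for {pop} must be in [0,1], got {f}")
        for prop_name in ("constrained_fraction", "missense_fraction", "missing_rate",
                          "private_site_fraction", "private_allele_freq",
                          "derived_site_fraction", "derived_allele_freq",
                          "derived_functional_rate", "base_deleterious_rate"):
            v = getattr(self, prop_name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{prop_name} must be in [0,1], got {v}")
        if self.private_site_fraction + self.derived_site_fraction > 1.0:
            raise ValueError("private + derived site fractions exceed 1")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        for g in set(self.group_labels.values()):
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
        seen: dict[str, list[tuple[int, int]]] = {}
        for sample, chrom, start, end in self.planted_roh:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"planted RoH on unknown chromosome {chrom!r}")
            if not (1 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(
                    f"planted RoH {sample}:{chrom}:{start}-{end} outside chromosome bounds")
            for s0, e0 in seen.setdefault(f"{sample}|{chrom}", []):
                if start <= e0 and s0 <= end:
                    raise ValueError(f"overlapping planted RoH for sample {sample}")
            seen[f"{sample}|{chrom}"].append((start, end))


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    true_site_freqs: np.ndarray        # populations x sites
    population_names: list[str]
    true_constrained_mask: np.ndarray  # per-site bool (score drawn constrained)
    true_roh: list[tuple[str, str, int, int]]
    true_f: dict[str, float]
    true_cn: dict[str, float]
    site_class: np.ndarray             # per-site: 'shared' | 'private' | 'derived'
    site_owner: np.ndarray             # owning population for private/derived, '' else
    deleterious_mask: np.ndarray       # private-deleterious sites
    functional_mask: np.ndarray        # derived functional sites

    def to_json(self, path) -> None:
        out = {
            "population_names": self.population_names,
            "true_site_freqs": np.round(self.true_site_freqs, 6).tolist(),
            "true_constrained_mask": self.true_constrained_mask.astype(int).tolist(),
            "true_roh": [list(t) for t in self.true_roh],
            "true_f": self.true_f,
            "true_cn": self.true_cn,
            "site_class": self.site_class.tolist(),
            "site_owner": self.site_owner.tolist(),
            "deleterious_mask": self.deleterious_mask.astype(int).tolist(),
            "functional_mask": self.functional_mask.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(out, fh)


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions on a chromosome of given length."""
    if n > length:
        raise ValueError("more sites than base pairs")
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 8))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    keep = np.sort(rng.choice(len(pos), size=n, replace=False))
    return pos[keep]


def _draw_scores(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    kind = dist.get("kind", "neutral")
    if kind == "neutral":
        return -np.log10(rng.uniform(size=n))
    if kind == "shifted_neutral":
        return dist.get("shift", 4.0) - np.log10(rng.uniform(size=n))
    if kind == "normal":
        return rng.normal(dist.get("mean", 4.0), dist.get("sd", 1.0), size=n)
    raise ValueError(f"unknown score distribution kind {kind!r}")


def _gene_tiling(chrom_lengths: dict[str, int], genes_per_chrom: int) -> pd.DataFrame:
    rows = []
    for chrom, length in chrom_lengths.items():
        bounds = np.linspace(0, length, genes_per_chrom + 1).astype(np.int64)
        for g in range(genes_per_chrom):
            rows.append((chrom, int(bounds[g]), int(bounds[g + 1]),
                         f"{chrom.upper()}G{g + 1:03d}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def simulate_cohort(config: SyntheticCohortConfig
                    ) -> tuple[GenotypeMatrix, SiteAnnotation, SampleTable, GroundTruth]:
    """Draw one synthetic cohort; fully deterministic under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pops = config.population_names()
    n_pops, n_sites = config.n_populations, config.n_sites

    # --- site coordinates -------------------------------------------------
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    per_chrom = np.floor(n_sites * lengths / lengths.sum()).astype(int)
    per_chrom[: n_sites - per_chrom.sum()] += 1
    site_chrom, site_pos = [], []
    for c, k in zip(chroms, per_chrom):
        p = _draw_positions(rng, config.chrom_lengths[c], int(k))
        site_chrom.extend([c] * int(k))
        site_pos.append(p)
    site_chrom = np.array(site_chrom, dtype=object)
    site_pos = np.concatenate(site_pos) if site_pos else np.array([], dtype=np.int64)

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=n_sites)]
    alt_shift = rng.integers(1, 4, size=n_sites)
    alt = bases[(np.searchsorted(bases, ref) + alt_shift) % 4]

    # --- gene assignment --------------------------------------------------
    genes = _gene_tiling(config.chrom_lengths, config.genes_per_chrom)
    site_gene = np.empty(n_sites, dtype=object)
    for c in chroms:
        m = site_chrom == c
        gsub = genes[genes["chrom"] == c].reset_index(drop=True)
        idx = np.searchsorted(gsub["end"].to_numpy(), site_pos[m] - 1, side="right")
        idx = np.clip(idx, 0, len(gsub) - 1)
        site_gene[m] = gsub["gene"].to_numpy()[idx]

    # --- site classes -----------------------------------------------------
    site_class = np.full(n_sites, "shared", dtype=object)
    site_owner = np.full(n_sites, "", dtype=object)
    n_private = int(round(config.private_site_fraction * n_sites))
    n_derived = int(round(config.derived_site_fraction * n_sites))
    perm = rng.permutation(n_sites)
    private_idx = perm[:n_private]
    derived_idx = perm[n_private:n_private + n_derived]
    site_class[private_idx] = "private"
    site_class[derived_idx] = "derived"

    site_owner[private_idx] = np.array(pops, dtype=object)[
        np.arange(n_private) % n_pops] if n_private else site_owner[private_idx]
    nonwolf = [p for p in pops if config.group_of(p) != "wolf"] or pops

    # derived-site ownership, optionally biased into designated genes
    plant = config.enrichment_plant
    planted_genes: list[str] = []
    if n_derived:
        derived_owner = np.array(nonwolf, dtype=object)[np.arange(n_derived) % len(nonwolf)]
        rng.shuffle(derived_owner)
        site_owner[derived_idx] = derived_owner

    functional_mask = np.zeros(n_sites, dtype=bool)
    if n_derived:
        functional_mask[derived_idx] = rng.uniform(size=n_derived) < config.derived_functional_rate

    if plant is not None and n_derived:
        focal = plant["population"]
        mult = float(plant.get("multiplier", 3.0))
        if "genes" in plant:
            planted_genes = list(plant["genes"])
        else:
            planted_genes = list(genes["gene"].iloc[: int(plant.get("n_genes", 10))])
        pg = set(planted_genes)
        focal_fn = derived_idx[(site_owner[derived_idx] == focal) & functional_mask[derived_idx]]
        pool = derived_idx[site_owner[derived_idx] != focal]
        in_gene_pool = [i for i in pool if site_gene[i] in pg]
        baseline = np.mean([site_gene[i] in pg for i in derived_idx]) if len(derived_idx) else 0.0
        p_in = min(1.0, mult * baseline)
        # swap focal functional sites into designated genes at mult x baseline rate
        for i in list(focal_fn):
            want_in = rng.uniform() < p_in
            is_in = site_gene[i] in pg
            if want_in != is_in:
                cand = in_gene_pool if want_in else [j for j in pool if site_gene[j] not in pg]
                if not cand:
                    continue
                j = cand[int(rng.integers(len(cand)))]
                site_owner[i], site_owner[j] = site_owner[j], site_owner[i]
                fi, fj = functional_mask[i], functional_mask[j]
                functional_mask[i], functional_mask[j] = fj, fi
                pool = derived_idx[site_owner[derived_idx] != focal]
                in_gene_pool = [x for x in pool if site_gene[x] in pg]

    # --- per-population allele frequencies (Balding–Nichols) --------------
    a, b = config.ancestral_freq_dist
    p_anc = rng.beta(a, b, size=n_sites)
    Q = np.empty((n_pops, n_sites))
    for j, pop in enumerate(pops):
        F = config.divergence_of(pop)
        if F == 0.0:
            Q[j] = p_anc
        else:
            alpha = p_anc * (1 - F) / F
            beta = (1 - p_anc) * (1 - F) / F
            Q[j] = rng.beta(np.clip(alpha, 1e-12, None), np.clip(beta, 1e-12, None))
    Q[:, private_idx] = 0.0
    Q[:, derived_idx] = 0.0
    for i in private_idx:
        Q[pops.index(site_owner[i]), i] = config.private_allele_freq
    for i in derived_idx:
        Q[pops.index(site_owner[i]), i] = config.derived_allele_freq

    # --- genotypes --------------------------------------------------------
    sample_rows = []
    calls = np.empty((n_pops * config.samples_per_population, n_sites), dtype=np.int8)
    true_f: dict[str, float] = {}
    k = 0
    for j, pop in enumerate(pops):
        f = config.inbreeding_of(pop)
        q = Q[j]
        p_hom_alt = q * q + f * q * (1 - q)
        p_het = 2 * q * (1 - q) * (1 - f)
        for s in range(config.samples_per_population):
            name = f"{pop}_s{s + 1}"
            u = rng.uniform(size=n_sites)
            g = np.zeros(n_sites, dtype=np.int8)
            g[u < p_hom_alt] = 2
            g[(u >= p_hom_alt) & (u < p_hom_alt + p_het)] = 1
            calls[k] = g
            sample_rows.append((name, pop, config.group_of(pop)))
            true_f[name] = f
            k += 1
    sample_ids = [r[0] for r in sample_rows]

    # --- planted autozygous tracts ----------------------------------------
    for sample, chrom, start, end in config.planted_roh:
        if sample not in sample_ids:
            raise ValueError(f"planted RoH names unknown sample {sample!r}")
        si = sample_ids.index(sample)
        pop_j = pops.index(sample_rows[si][1])
        m = (site_chrom == chrom) & (site_pos >= start) & (site_pos <= end)
        hom_alt = rng.uniform(size=int(m.sum())) < Q[pop_j, m]
        calls[si, m] = np.where(hom_alt, 2, 0).astype(np.int8)

    if config.missing_rate > 0:
        miss = rng.uniform(size=calls.shape) < config.missing_rate
        calls[miss] = MISSING

    # --- constraint scores and consequences --------------------------------
    deleterious_mask = np.zeros(n_sites, dtype=bool)
    if n_private:
        shift_rate = np.array([
            min(1.0, config.base_deleterious_rate
                * config.burden_shift.get(config.group_of(site_owner[i]), 1.0))
            for i in private_idx])
        deleterious_mask[private_idx] = rng.uniform(size=n_private) < shift_rate

    constrained_mask = np.zeros(n_sites, dtype=bool)
    shared_mask = site_class == "shared"
    constrained_mask[shared_mask] = (
        rng.uniform(size=int(shared_mask.sum())) < config.constrained_fraction)
    constrained_mask |= deleterious_mask | functional_mask

    scores = _draw_scores(rng, config.neutral_score_dist, n_sites)
    n_con = int(constrained_mask.sum())
    if n_con:
        scores[constrained_mask] = _draw_scores(rng, config.constrained_score_dist, n_con)

    consequence = np.where(rng.uniform(size=n_sites) < 0.5, "synonymous", "other").astype(object)
    base_missense = rng.uniform(size=n_sites) < config.missense_fraction
    consequence[base_missense] = "missense"
    consequence[deleterious_mask | functional_mask] = "missense"

    # --- assemble ----------------------------------------------------------
    order = np.lexsort((site_pos, np.array([chroms.index(c) for c in site_chrom])))
    sites = pd.DataFrame({
        "chrom": site_chrom[order], "pos": site_pos[order],
        "ref": ref[order], "alt": alt[order]})
    geno = GenotypeMatrix(sample_ids, sites, calls[:, order])
    ann = SiteAnnotation(pd.DataFrame({
        "chrom": site_chrom[order], "pos": site_pos[order],
        "ref": ref[order], "alt": alt[order],
        "gene": site_gene[order], "consequence": consequence[order],
        "phylop": np.round(scores[order], 6)}))
    samples = SampleTable(pd.DataFrame(sample_rows, columns=["sample", "population", "group"]))
    truth = GroundTruth(
        true_site_freqs=Q[:, order], population_names=pops,
        true_constrained_mask=constrained_mask[order],
        true_roh=list(config.planted_roh), true_f=true_f, true_cn={},
        site_class=site_class[order], site_owner=site_owner[order],
        deleterious_mask=deleterious_mask[order], functional_mask=functional_mask[order])
    return geno, ann, samples, truth


def simulate_depth(regions: pd.DataFrame, true_cn: dict[str, float],
                   depth_mean: float, seed: int) -> pd.DataFrame:
    """Poisson read counts per region: counts ~ Poisson(depth_mean * len * cn/2).

    ``regions`` needs columns region_id, chrom, start, end (0-based half-open)
    and optionally role; regions absent from ``true_cn`` are diploid (cn=2).
    """
    if depth_mean < 0:
        raise ValueError("depth_mean must be >= 0")
    lengths = (regions["end"] - regions["start"]).to_numpy()
    if (lengths <= 0).any():
        raise ValueError("regions must have positive length")
    starts = regions.sort_values(["chrom", "start"])
    prev_end = None
    for _, r in starts.iterrows():
        if prev_end is not None and r["chrom"] == prev_chrom and r["start"] < prev_end:
            raise ValueError("regions overlap")
        prev_end, prev_chrom = r["end"], r["chrom"]
    rng = np.random.default_rng(seed)
    cn = regions["region_id"].map(lambda r: true_cn.get(r, 2.0)).to_numpy(dtype=float)
    lam = depth_mean * lengths * cn / 2.0
    out = regions.copy()
    out["n_reads"] = rng.poisson(lam)
    if "role" not in out.columns:
        out["role"] = "background"
    return out


def write_cohort_bundle(out_dir, geno: GenotypeMatrix, ann: SiteAnnotation,
                        samples: SampleTable, truth: GroundTruth) -> dict[str, str]:
    """Write VCF + annotation + sample table + ground-truth JSON to a directory."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "annotation": os.path.join(out_dir, "annotation.tsv"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "truth": os.path.join(out_dir, "ground_truth.json"),
    }
    write_vcf(geno, paths["vcf"])
    write_annotation(ann, paths["annotation"])
    write_sample_table(samples, paths["samples"])
    truth.to_json(paths["truth"])
    return paths


def config_from_yaml(path) -> SyntheticCohortConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SyntheticCohortConfig)}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    if "planted_roh" in raw:
        raw["planted_roh"] = [tuple(x) for x in raw["planted_roh"]]
    if "ancestral_freq_dist" in raw:
        raw["ancestral_freq_dist"] = tuple(raw["ancestral_freq_dist"])
    return SyntheticCohortConfig(**raw)
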