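# Methods

## The study design this package serves

All analyses assume a cohort where each population contributes a single
representative genome — the design forced on studies that compare one
historic/ancient individual against many modern populations. With one
diploid genome per population, classical frequency-based statistics are
unavailable at the population level; the package therefore works with
presence/absence contrasts across representatives (population-unique and
homozygous-derived variants), within-individual statistics (runs of
homozygosity, method-of-moments inbreeding), and group-level comparisons
across representatives.

## Variant discovery definitions

**Population-unique ("rare") variant** for representative *i*: the ALT
allele is carried by *i* (dosage 1 or 2) and by no other representative
(dosage 0). Missing calls in other representatives count as non-carrier —
treating them as carriers would silently delete variants; the per-sample
count of affected sites is logged so the effect is visible. Sites where the
focal representative is missing are excluded. Each site is unique to at
most one representative, and removing a representative can only grow the
others' unique sets.

**Homozygous-derived variant**: dosage 2 in the representative and dosage 0
in every outgroup (wolf) sample, with the same missing-call convention.

**Frequency sanity checks.** Unique variants should be *uncommon* and
homozygous-derived variants *common* within their own population. Both
checks compare within-population ALT frequencies of the focal sites to an
equal-size random draw of sites, one-sided Wilcoxon rank-sum. The random
pool is restricted to sites segregating in the population (ALT observed at
least once): an unrestricted genome-wide draw is dominated by sites the
population does not carry at all (frequency 0), which would invert the
"rarer than random" comparison into a triviality. Populations with fewer
than two genotyped samples return a not-computable result rather than a
test.

## Constraint classification

A phyloP-style score *s* is read as the −log10 p-value of a neutrality
test (conservation positive), so *p* = 10^(−s). Two modes:

* **fixed** (default): the published genome-wide cutoffs — 2.56 at FDR
  0.05, 3.52 at FDR 0.01 — for reproducing analyses tied to the external
  genome-wide score track.
* **estimated**: Benjamini–Hochberg over the scores at hand; the cutoff is
  the smallest rejected score, +∞ (nothing constrained, warning logged)
  when nothing is rejected. This is the right mode for synthetic data,
  whose score distribution is not the genome-wide one.

"Constrained" means *strictly above* the cutoff, so a negative score
(acceleration) is never constrained and a score exactly at the cutoff is
not constrained. Constrained and missense flags are independent; a variant
can count in both burden categories.

## Burden comparison

Per representative: n_unique, the counts constrained/missense among them,
and the two fractions (0 when n_unique = 0, with a warning). Group
comparison is a two-sided Wilcoxon rank-sum by default (exact null when the
combined n ≤ 20 and there are no ties; otherwise normal approximation with
continuity correction and mid-rank ties; fully tied data returns p = 1), or
a Welch t-test — both are exposed because both conventions are common for
this contrast. No multiple-testing correction is applied across the two
metrics; raw p-values are reported.

## Gene-set enrichment

Functional variants (constrained at the strict level ∧ missense) are
collapsed to genes; a gene counts once regardless of how many qualifying
variants hit it. For each gene set: k hits in set, n total hits, K set
size within the universe, N universe size; p = hypergeometric upper tail
P(X ≥ k); fold = (k/n)/(K/N); q = Benjamini–Hochberg across all sets within
the sample. The gene universe defaults to the genes present in the
annotation table (hits can only arise there); it is an argument, since
using the full gene-set collection's gene list is also defensible. All
(sample, set) pairs are pooled and ranked by raw p ascending with
deterministic tie-breaking by (sample id, set id); the pool size — samples
× sets — is reported alongside. Gene sets are read from GMT files so real
GO collections drop in. Only one-sided enrichment is computed.

## Runs of homozygosity and inbreeding

The RoH caller is the classic SNP-count sliding window scheme: windows of
`window_snps` consecutive sites (default 50) are homozygous when they hold
at most `window_max_het` (1) heterozygous and `window_max_missing` (5)
missing calls; a SNP is eligible when at least `hit_threshold` (5%) of the
windows containing it are homozygous; maximal eligible runs are split at
inter-SNP gaps above `max_gap_kb` (1000) and kept when they reach
`min_segment_snps` (100), `min_segment_kb` (1000) and at least one SNP per
`min_density_kb_per_snp` (50). These defaults mirror the de-facto
convention of the widely used window-based caller; all are parameters.
Segment boundaries are the first and last eligible SNP, so calls extend
slightly past a true autozygous tract boundary (the window tolerance
admits a single flanking heterozygote); at the package's default scales
this bias is well inside the ±0.02 recovery tolerance checked by the
tests.

F_RoH = Σ segment length / assayed length, where assayed length is the
first-to-last-site span summed over chromosomes (a fixed genome length can
be supplied instead). F_MoM uses cohort ALT frequencies p_l and non-missing
allele counts n_l at the sample's non-missing cohort-polymorphic sites:
E_hom = Σ[1 − 2 p_l (1−p_l) n_l/(n_l−1)], F = (O_hom − E_hom)/(L − E_hom).
The n/(n−1) factor is the usual small-sample correction; with population
structure in the cohort the estimate absorbs the Wahlund effect, which is a
property of the estimator, not a bug — calibration tests therefore use
single-population cohorts. The correlation between the two coefficients is
Pearson r with t = r√(df/(1−r²)), df = n−2, two-sided p from the t
distribution. Samples with any missing genotype are dropped from the
inbreeding table by default (complete-case convention for homozygosity
analyses); a flag keeps them.

## Hudson F_ST and marker selection

Per site, with sample frequencies p1, p2 and allele counts n1, n2:

    num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)

Sites with fewer than two non-missing alleles in either group or den = 0
are undefined (marked, excluded from aggregation). The genome-wide value is
the ratio of averages Σnum/Σden, the aggregation with the better bias
properties. Negative per-site estimates are kept; the estimator is
symmetric in groups and invariant to allele relabeling.

Marker selection keeps sites exceeding `fst_min` in **at least one**
contrast by default ("in all" by flag) — with several contrast families
feeding one panel, the union reading is the workable one. Pruning is
greedy in position order: a candidate is dropped when its genotype-dosage
r² (composite LD, missing excluded pairwise; undefined r² never prunes)
with any already-retained site within `window_bp` exceeds `r2_max`. The
later site of a violating pair always loses, which makes the output
deterministic and order-reproducible.

## Copy number

CN = 2 × (target per-bp read rate / pooled background per-bp rate),
background assumed diploid; the factor 2 is a parameter. The 95% CI is a
bootstrap over background windows *combined with* a Poisson resample of the
target read total. The background-only bootstrap was considered and
rejected: under Poisson depth the target's counting noise is of the same
order as the background window-to-window variability, and ignoring it gives
~40% coverage at 30× with 75×1kb windows instead of the nominal 95%.
Background windows are placed uniformly, non-overlapping, avoiding an
exclusion list, deterministically under a seed.

## Phenotype rules

Each rule maps a diploid dosage (or a user-supplied allele call for
region-typed loci such as promoter-length polymorphisms, which need phased
haplotypes produced upstream) to a trait state on one channel. Masking is
epistasis: a rule lists (locus, state) pairs that hide its expression; a
locus is masked when any masker is itself expressed in the masking state,
so the result is a well-defined fixed point for acyclic mask graphs and is
independent of rule order (checked against an exhaustive fixed-point
evaluator). Missing genotypes give "unknown" without blocking other
channels, and an unknown locus never masks. The packaged default panel
covers the classic loci (dominant black, tan points, wolf agouti, domino,
melanistic mask, blue eyes, MITF white spotting as a region rule, coat
layer, pigment intensity); a complete custom panel is supplied in the same
YAML schema.

## Synthetic cohort generator

Ancestral frequencies are Beta(0.5, 0.5); each population drifts under
Balding–Nichols: q ~ Beta(p(1−F)/F, (1−p)(1−F)/F), with q = p exactly at
F = 0. Genotypes use an excess-homozygosity parameter f: P(het) =
2q(1−q)(1−f), the remaining mass split as q²+fq(1−q) / (1−q)²+fq(1−q).
Planted autozygous tracts force homozygosity (allele drawn once at the
population frequency) at every covered site. Neutral scores are −log10(U);
constrained sites draw from a shifted neutral distribution (default shift
+4, comfortably above both fixed cutoffs). Genes tile each chromosome
uniformly; depth tables are Poisson(depth_mean × length × cn/2).

Three site classes create recoverable signal. **Shared** sites segregate
everywhere. **Private** sites (default 50% of sites) belong to one
population at frequency 0.05 and are absent elsewhere — the ground truth
for unique-variant discovery; each is deleterious (constrained + missense)
with probability base_deleterious_rate (0.2) × the owning group's
burden_shift multiplier. These two defaults were set by a power analysis of
the intended detection experiment: with one representative per population,
a ~100-variant unique set per dog is roughly 40% chance-unique shared
drift variants and 60% private carriers, which keeps a 2× group shift in
the deleterious rate (constrained fraction ~0.15 vs ~0.24) detectable by
rank-sum at 15 vs 15 populations and 20k sites while leaving the null
exchangeable (calibrated type-I error). **Derived** sites belong to one
non-wolf population at frequency 0.8 (common there) and are absent from
all wolf-group populations — ground truth for homozygous-derived
discovery; a fraction is functional. An optional enrichment plant reassigns
the focal population's functional derived sites into a designated gene set
at multiplier × the baseline gene fraction by swapping site ownership, so
marginal counts are preserved.

Everything derives from one integer seed; reruns are byte-identical
including the emitted VCF. Missingness is off by default (`missing_rate`).
Monomorphic sites are retained and handled downstream. Coordinates are
"chr1"-style, 1-based inclusive in VCF and tables, 0-based half-open in
BED exports and internal interval arithmetic.

**What the generator does not emulate:** linkage disequilibrium from
recombination and shared haplotypes (sites are independent given
frequencies — LD-pruning tests therefore build correlated columns
explicitly), realistic site-frequency spectra from demography, sequencing
error or ancient-DNA damage, and genotype-call uncertainty. Passing
recovery tests shows the estimators are correct under the stated
generative model, not that real data meet that model.

## Problem sizes and numerics

Tests and the acceptance script run scaled-down versions of each analysis,
chosen so every statistical check retains its meaning: calibration runs use
1000 replicates at small cohort size (type-I error is size-free); power
and recovery runs use the stated planted conditions (15 vs 15 populations
× 20k sites; 50Mb chromosomes with 20k SNPs; 30 samples × 50k sites for
F_MoM; 75 background windows at 30×). Exact-agreement checks (set
discovery, RoH calling, LD pruning, hypergeometric tails) compare against
independent brute-force oracles on randomized instances. Ties are broken
deterministically everywhere (documented per operation); divisions guard
their degenerate cases (zero-variance metrics, empty groups, undefined
F_ST sites, L = E_hom) by raising or marking rather than returning NaN
silently.

## Known limitations

* The fixed 2.56/3.52 cutoffs reproduce the published classification only
  with the original genome-wide score track; the estimated mode is a
  documented stand-in whose cutoffs depend on the supplied scores.
* RoH parameter defaults follow the common windowed-caller convention; the
  original analysis' exact flags are not published, so segment-level
  concordance with it is not claimed.
* The copy-number model ignores GC bias and mappability; inputs are region
  read-count tables, alignment is upstream.
* Exact reproduction of the published variant counts, enrichment q-values
  and marker-panel sizes requires the full external call set, score track
  and gene-set release; the package reproduces the methods and verifies
  them on generative ground truth instead.
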