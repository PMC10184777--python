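# paleopop

Comparative population genomics for cohorts sampled **one representative per
population** — the study design used when a single historic or ancient genome
(for example a famous working sled dog sequenced from museum remains) is
assessed against a panel of modern populations, each contributing one dog.

Given multi-sample biallelic genotypes (VCF), a per-site constraint-score and
annotation table, and sample→population/group metadata, the package computes:

* **Population-unique ("rare") variant burden** — variants carried (het or hom)
  by a population's representative and absent from every other representative;
  the fraction that is evolutionarily constrained or missense; Wilcoxon
  rank-sum / Welch-t comparison between groups (e.g. working sled dogs vs
  modern breeds).
* **Homozygous-derived functional variants** — sites homozygous for the
  alternate allele in a representative and unobserved in a wolf outgroup,
  filtered to constrained (strict FDR) missense variants, collapsed to genes,
  with hypergeometric gene-set enrichment (Benjamini–Hochberg within sample)
  and a pooled global rank over all (dog, gene-set) pairs.
* **Runs of homozygosity and inbreeding** — windowed RoH calling,
  F<sub>RoH</sub> = Σ RoH length / assayed length, the method-of-moments
  coefficient F<sub>MoM</sub> = (O<sub>hom</sub> − E<sub>hom</sub>)/(L − E<sub>hom</sub>),
  and their Pearson correlation with t = r·√(df/(1−r²)).
* **Ancestry-informative marker panels** — per-site Hudson F<sub>ST</sub>
  (ratio-of-averages genome wide), thresholding across contrasts, and greedy
  LD pruning (genotype r² within physical windows).
* **Read-depth copy number** — per-bp read rate of a target region over the
  pooled rate of random background windows, CN = 2 × ratio, with a bootstrap CI.
* **Phenotype prediction** — a config-driven rule engine mapping genotypes at
  classic canine appearance loci to trait states with epistatic masking (e.g.
  tan points and blue eyes hidden behind a melanistic facial mask).
* **Synthetic cohorts** — a Balding–Nichols generator with planted autozygous
  tracts, population-private and derived site classes, a neutral/constrained
  score mixture, and Poisson window depth, so every stage has recoverable
  ground truth.

## Worked example

```python
import numpy as np
import paleopop as pp

groups = {f"pop{i:02d}": ("working" if i <= 15 else "breed") for i in range(1, 31)}
cfg = pp.SyntheticCohortConfig(
    n_populations=30, samples_per_population=1, n_sites=20_000,
    chrom_lengths={"chr1": 20_000_000},
    group_labels=groups, burden_shift={"breed": 2.0}, seed=7)
geno, ann_obj, samples, truth = pp.simulate_cohort(cfg)
ann = ann_obj.aligned_to(geno)

reps = pp.pick_representatives(samples, seed=7)
flags = pp.classify_sites(ann, pp.fixed_cutoffs(), level=0.05)
records = [pp.burden_profile(rep, samples,
                             pp.find_population_unique(geno, reps, rep), flags)
           for _, rep in reps]
print("mean unique variants per dog:",
      round(np.mean([r.n_unique for r in records]), 1))
cmp = pp.compare_groups(records, "working", "breed", "pct_constrained")
print(f"wilcoxon U={cmp.statistic:.1f} p={cmp.p_value:.4f}")
```

prints

```
mean unique variants per dog: 102.4
wilcoxon U=4.0 p=0.0000
```

i.e. each representative carries ~102 variants seen in no other
representative, and with a 2× planted deleterious rate in the breed group
the working dogs carry a clearly lower constrained fraction (mean 0.155 vs
0.243; rank-sum p < 10⁻⁴). The same stages run from the shell:

```bash
paleopop simulate --config cohort.yaml --out sim/
paleopop run --config run.yaml          # full pipeline + manifest
paleopop rare-burden --vcf sim/cohort.vcf --ann sim/annotation.tsv \
    --samples sim/samples.tsv --fdr 0.05 --mode estimated --out burden
paleopop copy-number --counts depth.tsv --out cn.json
```

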