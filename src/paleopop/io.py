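"""Cohort input/output: genotype matrices, annotations, sample metadata.

Genotypes are held as a dense ``samples x sites`` int8 array counting ALT
alleles (0, 1, 2) with ``-1`` for missing.  Sites are biallelic SNPs only;
coordinates are 1-based inclusive in VCF and in the in-memory site table,
and converted to 0-based half-open only where interval arithmetic needs it
(BED export, gene assignment).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("paleopop")

MISSING = -1

#: closed vocabulary for sample group labels
GROUPS = ("working", "breed", "wolf", "coyote", "village", "other")

#: closed vocabulary for consequence classes
CONSEQUENCES = ("missense", "synonymous", "other", "none")


def _chrom_sort_key(chrom: str):
    body = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(body)) if body.isdigit() else (1, body)


@dataclass
class GenotypeMatrix:
    """Diploid ALT-allele dosages for samples x biallelic SNP sites.

    Attributes
    ----------
    sample_ids : list of str
        Column identity of ``calls`` rows.
    sites : pandas.DataFrame
        Columns ``chrom, pos, ref, alt``; ``pos`` is 1-based. Positions are
        strictly increasing within each chromosome.
    calls : numpy.ndarray of int8, shape (n_samples, n_sites)
        Values in {0, 1, 2, -1}; -1 encodes a missing genotype.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sample_ids)}, {len(self.sites)})"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0,1,2,-1}")
        s = self.sites
        if len(s) and (s["ref"] == s["alt"]).any():
            raise ValueError("ref == alt at some site")
        for _, pos in s.groupby("chrom", sort=False)["pos"]:
            if not pos.is_monotonic_increasing or pos.duplicated().any():
                raise ValueError("positions not strictly increasing within chromosome")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def row(self, sample: str) -> np.ndarray:
        return self.calls[self.sample_index(sample)]

    def site_keys(self) -> pd.Index:
        """Index of (chrom, pos, ref, alt) tuples, the join key everywhere."""
        return pd.MultiIndex.from_frame(self.sites[["chrom", "pos", "ref", "alt"]])

    def alt_freq(self, sample_subset: list[str] | None = None) -> np.ndarray:
        """ALT allele frequency per site over non-missing calls (NaN if none)."""
        calls = self.calls
        if sample_subset is not None:
            idx = [self.sample_index(s) for s in sample_subset]
            calls = calls[idx]
        ok = calls != MISSING
        n_alleles = 2 * ok.sum(axis=0)
        alt = np.where(ok, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)


@dataclass
class SampleTable:
    """Sample -> (population, group) metadata."""

    table: pd.DataFrame  # columns: sample, population, group

    def __post_init__(self):
        need = {"sample", "population", "group"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"sample table needs columns {sorted(need)}")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate sample rows")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; allowed: {GROUPS}")
        self.table = self.table.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def population_of(self, sample: str) -> str:
        row = self.table.loc[self.table["sample"] == sample]
        if row.empty:
            raise KeyError(f"unknown sample {sample!r}")
        return row["population"].iloc[0]

    def group_of(self, sample: str) -> str:
        row = self.table.loc[self.table["sample"] == sample]
        if row.empty:
            raise KeyError(f"unknown sample {sample!r}")
        return row["group"].iloc[0]

    def members(self, population: str) -> list[str]:
        return list(self.table.loc[self.table["population"] == population, "sample"])

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample"])


@dataclass
class SiteAnnotation:
    """Per-site constraint score, gene and consequence, keyed (chrom,pos,ref,alt)."""

    table: pd.DataFrame  # columns: chrom, pos, ref, alt, gene, consequence, phylop

    def __post_init__(self):
        need = {"chrom", "pos", "ref", "alt", "gene", "consequence", "phylop"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"annotation needs columns {sorted(need)}")
        bad = set(self.table["consequence"].dropna()) - set(CONSEQUENCES)
        if bad:
            raise ValueError(f"unknown consequence classes {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    def keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.table[["chrom", "pos", "ref", "alt"]])

    def aligned_to(self, geno: GenotypeMatrix) -> pd.DataFrame:
        """Annotation reindexed to the matrix's site order.

        Sites absent from the annotation get phylop=NaN, gene=None,
        consequence='none'.  Annotated sites absent from the matrix are
        ignored with a logged count.
        """
        ann = self.table.set_index(self.keys())
        ann = ann[~ann.index.duplicated(keep="first")]
        keys = geno.site_keys()
        extra = ann.index.difference(keys)
        if len(extra):
            logger.info("ignoring %d annotated sites absent from genotype matrix", len(extra))
        out = ann.reindex(keys)
        out["consequence"] = out["consequence"].fillna("none")
        out["gene"] = out["gene"].where(pd.notna(out["gene"]), None)
        return out.reset_index(drop=True)


@dataclass
class RepresentativeSet:
    """population -> single representative sample."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        vals = list(self.mapping.values())
        if len(set(vals)) != len(vals):
            raise ValueError("representatives must be distinct samples")

    @property
    def samples(self) -> list[str]:
        return list(self.mapping.values())

    def __len__(self):
        return len(self.mapping)

    def __iter__(self):
        return iter(self.mapping.items())


# ---------------------------------------------------------------------------
# VCF / TSV round trip
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal multi-sample VCF v4.2 with GT only."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chroms = sorted(set(geno.sites["chrom"]), key=_chrom_sort_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=paleopop\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        sites = geno.sites
        for j in range(geno.n_sites):
            row = sites.iloc[j]
            gts = "\t".join(gt_map[int(c)] for c in geno.calls[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; skip everything else with logged counts.

    Half-calls (one allele missing) are treated as fully missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    recs, calls = [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if v.REF == v.ALT[0] or v.REF not in "ACGT" or v.ALT[0] not in "ACGT":
            n_skipped += 1
            continue
        row = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            row[i] = MISSING if (a < 0 or b < 0) else (a > 0) + (b > 0)
        recs.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        calls.append(row)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records", n_skipped)
    if not recs:
        raise ValueError("no usable sites in VCF")
    sites = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(samples, sites, np.vstack(calls).T)


def write_annotation(ann: SiteAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> SiteAnnotation:
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    tab["gene"] = tab["gene"].where(pd.notna(tab["gene"]), None)
    return SiteAnnotation(tab)


def write_sample_table(samples: SampleTable, path) -> None:
    samples.table.to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype=str))


def write_cohort(geno: GenotypeMatrix, ann: SiteAnnotation, samples: SampleTable,
                 vcf_path, annotation_path, sample_table_path) -> None:
    write_vcf(geno, vcf_path)
    write_annotation(ann, annotation_path)
    write_sample_table(samples, sample_table_path)


def read_cohort(vcf_path, annotation_path, sample_table_path
                ) -> tuple[GenotypeMatrix, SiteAnnotation, SampleTable]:
    """Load and cross-validate the three cohort files.

    Every VCF sample must appear in the sample table; offenders are listed in
    the raised error.
    """
    geno = read_vcf(vcf_path)
    ann = read_annotation(annotation_path)
    samples = read_sample_table(sample_table_path)
    missing = [s for s in geno.sample_ids if s not in set(samples.samples)]
    if missing:
        raise ValueError(f"VCF samples absent from sample table: {missing}")
    return geno, ann, samples


def pick_representatives(samples: SampleTable, seed: int) -> RepresentativeSet:
    """Uniform random choice of one representative per population.

    Deterministic under ``seed``; a single-member population contributes that
    member regardless of seed.
    """
    rng = np.random.default_rng(seed)
    mapping = {}
    for pop in samples.populations():
        members = samples.members(pop)
        if not members:
            raise ValueError(f"population {pop!r} has no samples")
        mapping[pop] = members[int(rng.integers(len(members)))]
    return RepresentativeSet(mapping)


def setup_logging(level: str = "INFO") -> None:
    """Route package logs to stderr (results go to files)."""
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [h]
    logger.setLevel(level.upper())
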