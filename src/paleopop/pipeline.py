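"""End-to-end orchestration: one config, plain-file stage outputs, manifest.

Stages run in a fixed order — (optional) simulate, read, representative
selection, constraint classification, rare-variant burden, homozygous-
derived enrichment, homozygosity/inbreeding, ancestry marker panel, then
copy number and phenotype prediction when their inputs are supplied.  Each
stage writes the documented TSV/BED/JSON formats so any stage can be rerun
independently; a manifest records versions, seeds, parameters and input
checksums, and reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from . import ancestry, burden, constraint, copy_number, enrichment, homozygosity
from . import io as cio
from . import phenotype as pheno
from . import synthetic

logger = logging.getLogger("paleopop")


class ValidationError(ValueError):
    """Config invalid; message names the offending field."""


class StageError(RuntimeError):
    """A pipeline stage failed; message is stage-tagged."""


@dataclass
class RunConfig:
    out_dir: str
    vcf: str | None = None
    annotation: str | None = None
    samples: str | None = None
    simulate: dict | None = None
    representative_seed: int = 0
    constraint_mode: str = "fixed"           # "fixed" | "estimated"
    fdr_burden: float = 0.05
    fdr_functional: float = 0.01
    group_a: str = "working"
    group_b: str = "breed"
    outgroup_group: str = "wolf"
    gene_sets: str | None = None
    roh: dict = field(default_factory=dict)
    fst_min: float = 0.5
    ld_window_bp: int = 250_000
    r2_max: float = 0.2
    contrasts: list[list[str]] = field(default_factory=lambda: [["working", "breed"]])
    depth_table: str | None = None
    pheno_rules: str | None = None
    pheno_sample: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config fields: {sorted(bad)}")
        if "out_dir" not in raw:
            raise ValidationError("missing required field: out_dir")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("vcf", "annotation", "samples"):
                p = getattr(self, name)
                if p is None:
                    raise ValidationError(f"missing required field: {name}")
                if not os.path.exists(p):
                    raise ValidationError(f"{name}: file not found: {p}")
        for name in ("gene_sets", "depth_table", "pheno_rules"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise ValidationError(f"{name}: file not found: {p}")
        if self.constraint_mode not in ("fixed", "estimated"):
            raise ValidationError("constraint_mode must be 'fixed' or 'estimated'")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every applicable stage; returns the manifest dict."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "paleopop_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {},
        "stages": [],
    }

    def stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        if config.simulate is not None:
            stage("simulate")
            sim_cfg = synthetic.SyntheticCohortConfig(**config.simulate)
            geno, ann_obj, samples, truth = synthetic.simulate_cohort(sim_cfg)
            sim_dir = os.path.join(out, "simulated")
            paths = synthetic.write_cohort_bundle(sim_dir, geno, ann_obj, samples, truth)
            config.vcf, config.annotation, config.samples = (
                paths["vcf"], paths["annotation"], paths["samples"])
    except ValidationError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[simulate] {e}") from e

    for name in ("vcf", "annotation", "samples", "gene_sets", "depth_table", "pheno_rules"):
        p = getattr(config, name)
        if p:
            manifest["inputs"][name] = {"path": p, "sha256": _sha256(p)}

    try:
        stage("read")
        geno, ann_obj, samples = cio.read_cohort(config.vcf, config.annotation, config.samples)
        ann = ann_obj.aligned_to(geno)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[read] {e}") from e

    try:
        stage("representatives")
        reps = cio.pick_representatives(samples, config.representative_seed)
        pd.DataFrame(sorted(reps.mapping.items()), columns=["population", "sample"]
                     ).to_csv(os.path.join(out, "representatives.tsv"), sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[representatives] {e}") from e

    try:
        stage("constraint")
        levels = sorted({config.fdr_burden, config.fdr_functional})
        if config.constraint_mode == "fixed":
            cuts = constraint.fixed_cutoffs()
        else:
            cuts = constraint.estimate_fdr_cutoffs(ann["phylop"].to_numpy(), levels)
        cuts.to_frame(ann["phylop"].to_numpy()).to_csv(
            os.path.join(out, "cutoffs.tsv"), sep="\t", index=False)
        flags_burden = constraint.classify_sites(ann, cuts, config.fdr_burden)
        flags_functional = constraint.classify_sites(ann, cuts, config.fdr_functional)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[constraint] {e}") from e

    try:
        stage("rare_burden")
        records, rarity_rows = [], []
        for pop, rep in reps:
            uniq = burden.find_population_unique(geno, reps, rep)
            records.append(burden.burden_profile(rep, samples, uniq, flags_burden))
            rc = burden.rarity_check(geno, samples, rep, uniq,
                                     seed=config.representative_seed)
            rarity_rows.append({"sample": rep, "population": pop,
                                "computable": rc.computable, "p_value": rc.p_value})
        burden.records_to_frame(records).to_csv(
            os.path.join(out, "burden.tsv"), sep="\t", index=False)
        pd.DataFrame(rarity_rows).to_csv(
            os.path.join(out, "rarity_check.tsv"), sep="\t", index=False)
        comps = []
        groups = {r.group for r in records}
        if config.group_a in groups and config.group_b in groups:
            for metric in ("pct_constrained", "pct_missense"):
                for test in ("wilcoxon", "t"):
                    c = burden.compare_groups(records, config.group_a, config.group_b,
                                              metric, test)
                    comps.append(dataclasses.asdict(c))
        pd.DataFrame(comps).to_csv(
            os.path.join(out, "comparisons.tsv"), sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[rare_burden] {e}") from e

    try:
        stage("derived_enrichment")
        outgroup = samples.samples_in_group(config.outgroup_group)
        outgroup = [s for s in outgroup if s in geno.sample_ids]
        if outgroup:
            rows, enrich_frames = [], []
            gene_sets = enrichment.read_gmt(config.gene_sets) if config.gene_sets else None
            universe = sorted({g for g in ann["gene"] if g is not None and pd.notna(g)})
            for pop, rep in reps:
                if rep in outgroup:
                    continue
                dv = enrichment.derived_variant_set(geno, rep, outgroup,
                                                    flags_functional, ann)
                cc = enrichment.commonness_check(geno, samples, rep, dv.sites,
                                                 seed=config.representative_seed)
                rows.append({"sample": rep, "population": pop,
                             "n_derived": dv.n_total, "n_functional": dv.n_functional,
                             "n_genes_hit": len(dv.genes_hit),
                             "commonness_p": cc.p_value if cc.computable else None})
                if gene_sets:
                    enrich_frames.append(enrichment.enrich(
                        dv.genes_hit, gene_sets, universe, sample=rep))
            pd.DataFrame(rows).to_csv(
                os.path.join(out, "derived.tsv"), sep="\t", index=False)
            if gene_sets and enrich_frames:
                ranked = enrichment.global_rank(pd.concat(enrich_frames))
                ranked.to_csv(os.path.join(out, "enrichment.tsv"), sep="\t", index=False)
        else:
            logger.warning("no %s-group samples; derived-variant stage skipped",
                           config.outgroup_group)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[derived_enrichment] {e}") from e

    try:
        stage("homozygosity")
        params = homozygosity.RohParams(**config.roh)
        assayed = homozygosity.assayed_length(geno)
        results, all_segs = [], []
        for s in geno.sample_ids:
            segs = homozygosity.detect_roh(geno, s, params)
            all_segs.extend(segs)
            if (geno.row(s) == cio.MISSING).any():
                logger.info("%s excluded from inbreeding table (missing calls)", s)
                continue
            results.append(homozygosity.InbreedingResult(
                s, homozygosity.f_roh(segs, assayed), homozygosity.f_mom(geno, s)))
        pd.DataFrame([dataclasses.asdict(s) for s in all_segs]).to_csv(
            os.path.join(out, "roh.tsv"), sep="\t", index=False)
        homozygosity.segments_to_bed(all_segs, os.path.join(out, "roh.bed"))
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            os.path.join(out, "inbreeding.tsv"), sep="\t", index=False)
        corr = None
        if len(results) >= 3:
            try:
                r, t, df, p = homozygosity.correlate_f(results)
                corr = {"pearson_r": r, "t": t, "df": df, "p": p}
            except ValueError as e:
                logger.warning("F_RoH/F_MoM correlation not computable: %s", e)
        with open(os.path.join(out, "inbreeding_correlation.json"), "w") as fh:
            json.dump(corr, fh, indent=2)
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[homozygosity] {e}") from e

    try:
        stage("ancestry_panel")
        tables = []
        for ga, gb in config.contrasts:
            sa = [s for s in samples.samples_in_group(ga) if s in geno.sample_ids]
            sb = [s for s in samples.samples_in_group(gb) if s in geno.sample_ids]
            if not sa or not sb:
                logger.warning("contrast %s vs %s has an empty group; skipped", ga, gb)
                continue
            tab, gw = ancestry.hudson_fst(geno, sa, sb)
            tab.insert(0, "contrast", f"{ga}_vs_{gb}")
            tables.append((tab, gw))
        if tables:
            panel = ancestry.select_markers(
                geno, [t for t, _ in tables], config.fst_min,
                config.ld_window_bp, config.r2_max)
            sel = geno.sites.iloc[panel.site_indices]
            sel.to_csv(os.path.join(out, "panel.tsv"), sep="\t", index=False)
            with open(os.path.join(out, "fst_genome_wide.json"), "w") as fh:
                json.dump({t["contrast"].iloc[0]: gw for t, gw in tables}, fh, indent=2)
            sub = cio.GenotypeMatrix(
                geno.sample_ids, sel.reset_index(drop=True),
                geno.calls[:, panel.site_indices])
            cio.write_vcf(sub, os.path.join(out, "panel.vcf"))
    except Exception as e:  # noqa: BLE001
        raise StageError(f"[ancestry_panel] {e}") from e

    if config.depth_table:
        try:
            stage("copy_number")
            depth = copy_number.read_depth_table(config.depth_table)
            est = copy_number.estimate_cn(depth, seed=config.representative_seed)
            est.to_json(os.path.join(out, "cn.json"))
        except Exception as e:  # noqa: BLE001
            raise StageError(f"[copy_number] {e}") from e

    if config.pheno_rules:
        try:
            stage("pheno_panel")
            rules = pheno.load_rules(config.pheno_rules)
            target = config.pheno_sample or geno.sample_ids[0]
            gts = pheno.genotypes_for_sample(geno, target)
            pred = pheno.predict_phenotype(gts, rules)
            with open(os.path.join(out, "pheno.json"), "w") as fh:
                json.dump({"sample": target, **pheno.prediction_to_dict(pred)},
                          fh, indent=2)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"[pheno_panel] {e}") from e

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
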