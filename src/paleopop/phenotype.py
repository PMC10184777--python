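"""Rule-based prediction of appearance traits from genotypes at known loci.

Each rule maps the diploid genotype at one locus (a single site, or a named
region whose allele call the user supplies, e.g. promoter-length
polymorphisms that need phased haplotypes upstream) to a trait state on one
channel (base color, pattern, mask, eye color, white spotting, coat layer,
pigment intensity).  Epistasis is expressed as masking: a rule lists
(locus, state) pairs that suppress its visible expression — e.g. a
melanistic facial mask hides tan points and blue eyes.  Masking must be
acyclic; a locus is masked when any of its maskers is *itself expressed*
in the masking state, so the result is independent of evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import yaml

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("paleopop")

CHANNELS = ("base color", "pattern", "mask", "eye color", "white spotting",
            "coat layer", "pigment intensity")

GT_KEYS = ("0", "1", "2", "missing")


@dataclass
class PhenoRule:
    locus: str
    channel: str
    genotype_map: dict[str, str]          # over "0","1","2","missing"
    site: tuple[str, int, str, str] | None = None
    region: tuple[str, int, int] | None = None
    masked_by: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if (self.site is None) == (self.region is None):
            raise ValueError(f"rule {self.locus}: exactly one of site/region required")


@dataclass
class LocusCall:
    locus: str
    channel: str
    genotype: str         # "0" | "1" | "2" | "missing"
    state: str
    visible: bool
    masked_by: str | None  # "locus=state" that did the masking, if any


@dataclass
class PhenoPrediction:
    """Per-locus calls plus a per-channel roll-up.

    ``channels[ch]`` is the list of visible states on that channel, or
    ``["unknown (missing genotype)"]`` when nothing on the channel could be
    resolved.
    """

    calls: dict[str, LocusCall]
    channels: dict[str, list[str]]

    def state_of(self, locus: str) -> str:
        return self.calls[locus].state

    def is_visible(self, locus: str) -> bool:
        return self.calls[locus].visible


def validate_rules(rules: list[PhenoRule]) -> list[str]:
    """Return a list of problems (empty = clean); raises nothing."""
    problems = []
    seen = set()
    for r in rules:
        if r.locus in seen:
            problems.append(f"duplicate locus {r.locus!r}")
        seen.add(r.locus)
        missing_keys = [k for k in GT_KEYS if k not in r.genotype_map]
        if missing_keys:
            problems.append(f"{r.locus}: genotype map not total, missing {missing_keys}")
    by_locus = {r.locus: r for r in rules}
    for r in rules:
        for masker, _state in r.masked_by:
            if masker not in by_locus:
                problems.append(f"{r.locus}: masked_by references unknown locus {masker!r}")
    # cycle check on the masking graph
    color: dict[str, int] = {}

    def visit(locus):
        color[locus] = 1
        for masker, _ in by_locus[locus].masked_by:
            if masker not in by_locus:
                continue
            if color.get(masker) == 1:
                problems.append(f"masking cycle through {locus!r} and {masker!r}")
            elif color.get(masker, 0) == 0:
                visit(masker)
        color[locus] = 2

    for r in rules:
        if color.get(r.locus, 0) == 0:
            visit(r.locus)
    return problems


def genotypes_for_sample(geno: GenotypeMatrix, sample: str
                         ) -> dict[tuple[str, int, str, str], int]:
    row = geno.row(sample)
    keys = geno.site_keys()
    return {tuple(k): int(c) for k, c in zip(keys, row)}


def predict_phenotype(genotypes: dict, rules: list[PhenoRule],
                      region_calls: dict[str, int] | None = None) -> PhenoPrediction:
    """Evaluate every rule, then apply masking.

    ``genotypes`` maps (chrom, pos, ref, alt) -> call in {0,1,2,-1};
    ``region_calls`` maps region-typed locus ids to the same call codes.
    A locus whose site is absent from the input is "unknown" (logged) and
    never masks anything.
    """
    problems = validate_rules(rules)
    if problems:
        raise ValueError("invalid rule set: " + "; ".join(problems))
    region_calls = region_calls or {}

    def raw_call(rule: PhenoRule) -> str:
        if rule.site is not None:
            key = (rule.site[0], int(rule.site[1]), rule.site[2], rule.site[3])
            if key not in genotypes:
                logger.warning("locus %s: site %s absent from genotypes", rule.locus, key)
                return "missing"
            g = genotypes[key]
        else:
            if rule.locus not in region_calls:
                logger.warning("locus %s: no region call supplied", rule.locus)
                return "missing"
            g = region_calls[rule.locus]
        return "missing" if g == MISSING else str(int(g))

    by_locus = {r.locus: r for r in rules}
    gt = {r.locus: raw_call(r) for r in rules}
    state = {r.locus: r.genotype_map[gt[r.locus]] for r in rules}

    masked_cache: dict[str, str | None] = {}

    def masker_of(locus: str) -> str | None:
        """The (locus=state) suppressing this locus, or None (memoized)."""
        if locus in masked_cache:
            return masked_cache[locus]
        masked_cache[locus] = None  # acyclic, so no re-entry on the same path
        for masker, mstate in by_locus[locus].masked_by:
            if gt[masker] == "missing":
                continue
            if state[masker] == mstate and masker_of(masker) is None:
                masked_cache[locus] = f"{masker}={mstate}"
                break
        return masked_cache[locus]

    calls = {}
    for r in rules:
        m = masker_of(r.locus)
        unknown = gt[r.locus] == "missing"
        calls[r.locus] = LocusCall(r.locus, r.channel, gt[r.locus], state[r.locus],
                                   visible=(m is None) and not unknown,
                                   masked_by=m)
    channels: dict[str, list[str]] = {}
    for ch in CHANNELS:
        on_channel = [c for c in calls.values() if c.channel == ch]
        if not on_channel:
            continue
        visible = [c.state for c in on_channel if c.visible]
        if visible:
            channels[ch] = visible
        elif all(c.genotype == "missing" for c in on_channel):
            channels[ch] = ["unknown (missing genotype)"]
        else:
            channels[ch] = ["(masked)"]
    return PhenoPrediction(calls, channels)


# ---------------------------------------------------------------------------
# Rule config (YAML)
# ---------------------------------------------------------------------------

def rules_from_dict(raw: dict) -> list[PhenoRule]:
    rules = []
    for item in raw.get("loci", []):
        gm = {str(k): str(v) for k, v in item["genotype_map"].items()}
        rules.append(PhenoRule(
            locus=item["locus"], channel=item["channel"], genotype_map=gm,
            site=tuple(item["site"]) if "site" in item else None,
            region=tuple(item["region"]) if "region" in item else None,
            masked_by=[tuple(m) for m in item.get("masked_by", [])]))
    if not rules:
        raise ValueError("rule config defines no loci")
    return rules


def load_rules(path) -> list[PhenoRule]:
    with open(path) as fh:
        return rules_from_dict(yaml.safe_load(fh))


def default_panel() -> list[PhenoRule]:
    """The packaged appearance panel covering the classic canine coat loci."""
    from importlib.resources import files

    text = files("paleopop.data").joinpath("default_panel.yaml").read_text()
    return rules_from_dict(yaml.safe_load(text))


def prediction_to_dict(pred: PhenoPrediction) -> dict:
    return {
        "channels": pred.channels,
        "loci": {k: {"channel": c.channel, "genotype": c.genotype, "state": c.state,
                     "visible": c.visible, "masked_by": c.masked_by}
                 for k, c in pred.calls.items()},
    }
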