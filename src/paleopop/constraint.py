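"""Evolutionary-constraint classification of sites via FDR-controlled cutoffs.

A phyloP-style score s is treated as the -log10 p-value of a neutrality
test (conservation positive), so p = 10**(-s).  Benjamini–Hochberg at a
chosen FDR level over all scored sites turns the genome-wide score
distribution into a single score cutoff: the smallest score in the rejected
set.  Two modes are supported:

* **fixed** — the published genome-wide cutoffs 2.56 (FDR 0.05) and 3.52
  (FDR 0.01), for reproducing the reference analysis whose score track is
  external;
* **estimated** — cutoffs recomputed from the scores at hand (the right
  mode for synthetic cohorts).

"Constrained" always means *strictly above* the cutoff; negative scores
(acceleration) can therefore never be constrained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("paleopop")

#: published genome-wide cutoffs: score 2.56 at FDR 0.05, 3.52 at FDR 0.01
FIXED_CUTOFFS = {0.05: 2.56, 0.01: 3.52}


@dataclass
class ConstraintCutoffs:
    """Score cutoff per FDR level; smaller FDR always means a larger cutoff."""

    cutoffs: dict[float, float]
    provenance: str = "fixed"  # "fixed" | "estimated"

    def __post_init__(self):
        levels = sorted(self.cutoffs)
        vals = [self.cutoffs[w] for w in levels]
        if any(v2 > v1 for v1, v2 in zip(vals, vals[1:])):
            raise ValueError("cutoffs must be non-increasing in FDR level")
        if self.provenance not in ("fixed", "estimated"):
            raise ValueError("provenance must be 'fixed' or 'estimated'")

    def cutoff_at(self, level: float) -> float:
        if level not in self.cutoffs:
            raise KeyError(f"no cutoff for FDR level {level}")
        return self.cutoffs[level]

    def to_frame(self, scores=None) -> pd.DataFrame:
        rows = []
        for level in sorted(self.cutoffs, reverse=True):
            c = self.cutoffs[level]
            n_above = int((np.asarray(scores) > c).sum()) if scores is not None else None
            rows.append({"fdr": level, "cutoff": c, "n_above": n_above})
        return pd.DataFrame(rows)


def fixed_cutoffs() -> ConstraintCutoffs:
    return ConstraintCutoffs(dict(FIXED_CUTOFFS), provenance="fixed")


def estimate_fdr_cutoffs(scores, fdr_levels=(0.05, 0.01)) -> ConstraintCutoffs:
    """BH cutoff per FDR level over p = 10**(-score).

    If nothing is rejected at a level the cutoff is +inf (no site can be
    constrained) and a warning is logged.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    pvals = np.power(10.0, -scores)
    out = {}
    for level in fdr_levels:
        if not (0.0 < level < 1.0):
            raise ValueError(f"FDR level must be in (0,1), got {level}")
        reject, *_ = multipletests(pvals, alpha=level, method="fdr_bh")
        if reject.any():
            out[level] = float(scores[reject].min())
        else:
            logger.warning("no site rejected at FDR %.3g; cutoff set to +inf", level)
            out[level] = np.inf
    return ConstraintCutoffs(out, provenance="estimated")


def classify_sites(ann: pd.DataFrame, cutoffs: ConstraintCutoffs,
                   level: float = 0.05) -> pd.DataFrame:
    """Per-site flags: constrained (score strictly above cutoff) and missense.

    ``ann`` is an annotation frame with ``phylop`` and ``consequence``
    columns (e.g. ``SiteAnnotation.aligned_to``).  The two flags are
    independent.  Sites with no score are never constrained (logged count).
    """
    cut = cutoffs.cutoff_at(level)
    scores = pd.to_numeric(ann["phylop"], errors="coerce")
    n_unscored = int(scores.isna().sum())
    if n_unscored:
        logger.info("%d sites lack a constraint score; treated as unconstrained", n_unscored)
    constrained = (scores > cut).fillna(False).to_numpy(dtype=bool)
    missense = (ann["consequence"] == "missense").to_numpy(dtype=bool)
    return pd.DataFrame({"constrained": constrained, "missense": missense},
                        index=ann.index)
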