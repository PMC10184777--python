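"""Ancestry-informative marker panels: Hudson F_ST and windowed LD pruning.

The per-site Hudson estimator of F_ST for two groups with sample ALT
frequencies p1, p2 and allele counts n1, n2 is num/den with::

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

and the genome-wide value is the ratio of averages, sum(num)/sum(den) over
defined sites.  Sites with fewer than two non-missing alleles in either
group, or den = 0, are marked undefined.  Per-site estimates can be
negative and are deliberately not clamped.

Marker selection keeps sites whose F_ST exceeds a threshold in at least
one (default) or all contrasts, then greedily prunes linked sites: scanning
in position order, a site is dropped when its genotype-dosage r^2 with any
already-retained site within ``window_bp`` exceeds ``r2_max`` (the later
site of a violating pair always loses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("paleopop")


def hudson_fst(geno: GenotypeMatrix, group_a_samples: list[str],
               group_b_samples: list[str]) -> tuple[pd.DataFrame, float]:
    """Per-site Hudson F_ST records and the genome-wide ratio of averages."""
    if not group_a_samples or not group_b_samples:
        raise ValueError("both groups must be non-empty")
    rec = {}
    for tag, members in (("1", group_a_samples), ("2", group_b_samples)):
        calls = geno.calls[[geno.sample_index(s) for s in members]]
        ok = calls != MISSING
        n = 2 * ok.sum(axis=0)
        alt = np.where(ok, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / n, np.nan)
        rec[f"p{tag}"], rec[f"n{tag}"] = p, n
    p1, p2 = rec["p1"], rec["p2"]
    n1, n2 = rec["n1"], rec["n2"]
    defined = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
               - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    defined &= np.nan_to_num(den) > 0
    fst = np.where(defined, num / np.where(den > 0, den, 1.0), np.nan)
    table = pd.DataFrame({
        "chrom": geno.sites["chrom"], "pos": geno.sites["pos"],
        "p1": p1, "p2": p2, "n1": n1, "n2": n2,
        "num": np.where(defined, num, np.nan),
        "den": np.where(defined, den, np.nan),
        "fst": fst, "defined": defined})
    if defined.any():
        genome_wide = float(np.nansum(num[defined]) / np.nansum(den[defined]))
    else:
        logger.warning("no defined sites for genome-wide F_ST")
        genome_wide = np.nan
    return table, genome_wide


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of dosages, missing excluded pairwise.

    NaN when fewer than two complete pairs remain or either column is
    constant (no LD evidence).
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


@dataclass
class MarkerPanel:
    """Sites surviving the F_ST and LD filters, with per-site provenance."""

    site_indices: np.ndarray
    provenance: pd.DataFrame  # per input site: passed_fst, pruned_ld, retained


def select_markers(geno: GenotypeMatrix, fst_tables: list[pd.DataFrame],
                   fst_min: float = 0.5, window_bp: int = 250_000,
                   r2_max: float = 0.2, mode: str = "any") -> MarkerPanel:
    """F_ST thresholding over contrasts, then greedy windowed LD pruning.

    ``mode='any'`` keeps a site when its F_ST exceeds ``fst_min`` in at
    least one contrast; ``mode='all'`` requires every contrast (undefined
    estimates never satisfy the threshold).
    """
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    if not fst_tables:
        raise ValueError("need at least one F_ST contrast")
    passes = np.column_stack([
        np.nan_to_num(t["fst"].to_numpy(), nan=-np.inf) > fst_min for t in fst_tables])
    passed_fst = passes.any(axis=1) if mode == "any" else passes.all(axis=1)
    if not passed_fst.any():
        logger.warning("no site exceeds F_ST %.3g in %s contrast(s); panel empty",
                       fst_min, mode)

    pruned = np.zeros(geno.n_sites, dtype=bool)
    retained_idx: list[int] = []
    chroms = geno.sites["chrom"].to_numpy()
    pos = geno.sites["pos"].to_numpy()
    for chrom, idx in geno.sites.groupby("chrom", sort=False).indices.items():
        kept_here: list[int] = []
        for j in idx:
            if not passed_fst[j]:
                continue
            violated = False
            for i in reversed(kept_here):
                if pos[j] - pos[i] > window_bp:
                    break
                r2 = genotype_r2(geno.calls[:, i], geno.calls[:, j])
                if not np.isnan(r2) and r2 > r2_max:
                    violated = True
                    break
            if violated:
                pruned[j] = True
            else:
                kept_here.append(j)
        retained_idx.extend(kept_here)
    retained = np.zeros(geno.n_sites, dtype=bool)
    retained[retained_idx] = True
    prov = pd.DataFrame({
        "chrom": chroms, "pos": pos,
        "passed_fst": passed_fst, "pruned_ld": pruned, "retained": retained})
    return MarkerPanel(np.sort(np.array(retained_idx, dtype=int)), prov)
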