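"""Read-depth copy-number estimation for a target region vs background windows.

The estimator follows the amylase-locus convention: per-bp read rate of the
target region(s) divided by the per-bp rate over randomly placed background
windows; since the background is diploid, copy number is twice that ratio.
Uncertainty comes from bootstrapping the background windows, whose
window-to-window variance dominates the Poisson counting noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("region_id", "chrom", "start", "end", "n_reads", "role")


@dataclass
class CnEstimate:
    target_rate: float       # reads per bp over all target regions
    background_rate: float
    depth_ratio: float       # target_rate / background_rate
    cn_estimate: float       # cn_scale * depth_ratio
    ci_low: float
    ci_high: float
    n_target_regions: int
    n_background_windows: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def validate_depth_table(depth: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in depth.columns]
    if missing:
        raise ValueError(f"depth table missing columns {missing}")
    lengths = depth["end"] - depth["start"]
    if (lengths <= 0).any():
        raise ValueError("regions must have positive length")
    if (depth["n_reads"] < 0).any():
        raise ValueError("read counts must be non-negative")
    roles = set(depth["role"])
    if "target" not in roles or "background" not in roles:
        raise ValueError("need at least one target and one background region")


def estimate_cn(depth: pd.DataFrame, cn_scale: float = 2.0,
                n_boot: int = 1000, seed: int = 0) -> CnEstimate:
    """Pooled per-bp rates, depth ratio, copy number, and a bootstrap CI.

    The CI is the 2.5-97.5 percentile of the copy-number statistic over
    bootstrap resamples of the background windows combined with a Poisson
    resample of the target read total, so that both window-to-window
    variability and target counting noise are reflected.
    """
    validate_depth_table(depth)
    tgt = depth[depth["role"] == "target"]
    bg = depth[depth["role"] == "background"]
    t_len = float((tgt["end"] - tgt["start"]).sum())
    t_reads = float(tgt["n_reads"].sum())
    b_len_each = (bg["end"] - bg["start"]).to_numpy(dtype=float)
    b_reads_each = bg["n_reads"].to_numpy(dtype=float)
    target_rate = t_reads / t_len
    b_rate = b_reads_each.sum() / b_len_each.sum()
    if b_rate == 0:
        raise ZeroDivisionError("background read rate is zero")
    ratio = target_rate / b_rate
    rng = np.random.default_rng(seed)
    nb = len(bg)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        pick = rng.integers(0, nb, size=nb)
        denom = b_reads_each[pick].sum()
        t_star = rng.poisson(t_reads) / t_len
        boots[i] = np.nan if denom == 0 else (
            cn_scale * t_star / (denom / b_len_each[pick].sum()))
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return CnEstimate(target_rate, b_rate, ratio, cn_scale * ratio,
                      float(lo), float(hi), len(tgt), nb)


def sample_background_windows(chrom_lengths: dict[str, int], n_windows: int,
                              window_bp: int, exclude: pd.DataFrame | None,
                              seed: int, max_tries: int = 10_000) -> pd.DataFrame:
    """Uniformly place non-overlapping windows, avoiding excluded regions.

    ``exclude`` uses 0-based half-open coordinates (columns chrom, start,
    end).  Deterministic under ``seed``; raises after ``max_tries`` failed
    placements.
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    if (weights < window_bp).all() and n_windows > 0:
        raise ValueError("no chromosome can hold a window")
    weights = np.maximum(weights - window_bp + 1, 0)
    probs = weights / weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    if exclude is not None:
        for _, r in exclude.iterrows():
            if r["chrom"] in placed:
                placed[r["chrom"]].append((int(r["start"]), int(r["end"])))
    rows, tries = [], 0
    while len(rows) < n_windows:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_windows} windows after {max_tries} tries")
        tries += 1
        c = chroms[int(rng.choice(len(chroms), p=probs))]
        start = int(rng.integers(0, chrom_lengths[c] - window_bp + 1))
        end = start + window_bp
        if any(start < e and s < end for s, e in placed[c]):
            continue
        placed[c].append((start, end))
        rows.append((f"bg{len(rows) + 1:03d}", c, start, end, "background"))
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "role"])


def read_depth_table(path) -> pd.DataFrame:
    depth = pd.read_csv(path, sep="\t", dtype={"chrom": str, "role": str})
    validate_depth_table(depth)
    return depth


def write_depth_table(depth: pd.DataFrame, path) -> None:
    depth.to_csv(path, sep="\t", index=False)
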