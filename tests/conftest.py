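import numpy as np
import pandas as pd
import pytest

from paleopop import GenotypeMatrix, SampleTable, SyntheticCohortConfig, simulate_cohort


def make_matrix(calls, sample_ids=None, chrom="chr1", spacing=1000):
    """GenotypeMatrix from a raw samples x sites array with evenly spaced sites."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(1, n_sites + 1) * spacing,
        "ref": "A", "alt": "G"})
    return GenotypeMatrix(sample_ids, sites, calls)


def make_samples(pop_of: dict, group_of: dict | None = None) -> SampleTable:
    group_of = group_of or {}
    return SampleTable(pd.DataFrame({
        "sample": list(pop_of),
        "population": [pop_of[s] for s in pop_of],
        "group": [group_of.get(s, "breed") for s in pop_of]}))


@pytest.fixture(scope="session")
def small_cohort():
    """6 populations x 3 samples, with a wolf outgroup population."""
    groups = {"pop1": "working", "pop2": "working", "pop3": "breed",
              "pop4": "breed", "pop5": "breed", "pop6": "wolf"}
    cfg = SyntheticCohortConfig(
        n_populations=6, samples_per_population=3, n_sites=2000,
        chrom_lengths={"chr1": 5_000_000, "chr2": 5_000_000},
        group_labels=groups, seed=11)
    return simulate_cohort(cfg)
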