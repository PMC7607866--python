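import numpy as np
import pandas as pd
import pytest

from hydroxydomains.core import BinnedTrack, IntervalSet
from hydroxydomains.domains import DomainCallParams
from hydroxydomains.pipeline import build_consensus
from hydroxydomains.synthetic import SyntheticCohortConfig, simulate_cohort

SMALL_GENOME = (("chr1", 3_000_000), ("chr2", 5_000_000))


def small_config(seed: int = 7, **overrides) -> SyntheticCohortConfig:
    """A fast, few-Mb cohort keeping every planted structure (incl. the
    fixed enhancer-pair locus on the 5 Mb chromosome)."""
    kw = dict(
        seed=seed,
        n_normal=3,
        n_tumor=12,
        n_relapse_pairs=2,
        genome=SMALL_GENOME,
        group_sizes={"MMSET": 3, "CCND1": 3, "HD": 4, "other": 2},
        iss_sizes={"I": 4, "II": 4, "III": 3, "NA": 1},
        n_planted_domains=16,
        n_linked_domains=4,
        n_group_specific=1,
        n_genes_per_chrom=30,
    )
    kw.update(overrides)
    return SyntheticCohortConfig(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_consensus(small_cohort):
    return build_consensus(small_cohort, DomainCallParams(), min_support=2)


def random_intervals(
    rng: np.random.Generator,
    n: int,
    chroms=("chrA", "chrB"),
    max_pos: int = 10_000,
    max_len: int = 500,
) -> IntervalSet:
    rows = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        rows.append(
            (
                str(rng.choice(chroms)),
                start,
                start + int(rng.integers(1, max_len)),
            )
        )
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def random_track(
    rng: np.random.Generator, chrom_sizes=None, bin_width: int = 10
) -> BinnedTrack:
    chrom_sizes = chrom_sizes or {"chrA": 1000, "chrB": 777}
    values = {
        c: rng.gamma(2.0, 1.0, -(-size // bin_width))
        for c, size in chrom_sizes.items()
    }
    return BinnedTrack(chrom_sizes, bin_width, values)


def coverage_mask(intervals: IntervalSet, chrom: str, size: int) -> np.ndarray:
    """Per-base boolean oracle for flatten/overlap checks."""
    mask = np.zeros(size, dtype=bool)
    for rec in intervals.df.itertuples(index=False):
        if rec.chrom == chrom:
            mask[rec.start : rec.end] = True
    return mask
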