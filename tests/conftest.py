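from __future__ import annotations

import numpy as np
import pytest

from methcut.counts import (
    LocusCountMatrix,
    filter_coverage,
    normalize_libraries,
    relative_methylation,
)
from methcut.digest import get_enzyme
from methcut.synth import SyntheticDesign, plant_methylation, simulate_counts

TOY_SEQ = "AAATTAACCGCAAATTAAA"  # 19 bp worked example


@pytest.fixture(scope="session")
def mse():
    return get_enzyme("MseI")


@pytest.fixture(scope="session")
def aci():
    return get_enzyme("AciI")


@pytest.fixture
def toy_seq():
    return TOY_SEQ


def make_loci(n_loci: int, chrom_length: int, seed: int, chrom: str = "chr1"):
    """Random sorted locus registry on one chromosome."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(chrom_length, size=n_loci, replace=False))
    return [(chrom, int(p)) for p in pos]


def two_group_design(
    n_loci: int,
    coverage: float = 60.0,
    dispersion: float = 0.0,
    seed: int = 0,
    bulks: int = 5,
) -> SyntheticDesign:
    """Two-timepoint design with mean per-locus count ≈ coverage (at m = 0)."""
    return SyntheticDesign(
        chrom_lengths=(10_000_000,),
        n_bulks_per_timepoint=bulks,
        timepoints=("T0", "T30"),
        library_sizes=coverage * n_loci,
        dispersion=dispersion,
        seed=seed,
    )


def counts_to_meth(counts, design, min_reads: float = 0.0):
    """Counts → normalized → filtered → methylation matrix (test shorthand)."""
    lcm = LocusCountMatrix(counts=counts, design=design.to_frame())
    lcm = normalize_libraries(lcm)
    lcm, _ = filter_coverage(lcm, min_reads=min_reads)
    return relative_methylation(lcm)


@pytest.fixture
def small_pipeline():
    """A seeded 300-locus null dataset ready for DMP calling."""
    design = two_group_design(300, coverage=60, seed=42)
    loci = make_loci(300, 10_000_000, seed=1)
    truth = plant_methylation(loci, design, baseline=(6, 6), n_differential=0, seed=2)
    counts = simulate_counts(truth, design, seed=3)
    return design, truth, counts
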