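"""Locus count matrix handling and relative methylation levels.

Assembles per-sample cut-site counts into a locus × sample matrix,
standardizes library sizes, applies the minimum-coverage filter, converts
normalized counts into per-locus relative methylation levels with integer
pseudo-counts for the downstream test, and offers PCA-based sample QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocusCountMatrix",
    "MethylationMatrix",
    "assemble_counts",
    "normalize_libraries",
    "filter_coverage",
    "relative_methylation",
    "pca_qc",
]


@dataclass
class LocusCountMatrix:
    """Raw (and optionally normalized) counts over loci × samples.

    ``counts`` is indexed by a (chrom, pos) MultiIndex with one column per
    sample; ``design`` is indexed by sample with at least bulk and timepoint
    columns.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    norm_counts: pd.DataFrame | None = None
    normalization: str | None = None
    scale_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate loci in count matrix: {dups[:5]}")
        if (self.counts.values < 0).any():
            raise ValueError("raw counts must be non-negative")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        if self.scale_factors is not None and (self.scale_factors <= 0).any():
            raise ValueError("scale factors must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_loci(self) -> int:
        return len(self.counts)


def assemble_counts(
    per_sample: Mapping[str, pd.DataFrame],
    design: pd.DataFrame,
) -> LocusCountMatrix:
    """Union per-sample count tables into one matrix (absent locus → 0).

    Each per-sample frame needs columns chrom, pos, count. Loci are sorted by
    (chrom, pos); a duplicated locus inside one sample's table is an error.
    """
    missing = set(design.index) - set(per_sample)
    if missing:
        raise ValueError(f"no count table for sample(s): {sorted(missing)}")
    columns = {}
    for sample in design.index:
        df = per_sample[sample]
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            row = df[dup].iloc[0]
            line = int(np.flatnonzero(dup.values)[0]) + 1
            raise ValueError(
                f"sample {sample}: duplicate locus ({row['chrom']}, {row['pos']}) at row {line}"
            )
        columns[sample] = df.set_index(["chrom", "pos"])["count"]
    matrix = pd.DataFrame(columns).fillna(0).astype(np.int64).sort_index()
    matrix.index.names = ["chrom", "pos"]
    return LocusCountMatrix(counts=matrix[list(design.index)], design=design)


def normalize_libraries(
    matrix: LocusCountMatrix, method: str = "median-scale"
) -> LocusCountMatrix:
    """Standardize libraries.

    ``median-scale`` multiplies each sample by (median library total / sample
    total); ``cpm`` scales each sample to one million total counts.
    """
    totals = matrix.counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"zero-total sample(s): {bad}")
    if method == "median-scale":
        factors = float(totals.median()) / totals
    elif method == "cpm":
        factors = 1e6 / totals
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    norm = matrix.counts.astype(float) * factors
    return replace(
        matrix,
        norm_counts=norm,
        normalization=method,
        scale_factors=factors,
    )


def filter_coverage(
    matrix: LocusCountMatrix,
    min_reads: float = 10,
    scope: str = "all-samples",
    samples: Sequence[str] | None = None,
) -> tuple[LocusCountMatrix, pd.DataFrame]:
    """Keep loci covered by at least ``min_reads`` normalized reads.

    Scope ``all-samples`` requires the threshold in every sample;
    ``per-comparison`` restricts the requirement to the given ``samples``.
    Returns the filtered matrix and the drop report (dropped loci with their
    minimum coverage).
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if matrix.norm_counts is None:
        raise ValueError("normalize the matrix before coverage filtering")
    if scope == "all-samples":
        sub = matrix.norm_counts
    elif scope == "per-comparison":
        if not samples:
            raise ValueError("per-comparison scope requires a sample list")
        sub = matrix.norm_counts[list(samples)]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    keep = (sub >= min_reads).all(axis=1)
    dropped = matrix.norm_counts.loc[~keep]
    report = pd.DataFrame({"min_norm_count": dropped.min(axis=1)})
    if keep.sum() == 0:
        warnings.warn("coverage filter removed every locus", stacklevel=2)
    filtered = replace(
        matrix,
        counts=matrix.counts.loc[keep],
        norm_counts=matrix.norm_counts.loc[keep],
    )
    return filtered, report


@dataclass
class MethylationMatrix:
    """Relative methylation levels plus integer pseudo-counts per locus × sample."""

    meth_level: pd.DataFrame  # in [0, 1]
    eff_coverage: pd.Series  # per locus (shared across samples)
    pseudo_meth: pd.DataFrame  # integer successes
    pseudo_unmeth: pd.DataFrame  # integer failures
    design: pd.DataFrame

    def __post_init__(self) -> None:
        lvl = self.meth_level.values
        if np.nanmin(lvl) < 0 or np.nanmax(lvl) > 1:
            raise ValueError("methylation levels must lie in [0, 1]")
        total = self.pseudo_meth.add(self.pseudo_unmeth)
        if not (total.values == self.eff_coverage.values[:, None]).all():
            raise ValueError("pseudo counts must sum to the effective coverage")

    @property
    def samples(self) -> list[str]:
        return list(self.meth_level.columns)

    @property
    def loci(self) -> pd.MultiIndex:
        return self.meth_level.index


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def relative_methylation(
    matrix: LocusCountMatrix,
    transform: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
    trials_mode: str = "noise-matched",
) -> MethylationMatrix:
    """Convert normalized counts to relative methylation levels.

    Default transform: per locus, level = 1 − count / rowmax, anchoring the
    most-cut sample at zero methylation. Pseudo methylated/unmethylated
    counts are the integer split (half-up rounding) of level × effective
    coverage, feeding the binomial test downstream.

    ``trials_mode`` sets the effective number of binomial trials per locus:

    - ``noise-matched`` (default): round(rowmax − rowmean), floored at 1.
      For counting noise with variance ≈ mean (the digest readout), the
      level estimate 1 − c/M has variance mean/M², and a binomial with
      p = 1 − mean/M and n = M − mean has exactly that proportion variance,
      so the downstream test is calibrated under the null.
    - ``rowmax``: round(rowmax) — the naive choice; it overstates the
      information in each sample and makes the downstream test
      anti-conservative, but is kept selectable for sensitivity analysis.

    All-zero loci cannot be scaled and are dropped with a warning. A custom
    ``transform`` (norm counts → levels in [0, 1]) may be supplied to swap
    the level convention.
    """
    if matrix.norm_counts is None:
        raise ValueError("normalize the matrix before computing methylation levels")
    norm = matrix.norm_counts
    rowmax = norm.max(axis=1)
    zero = rowmax == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} all-zero locus/loci with undefined methylation",
            stacklevel=2,
        )
        norm = norm.loc[~zero]
        rowmax = rowmax.loc[~zero]
    if transform is None:
        level = 1.0 - norm.div(rowmax, axis=0)
    else:
        level = transform(norm)
        if ((level.values < 0) | (level.values > 1)).any():
            raise ValueError("custom transform produced levels outside [0, 1]")
    if trials_mode == "noise-matched":
        trials = np.maximum(rowmax.values - norm.values.mean(axis=1), 1.0)
    elif trials_mode == "rowmax":
        trials = rowmax.values
    else:
        raise ValueError(f"unknown trials_mode {trials_mode!r}")
    eff = pd.Series(_round_half_up(trials), index=rowmax.index, name="eff_coverage")
    pseudo_meth = pd.DataFrame(
        _round_half_up(level.values * eff.values[:, None]),
        index=level.index,
        columns=level.columns,
    )
    pseudo_unmeth = pseudo_meth.rsub(eff, axis=0)
    return MethylationMatrix(
        meth_level=level,
        eff_coverage=eff,
        pseudo_meth=pseudo_meth,
        pseudo_unmeth=pseudo_unmeth,
        design=matrix.design,
    )


def pca_qc(meth: MethylationMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Principal components of the sample × locus methylation matrix.

    Loci are centered; returns sample coordinates and per-component
    variance-explained fractions (summing to 1). Component signs are fixed by
    making the largest-magnitude loading of each component positive, so the
    output is deterministic. A constant matrix is flagged with a warning and
    all-zero fractions.
    """
    X = meth.meth_level.to_numpy(dtype=float).T  # samples × loci
    n_samples, n_loci = X.shape
    if n_samples < 3 or n_loci < 2:
        raise ValueError("PCA QC needs at least 3 samples and 2 loci")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s**2).sum())
    k = len(s)
    if total == 0:
        warnings.warn("constant methylation matrix: PCA undefined", stacklevel=2)
        frac = np.zeros(k)
        coords = np.zeros((n_samples, k))
    else:
        # deterministic sign: largest |loading| positive per component
        for j in range(k):
            pivot = np.argmax(np.abs(Vt[j]))
            if Vt[j, pivot] < 0:
                Vt[j] *= -1
                U[:, j] *= -1
        frac = s**2 / total
        coords = U * s
    names = [f"PC{i + 1}" for i in range(k)]
    coord_df = pd.DataFrame(coords, index=meth.samples, columns=names)
    return coord_df, pd.Series(frac, index=names, name="variance_fraction")
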