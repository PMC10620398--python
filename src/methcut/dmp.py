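"""Differential methylation position (DMP) testing.

Per-locus binomial logistic regression of methylation proportion on a
two-group indicator, with likelihood-ratio p-values, Benjamini–Hochberg FDR
and direction calls. With a single binary covariate and integer trial
weights, the maximum-likelihood fit has the group-pooled proportions as
fitted values, so the likelihood-ratio statistic is evaluated in closed form
(equivalent to the G-test on the pooled 2×2 table); this keeps genome-scale
scans vectorized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .counts import MethylationMatrix

__all__ = [
    "Comparison",
    "DMPRecord",
    "test_locus",
    "adjust_fdr",
    "call_dmps",
]


@dataclass(frozen=True)
class Comparison:
    """A two-group contrast; the name reads ``<late>_vs_<early>``."""

    name: str
    group_late: tuple[str, ...]
    group_early: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group_late or not self.group_early:
            raise ValueError(f"comparison {self.name}: both groups must be non-empty")
        if set(self.group_late) & set(self.group_early):
            raise ValueError(f"comparison {self.name}: groups must be disjoint")

    @classmethod
    def from_design(
        cls, design: pd.DataFrame, late_timepoint: str, early_timepoint: str
    ) -> "Comparison":
        late = tuple(design.index[design["timepoint"] == late_timepoint])
        early = tuple(design.index[design["timepoint"] == early_timepoint])
        return cls(f"{late_timepoint}_vs_{early_timepoint}", late, early)


@dataclass(frozen=True)
class DMPRecord:
    chrom: str
    pos: int
    comparison: str
    meth_diff: float  # percentage points, late minus early
    p_value: float
    q_value: float
    direction: str  # "methylated" | "de-methylated"


def _binom_loglik(y: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    # binomial coefficients cancel in likelihood ratios; xlogy handles p in {0,1}
    return special.xlogy(y, p) + special.xlogy(n - y, 1.0 - p)


def _lrt_two_group(
    y_early: np.ndarray,
    n_early: np.ndarray,
    y_late: np.ndarray,
    n_late: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized LRT p-values and meth differences from pooled group counts."""
    y_early = np.asarray(y_early, dtype=float)
    y_late = np.asarray(y_late, dtype=float)
    n_early = np.asarray(n_early, dtype=float)
    n_late = np.asarray(n_late, dtype=float)
    p_early = y_early / n_early
    p_late = y_late / n_late
    p_null = (y_early + y_late) / (n_early + n_late)
    ll_full = _binom_loglik(y_early, n_early, p_early) + _binom_loglik(
        y_late, n_late, p_late
    )
    ll_null = _binom_loglik(y_early, n_early, p_null) + _binom_loglik(
        y_late, n_late, p_null
    )
    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    pvals = stats.chi2.sf(stat, df=1)
    meth_diff = 100.0 * (p_late - p_early)
    return pvals, meth_diff


def test_locus(
    meth_early: np.ndarray,
    cov_early: np.ndarray,
    meth_late: np.ndarray,
    cov_late: np.ndarray,
) -> tuple[float, float]:
    """Test one locus: per-sample methylated pseudo-counts and coverages.

    Returns (p_value, meth_diff). The binomial logistic regression on the
    group indicator, weighted by coverage, reduces to the likelihood-ratio
    test of pooled group proportions against a common proportion (χ², 1 df);
    meth_diff is the coverage-weighted mean difference in percentage points
    (late − early).
    """
    cov_early = np.asarray(cov_early, dtype=float)
    cov_late = np.asarray(cov_late, dtype=float)
    if (cov_early < 1).any() or (cov_late < 1).any():
        raise ValueError("every sample needs effective coverage >= 1")
    p, d = _lrt_two_group(
        np.sum(meth_early), cov_early.sum(), np.sum(meth_late), cov_late.sum()
    )
    return float(p), float(d)


def adjust_fdr(p_values: np.ndarray, method: str = "BH") -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-invariant."""
    if method != "BH":
        raise ValueError(f"unsupported FDR method {method!r}")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_dmps(
    meth: MethylationMatrix,
    comparison: Comparison,
    alpha: float = 0.05,
    diff_threshold: float = 25.0,
    fdr_method: str = "BH",
) -> tuple[list[DMPRecord], int]:
    """Test every eligible locus and return significant DMPs plus the tested count.

    Loci with effective coverage < 1 are ineligible. FDR is applied over all
    tested loci; records keep only q < alpha and |meth_diff| >=
    ``diff_threshold`` (percentage points), sorted by (chrom, pos).
    """
    missing = (set(comparison.group_late) | set(comparison.group_early)) - set(
        meth.samples
    )
    if missing:
        raise ValueError(f"comparison samples absent from matrix: {sorted(missing)}")
    eligible = meth.eff_coverage >= 1
    if not eligible.any():
        warnings.warn(f"{comparison.name}: no eligible loci", stacklevel=2)
        return [], 0
    pm = meth.pseudo_meth.loc[eligible]
    late = list(comparison.group_late)
    early = list(comparison.group_early)
    cov = meth.eff_coverage.loc[eligible].to_numpy(dtype=float)
    y_late = pm[late].sum(axis=1).to_numpy(dtype=float)
    y_early = pm[early].sum(axis=1).to_numpy(dtype=float)
    n_late = cov * len(late)
    n_early = cov * len(early)
    pvals, diffs = _lrt_two_group(y_early, n_early, y_late, n_late)
    qvals = adjust_fdr(pvals, method=fdr_method)
    keep = (qvals < alpha) & (np.abs(diffs) >= diff_threshold)
    records = [
        DMPRecord(
            chrom=chrom,
            pos=int(pos),
            comparison=comparison.name,
            meth_diff=float(d),
            p_value=float(p),
            q_value=float(q),
            direction="methylated" if d > 0 else "de-methylated",
        )
        for (chrom, pos), p, q, d in zip(
            pm.index[keep], pvals[keep], qvals[keep], diffs[keep]
        )
    ]
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records, int(eligible.sum())


def summarize_dmps(records: list[DMPRecord]) -> dict[str, int]:
    """Counts of total / de-methylated / methylated DMPs."""
    demeth = sum(1 for r in records if r.direction == "de-methylated")
    return {
        "dmps": len(records),
        "dmps_de_methylated": demeth,
        "dmps_methylated": len(records) - demeth,
    }
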