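"""Synthetic data generation.

Builds random genomes with restriction sites planted at a requested density,
plants per-locus methylation states with clustered differential effects, and
simulates negative-binomial read counts in which methylation suppresses the
cut-site signal (count mean proportional to the unmethylated fraction).

Every stage is seeded and byte-reproducible, so the whole downstream pipeline
can be exercised and scored against known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import RestrictionEnzyme, find_sites, get_enzyme, reverse_complement_iupac

__all__ = [
    "SyntheticDesign",
    "SyntheticTruth",
    "simulate_genome",
    "plant_methylation",
    "simulate_counts",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SyntheticDesign:
    """Experimental layout: bulks × timepoints with per-sample library sizes.

    ``library_sizes`` may be a single expected total read count applied to
    every sample or a mapping sample-id → expected total. Sample ids are
    ``<timepoint>_<bulk>`` and every bulk appears at every timepoint.
    """

    chrom_lengths: tuple[int, ...]
    n_bulks_per_timepoint: int = 5
    timepoints: tuple[str, ...] = ("T0", "T30", "T90")
    library_sizes: float | Mapping[str, float] = 1e6
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths or any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("all chromosome lengths must be > 0")
        if self.n_bulks_per_timepoint < 1:
            raise ValueError("need at least one bulk per timepoint")
        if len(self.timepoints) < 2:
            raise ValueError("need at least two timepoints")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoint labels must be unique")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for sample in self.samples:
            if self.library_size(sample) <= 0:
                raise ValueError(f"library size for {sample} must be > 0")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(
            f"{tp}_{b + 1}"
            for tp in self.timepoints
            for b in range(self.n_bulks_per_timepoint)
        )

    def sample_bulk(self, sample: str) -> int:
        return int(sample.rsplit("_", 1)[1])

    def sample_timepoint(self, sample: str) -> str:
        return sample.rsplit("_", 1)[0]

    def library_size(self, sample: str) -> float:
        if isinstance(self.library_sizes, Mapping):
            return float(self.library_sizes[sample])
        return float(self.library_sizes)

    def to_frame(self) -> pd.DataFrame:
        """Design table: sample, bulk, timepoint, library_size."""
        rows = [
            {
                "sample": s,
                "bulk": self.sample_bulk(s),
                "timepoint": self.sample_timepoint(s),
                "library_size": self.library_size(s),
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows).set_index("sample")


@dataclass
class SyntheticTruth:
    """Planted ground truth: locus registry, methylation states, clusters."""

    loci: list[tuple[str, int]]
    samples: tuple[str, ...]
    locus_propensity: np.ndarray  # (n_loci,)
    methylation_state: np.ndarray  # (n_loci, n_samples) in [0, 1]
    differential_loci: dict[int, tuple[str, float]]  # idx -> (direction, delta)
    cluster_spans: list[tuple[str, int, int, str]]  # chrom, start, end, direction

    def __post_init__(self) -> None:
        m = np.asarray(self.methylation_state, dtype=float)
        if m.min() < 0 or m.max() > 1:
            raise ValueError("methylation_state must lie in [0, 1]")
        if (self.locus_propensity <= 0).any():
            raise ValueError("locus propensities must be positive")


def _site_patterns(enzyme: RestrictionEnzyme) -> list[str]:
    pats = [enzyme.recognition]
    rc = reverse_complement_iupac(enzyme.recognition)
    if rc != enzyme.recognition:
        pats.append(rc)
    return pats


def _find_pattern_spans(seq: str, patterns: Sequence[str]) -> list[tuple[int, int]]:
    import re

    from .digest import IUPAC_CODES

    spans = []
    for pat in patterns:
        k = len(pat)
        body = "".join(f"[{IUPAC_CODES[c]}]" for c in pat)
        for m in re.finditer(f"(?=({body}))", seq):
            spans.append((m.start(), m.start() + k))
    return spans


def _scrub_sites(
    seq: np.ndarray,
    patterns: Sequence[str],
    protected: np.ndarray,
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> None:
    """Mutate bases (outside protected spans) until no pattern matches remain.

    A spurious match entirely inside protected territory — possible at the
    junction of two planted sites — is left alone; such residues are the
    documented random-chance exception.
    """
    text = seq.tobytes().decode()
    for _ in range(max_rounds):
        dirty = False
        for start, end in _find_pattern_spans(text, patterns):
            free = [i for i in range(start, end) if not protected[i]]
            if not free:
                continue
            i = int(rng.choice(free))
            old = text[i]
            choices = [b for b in "ACGT" if b != old]
            text = text[:i] + str(rng.choice(choices)) + text[i + 1 :]
            dirty = True
        if not dirty:
            break
    seq[:] = np.frombuffer(text.encode(), dtype="S1")


def simulate_genome(
    design: SyntheticDesign,
    site_density: float,
    ms_enzyme: RestrictionEnzyme | str = "AciI",
    companion: RestrictionEnzyme | str = "MseI",
    companion_density: float | None = None,
    scrub_enzymes: Sequence[RestrictionEnzyme | str] = (),
) -> tuple[dict[str, str], list[tuple[str, int]]]:
    """Random genome with recognition sites planted at ``site_density`` per kbp.

    Returns the genome (chrom → sequence) and the cut positions of the
    methylation-sensitive enzyme (the locus registry). The background is
    scrubbed of accidental recognition sites for both enzymes (plus any
    extra ``scrub_enzymes``, useful for enzyme-ranking fixtures), so planted
    sites are the only ones present apart from rare junction artifacts.
    """
    if site_density < 0 or (companion_density is not None and companion_density < 0):
        raise ValueError("site densities must be >= 0")
    ms = get_enzyme(ms_enzyme) if isinstance(ms_enzyme, str) else ms_enzyme
    comp = get_enzyme(companion) if isinstance(companion, str) else companion
    if companion_density is None:
        companion_density = site_density
    rng = np.random.default_rng(design.seed)
    patterns = _site_patterns(ms) + _site_patterns(comp)
    for extra in scrub_enzymes:
        enz = get_enzyme(extra) if isinstance(extra, str) else extra
        patterns += _site_patterns(enz)

    genome: dict[str, str] = {}
    loci: list[tuple[str, int]] = []
    for chrom, L in zip(design.chrom_names, design.chrom_lengths):
        n_ms = int(round(site_density * L / 1000.0))
        n_comp = int(round(companion_density * L / 1000.0))
        span = max(ms.site_length, comp.site_length)
        if (n_ms + n_comp) * span > L:
            raise ValueError(
                f"{chrom}: requested {n_ms + n_comp} sites of ≤{span} bp "
                f"cannot fit without overlap in {L} bp"
            )
        seq = rng.choice(_BASES, size=L)
        protected = np.zeros(L, dtype=bool)
        _scrub_sites(seq, patterns, protected, rng)

        # choose non-overlapping planting slots for both enzymes at once
        slots: list[tuple[int, RestrictionEnzyme]] = []
        occupied = np.zeros(L, dtype=bool)
        wanted = [(ms, n_ms), (comp, n_comp)]
        for enz, n_sites in wanted:
            k = enz.site_length
            placed = 0
            attempts = 0
            while placed < n_sites:
                attempts += 1
                if attempts > 200 * max(n_sites, 1):
                    raise ValueError(
                        f"{chrom}: site density too high to place {n_sites} "
                        f"non-overlapping {enz.name} sites in {L} bp"
                    )
                start = int(rng.integers(0, L - k + 1))
                if occupied[start : start + k].any():
                    continue
                occupied[start : start + k] = True
                slots.append((start, enz))
                placed += 1
        for start, enz in slots:
            site = enz.recognition  # concrete for the shipped enzymes except BsrFI
            site = "".join(
                c if c in "ACGT" else str(rng.choice(list("ACGT")))
                for c in site
            )
            seq[start : start + enz.site_length] = np.frombuffer(
                site.encode(), dtype="S1"
            )
            protected[start : start + enz.site_length] = True
            if enz.name == ms.name:
                loci.append((chrom, start + ms.cut_offset_top))
        # remove accidental sites created by planting (junctions aside)
        _scrub_sites(seq, patterns, protected, rng)
        genome[chrom] = seq.tobytes().decode()
    loci.sort()
    return genome, loci


def plant_methylation(
    loci: Sequence[tuple[str, int]],
    design: SyntheticDesign,
    baseline: tuple[float, float] = (2.0, 2.0),
    n_differential: int = 0,
    effect_size: float = 0.5,
    cluster_width: int = 400,
    cluster_size: int = 3,
    seed: int | None = None,
    baseline_mode: str = "per-bulk",
    shifted_timepoints: Sequence[str] | None = None,
) -> SyntheticTruth:
    """Draw baseline methylation and plant clustered differential loci.

    Baseline methylation for each locus is drawn once per bulk (or once per
    locus with ``baseline_mode="shared"``) from Beta(*baseline*) and reused at
    every timepoint of that bulk, so non-differential loci are identical
    across timepoints. Differential loci come in clusters of ``cluster_size``
    loci spanning at most ``cluster_width`` bp; each cluster is shifted by
    ``+effect_size`` (direction ``methylated``) or ``-effect_size``
    (``de-methylated``) at the shifted timepoints (default: all but the
    first), truncated to [0, 1].
    """
    if abs(effect_size) > 1:
        raise ValueError("effect size must satisfy |delta| <= 1")
    if n_differential:
        if cluster_size < 2:
            raise ValueError("cluster_size must be >= 2")
        if cluster_width > min(design.chrom_lengths):
            raise ValueError("cluster_width exceeds the shortest chromosome")
        if n_differential % cluster_size:
            raise ValueError(
                f"n_differential={n_differential} is not a multiple of cluster_size={cluster_size}"
            )
    if baseline_mode not in ("per-bulk", "shared"):
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    if shifted_timepoints is None:
        shifted_timepoints = design.timepoints[1:]
    unknown = set(shifted_timepoints) - set(design.timepoints)
    if unknown:
        raise ValueError(f"shifted timepoints not in design: {sorted(unknown)}")

    rng = np.random.default_rng(design.seed if seed is None else seed)
    loci = sorted(loci)
    n_loci = len(loci)
    samples = design.samples
    n_samples = len(samples)
    a, b = baseline

    propensity = rng.lognormal(mean=0.0, sigma=0.25, size=n_loci)
    if baseline_mode == "shared":
        base = rng.beta(a, b, size=(n_loci, 1))
        meth = np.repeat(base, n_samples, axis=1)
    else:
        per_bulk = rng.beta(a, b, size=(n_loci, design.n_bulks_per_timepoint))
        meth = np.empty((n_loci, n_samples))
        for j, s in enumerate(samples):
            meth[:, j] = per_bulk[:, design.sample_bulk(s) - 1]

    differential: dict[int, tuple[str, float]] = {}
    cluster_spans: list[tuple[str, int, int, str]] = []
    if n_differential:
        n_clusters = n_differential // cluster_size
        candidates: list[tuple[int, ...]] = []
        by_chrom: dict[str, list[int]] = {}
        for idx, (chrom, _pos) in enumerate(loci):
            by_chrom.setdefault(chrom, []).append(idx)
        for idxs in by_chrom.values():
            for i in range(len(idxs) - cluster_size + 1):
                run = idxs[i : i + cluster_size]
                if loci[run[-1]][1] - loci[run[0]][1] < cluster_width:
                    candidates.append(tuple(run))
        order = rng.permutation(len(candidates))
        used: set[int] = set()
        chosen: list[tuple[int, ...]] = []
        for ci in order:
            run = candidates[ci]
            if used.isdisjoint(run):
                chosen.append(run)
                used.update(run)
            if len(chosen) == n_clusters:
                break
        if len(chosen) < n_clusters:
            raise ValueError(
                f"cannot host {n_clusters} clusters of {cluster_size} loci within "
                f"{cluster_width} bp: capacity is {len(chosen)} disjoint cluster(s)"
            )
        shifted_cols = [
            j for j, s in enumerate(samples)
            if design.sample_timepoint(s) in shifted_timepoints
        ]
        for run in chosen:
            direction = "methylated" if rng.random() < 0.5 else "de-methylated"
            delta = effect_size if direction == "methylated" else -effect_size
            for idx in run:
                differential[idx] = (direction, delta)
                meth[idx, shifted_cols] = np.clip(meth[idx, shifted_cols] + delta, 0.0, 1.0)
            chrom = loci[run[0]][0]
            start = loci[run[0]][1]
            end = loci[run[-1]][1] + 1
            cluster_spans.append((chrom, start, end, direction))
        cluster_spans.sort()

    return SyntheticTruth(
        loci=list(loci),
        samples=samples,
        locus_propensity=propensity,
        methylation_state=meth,
        differential_loci=differential,
        cluster_spans=cluster_spans,
    )


def simulate_counts(
    truth: SyntheticTruth,
    design: SyntheticDesign,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the locus × sample read-count matrix.

    Counts are negative binomial with mean ``s_j * a_i * (1 - m_ij)`` where
    ``s_j`` is the sample's library scale (expected library size divided by
    the locus count), ``a_i`` the locus propensity and ``m_ij`` the true
    methylation level; ``design.dispersion`` is the NB inverse-size parameter
    (0 degenerates to Poisson). A fully methylated locus is never cut.
    """
    if tuple(truth.samples) != tuple(design.samples):
        raise ValueError("truth and design disagree on the sample set")
    n_loci = len(truth.loci)
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    scale = np.array([design.library_size(s) / n_loci for s in design.samples])
    mean = truth.locus_propensity[:, None] * (1.0 - truth.methylation_state) * scale[None, :]
    alpha = design.dispersion
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    else:
        lam = mean
    counts = rng.poisson(lam)
    index = pd.MultiIndex.from_tuples(truth.loci, names=["chrom", "pos"])
    return pd.DataFrame(counts, index=index, columns=list(design.samples))


def expected_counts(truth: SyntheticTruth, design: SyntheticDesign) -> np.ndarray:
    """Expected value of :func:`simulate_counts` under the generative law."""
    n_loci = len(truth.loci)
    scale = np.array([design.library_size(s) / n_loci for s in design.samples])
    return truth.locus_propensity[:, None] * (1.0 - truth.methylation_state) * scale[None, :]
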