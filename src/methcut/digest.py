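"""In-silico restriction digestion.

Scans nucleotide sequences for enzyme recognition sites (IUPAC-aware, both
strands for non-palindromic enzymes), performs a two-enzyme double digest
producing a gap-free fragment tiling per chromosome, applies the size /
mixed-end selection used by double-digest library preparation, and ranks
candidate methylation-sensitive enzymes by selectable-fragment yield.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RestrictionEnzyme",
    "Fragment",
    "IUPAC_CODES",
    "reverse_complement_iupac",
    "load_enzyme_registry",
    "get_enzyme",
    "find_sites",
    "double_digest",
    "select_fragments",
    "rank_enzymes",
    "TERMINAL",
    "BOTH",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases they match.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: End label for chromosome termini.
TERMINAL = "terminal"
#: End label when both enzymes cut at the same coordinate.
BOTH = "both"


def reverse_complement_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (also works on plain ACGT)."""
    try:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r} in {pattern!r}") from exc


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme defined by recognition pattern and top-strand cut offset.

    ``cut_offset_top`` is the number of bases from the start of the recognition
    site (forward strand) to the cut coordinate.
    """

    name: str
    recognition: str
    cut_offset_top: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        bad = [c for c in rec if c not in IUPAC_CODES]
        if bad:
            raise ValueError(
                f"enzyme {self.name}: invalid IUPAC letter(s) {bad!r} in recognition {rec!r}"
            )
        if not 0 <= self.cut_offset_top <= len(rec):
            raise ValueError(
                f"enzyme {self.name}: cut offset {self.cut_offset_top} outside [0, {len(rec)}]"
            )

    @property
    def palindromic(self) -> bool:
        """True if the recognition pattern equals its own reverse complement."""
        return self.recognition == reverse_complement_iupac(self.recognition)

    @property
    def site_length(self) -> int:
        return len(self.recognition)


@dataclass(frozen=True)
class Fragment:
    """A digest fragment with the enzyme labels of its two termini."""

    chrom: str
    start: int
    end: int
    left_end: str
    right_end: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.chrom}:{self.start}-{self.end} is empty")

    @property
    def length(self) -> int:
        return self.end - self.start


def _parse_registry_lines(lines: Iterable[str], source: str) -> dict[str, RestrictionEnzyme]:
    registry: dict[str, RestrictionEnzyme] = {}
    for i, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "name":  # header
            continue
        if len(parts) < 3:
            raise ValueError(f"{source}:{i}: expected 3 tab-separated fields, got {len(parts)}")
        name, recognition, offset = parts[0], parts[1], int(parts[2])
        if name in registry:
            raise ValueError(f"{source}:{i}: duplicate enzyme {name!r}")
        registry[name] = RestrictionEnzyme(name, recognition, offset)
    return registry


def load_enzyme_registry(path: str | Path | None = None) -> dict[str, RestrictionEnzyme]:
    """Load enzymes from a TSV registry (``name  recognition  cut_offset_top``).

    Without a path, the packaged default registry is used.
    """
    if path is None:
        text = resources.files("methcut.data").joinpath("enzymes.tsv").read_text()
        return _parse_registry_lines(text.splitlines(), "enzymes.tsv")
    p = Path(path)
    return _parse_registry_lines(p.read_text().splitlines(), str(p))


_DEFAULT_REGISTRY: dict[str, RestrictionEnzyme] | None = None


def get_enzyme(name: str) -> RestrictionEnzyme:
    """Look up an enzyme in the packaged registry."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_enzyme_registry()
    try:
        return _DEFAULT_REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(_DEFAULT_REGISTRY))
        raise KeyError(f"unknown enzyme {name!r}; registry has: {known}") from None


def _iupac_regex(pattern: str) -> re.Pattern[str]:
    # lookahead so overlapping matches are all reported
    body = "".join(f"[{IUPAC_CODES[c]}]" for c in pattern)
    return re.compile(f"(?=({body}))")


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Return sorted, deduplicated cut coordinates in ``sequence``.

    Forward-strand matches cut at ``match_start + cut_offset_top``. For
    non-palindromic enzymes the reverse strand is also scanned (by matching
    the reverse-complement pattern on the forward strand); the bottom-strand
    cut is mapped back to the forward axis. Matches containing N never occur
    because N is outside every concrete IUPAC class.
    """
    seq = sequence.upper()
    cuts: set[int] = set()
    for m in _iupac_regex(enzyme.recognition).finditer(seq):
        cuts.add(m.start() + enzyme.cut_offset_top)
    if not enzyme.palindromic:
        rc = reverse_complement_iupac(enzyme.recognition)
        L = enzyme.site_length
        for m in _iupac_regex(rc).finditer(seq):
            cuts.add(m.start() + L - enzyme.cut_offset_top)
    return sorted(cuts)


def double_digest(
    genome: Mapping[str, str],
    ms_enzyme: RestrictionEnzyme,
    companion: RestrictionEnzyme,
) -> list[Fragment]:
    """Digest every chromosome with both enzymes and return the fragment tiling.

    Chromosome ends are labeled ``terminal``; internal boundaries carry the
    name of the cutting enzyme, or ``both`` on a shared cut coordinate.
    Fragments tile each chromosome without gaps or overlaps.
    """
    if ms_enzyme.name == companion.name and ms_enzyme.recognition == companion.recognition:
        raise ValueError("double digest requires two distinct enzymes")
    fragments: list[Fragment] = []
    for chrom, seq in genome.items():
        L = len(seq)
        labels: dict[int, str] = {}
        for enz in (ms_enzyme, companion):
            for cut in find_sites(seq, enz):
                if 0 < cut < L:
                    labels[cut] = BOTH if cut in labels and labels[cut] != enz.name else enz.name
        bounds = sorted(labels)
        edges = [0, *bounds, L]
        names = [TERMINAL, *(labels[b] for b in bounds), TERMINAL]
        for i in range(len(edges) - 1):
            fragments.append(
                Fragment(chrom, edges[i], edges[i + 1], names[i], names[i + 1])
            )
    return fragments


def select_fragments(
    fragments: Iterable[Fragment],
    ms_enzyme: RestrictionEnzyme | str,
    companion: RestrictionEnzyme | str,
    min_len: int = 200,
    max_len: int = 700,
    require_mixed_ends: bool = True,
) -> list[Fragment]:
    """Size selection plus (optionally) the mixed-end capture requirement.

    A mixed-end fragment has one terminus from the methylation-sensitive
    enzyme and one from the companion — the configuration retained by
    double-digest library preparation. An end labeled ``both`` satisfies
    either role.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    ms = ms_enzyme.name if isinstance(ms_enzyme, RestrictionEnzyme) else ms_enzyme
    comp = companion.name if isinstance(companion, RestrictionEnzyme) else companion

    def mixed(frag: Fragment) -> bool:
        ends = (frag.left_end, frag.right_end)
        if TERMINAL in ends:
            return False
        a, b = ends
        return (a in (ms, BOTH) and b in (comp, BOTH)) or (
            a in (comp, BOTH) and b in (ms, BOTH)
        )

    kept = [f for f in fragments if min_len <= f.length <= max_len]
    if require_mixed_ends:
        kept = [f for f in kept if mixed(f)]
    return kept


@dataclass
class EnzymeRanking:
    """Selectable-fragment counts per candidate enzyme, best candidate first."""

    counts: dict[str, int]
    best: str
    tie: bool = field(default=False)


def rank_enzymes(
    genome: Mapping[str, str],
    candidates: Sequence[RestrictionEnzyme],
    companion: RestrictionEnzyme,
    min_len: int = 200,
    max_len: int = 700,
    require_mixed_ends: bool = True,
) -> EnzymeRanking:
    """Rank candidate enzymes by count of size/end-selectable fragments.

    Deterministic: the best enzyme is the argmax count, ties broken
    alphabetically and flagged.
    """
    if not candidates:
        raise ValueError("need at least one candidate enzyme")
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    counts: dict[str, int] = {}
    for enz in candidates:
        frags = double_digest(genome, enz, companion)
        counts[enz.name] = len(
            select_fragments(frags, enz, companion, min_len, max_len, require_mixed_ends)
        )
    top = max(counts.values())
    winners = sorted(name for name, c in counts.items() if c == top)
    return EnzymeRanking(counts=counts, best=winners[0], tie=len(winners) > 1)
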