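"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (per-substring scans, explicit
enumeration, direct probability-mass summation) and shares no code with the
implementations under test.
"""

from __future__ import annotations

from math import comb

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_cuts(seq: str, recognition: str, offset: int) -> set[int]:
    """Every cut coordinate from testing all substrings on both strands."""
    k = len(recognition)
    rc = "".join(
        {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}[c] for c in reversed(recognition)
    )
    cuts: set[int] = set()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if all(b in IUPAC[p] for b, p in zip(window, recognition)):
            cuts.add(i + offset)
        if rc != recognition and all(b in IUPAC[p] for b, p in zip(window, rc)):
            cuts.add(i + k - offset)
    return cuts


def brute_force_fragment_bounds(seq: str, enzymes: list[tuple[str, int]]) -> list[int]:
    """Sorted internal fragment boundaries of a multi-enzyme digest."""
    cuts: set[int] = set()
    for recognition, offset in enzymes:
        cuts |= brute_force_cuts(seq, recognition, offset)
    return sorted(c for c in cuts if 0 < c < len(seq))


def bh_stepup(pvals: list[float]) -> list[float]:
    """Textbook Benjamini–Hochberg step-up, O(m^2)."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = indexed[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = min(val, 1.0)
        prev = q[i]
    return q


def brute_force_dmrs(
    dmps: list[tuple[str, int, str]],
    width: int,
    chrom_lengths: dict[str, int],
    phase: int = 0,
) -> list[tuple[str, int, int, str, int, int]]:
    """Enumerate every tile of every chromosome and apply the concordance rule.

    Returns (chrom, start, end, direction, n_concordant, n_discordant).
    """
    out = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        start = phase
        while start < L:
            end = min(start + width, L)
            inside = [d for d in dmps if d[0] == chrom and start <= d[1] < end]
            n_meth = sum(1 for d in inside if d[2] == "methylated")
            n_dem = sum(1 for d in inside if d[2] == "de-methylated")
            if max(n_meth, n_dem) >= 2 and n_meth != n_dem:
                if n_meth > n_dem:
                    out.append((chrom, start, end, "methylated", n_meth, n_dem))
                else:
                    out.append((chrom, start, end, "de-methylated", n_dem, n_meth))
            start += width
    return out


def allpairs_gene_hits(
    dmrs: list[tuple[str, int, int]],
    genes: list[tuple[str, str, int, int, str]],
    extension: int,
    chrom_lengths: dict[str, int] | None = None,
) -> set[tuple[int, str, str]]:
    """All-pairs overlap check. Returns {(dmr_index, gene_id, site)}.

    Genes are (gene_id, chrom, start, end, strand); promoter-style minus
    policy; body precedence.
    """
    hits = set()
    for di, (dchrom, dstart, dend) in enumerate(dmrs):
        for gid, gchrom, gstart, gend, strand in genes:
            if gchrom != dchrom:
                continue
            body = min(gend, dend) - max(gstart, dstart)
            if strand == "+":
                rlo, rhi = gstart - extension, gstart
            else:
                rlo, rhi = gend, gend + extension
            rlo = max(rlo, 0)
            if chrom_lengths is not None:
                rhi = min(rhi, chrom_lengths[gchrom])
            reg = min(rhi, dend) - max(rlo, dstart) if rlo < rhi else 0
            if body >= 1:
                hits.add((di, gid, "body"))
            elif reg >= 1:
                hits.add((di, gid, "regulatory"))
    return hits


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric mass."""
    denom = comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x) * comb(N - K, n - x)
    return total / denom
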