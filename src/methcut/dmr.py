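"""Window-based differentially methylated region (DMR) calling.

Chromosomes are tiled with adjacent fixed-width windows; a window holding at
least two direction-concordant significant DMPs becomes a DMR. The window
width is chosen by scanning a grid (default 100–2000 bp in 100 bp steps) and
keeping the width that maximizes the DMR count, smallest width on ties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dmp import DMPRecord

__all__ = [
    "DMRRecord",
    "WidthScan",
    "tile_windows",
    "call_dmrs_at_width",
    "optimize_width",
    "summarize_dmrs",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DMRRecord:
    chrom: str
    start: int
    end: int
    comparison: str
    direction: str
    n_dmps_concordant: int
    n_dmps_discordant: int
    members: tuple[DMPRecord, ...]

    def __post_init__(self) -> None:
        if self.n_dmps_concordant < 2:
            raise ValueError("a DMR needs at least two concordant DMPs")
        for m in self.members:
            if not (self.start <= m.pos < self.end):
                raise ValueError(
                    f"member DMP {m.chrom}:{m.pos} outside window "
                    f"[{self.start}, {self.end})"
                )

    @property
    def span(self) -> tuple[int, int]:
        """Min/max member-DMP span (half-open), tighter than the window."""
        positions = [m.pos for m in self.members]
        return min(positions), max(positions) + 1


@dataclass
class WidthScan:
    widths: list[int]
    dmr_counts: list[int]
    chosen_width: int
    tie: bool = field(default=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"width": self.widths, "n_dmrs": self.dmr_counts})


def tile_windows(chrom_length: int, width: int, phase: int = 0) -> list[tuple[int, int]]:
    """Adjacent non-overlapping windows covering [phase, chrom_length)."""
    if width <= 0:
        raise ValueError("window width must be > 0")
    if not 0 <= phase < max(chrom_length, 1):
        raise ValueError("phase must lie within the chromosome")
    windows = []
    start = phase
    while start < chrom_length:
        windows.append((start, min(start + width, chrom_length)))
        start += width
    return windows


def call_dmrs_at_width(
    dmps: Sequence[DMPRecord],
    width: int,
    chrom_lengths: Mapping[str, int],
    phase: int = 0,
) -> list[DMRRecord]:
    """Call DMRs on a fixed-width tiling.

    Each DMP falls in exactly one tile. A tile with >= 2 DMPs of the majority
    direction yields a DMR; an exact direction tie with both counts >= 2 is
    skipped and logged. Assumes the DMP list is already FDR/threshold
    filtered.
    """
    if width <= 0:
        raise ValueError("window width must be > 0")
    by_tile: dict[tuple[str, int], list[DMPRecord]] = {}
    for dmp in dmps:
        if dmp.chrom not in chrom_lengths:
            raise ValueError(f"DMP chromosome {dmp.chrom!r} has no known length")
        L = chrom_lengths[dmp.chrom]
        if not 0 <= dmp.pos < L:
            raise ValueError(f"DMP {dmp.chrom}:{dmp.pos} beyond chromosome length {L}")
        if dmp.pos < phase:
            continue
        tile = (dmp.pos - phase) // width
        by_tile.setdefault((dmp.chrom, tile), []).append(dmp)
    records: list[DMRRecord] = []
    for (chrom, tile), members in sorted(by_tile.items()):
        meth = [m for m in members if m.direction == "methylated"]
        demeth = [m for m in members if m.direction == "de-methylated"]
        n_meth, n_demeth = len(meth), len(demeth)
        if max(n_meth, n_demeth) < 2:
            continue
        if n_meth == n_demeth:
            log.info(
                "skipping tied window %s:[%d,%d) with %d DMPs per direction",
                chrom, phase + tile * width, phase + (tile + 1) * width, n_meth,
            )
            continue
        if n_meth > n_demeth:
            direction, concordant, discordant = "methylated", meth, demeth
        else:
            direction, concordant, discordant = "de-methylated", demeth, meth
        start = phase + tile * width
        end = min(start + width, chrom_lengths[chrom])
        comparison = members[0].comparison
        records.append(
            DMRRecord(
                chrom=chrom,
                start=start,
                end=end,
                comparison=comparison,
                direction=direction,
                n_dmps_concordant=len(concordant),
                n_dmps_discordant=len(discordant),
                members=tuple(sorted(concordant, key=lambda m: m.pos)),
            )
        )
    records.sort(key=lambda r: (r.chrom, r.start))
    return records


def optimize_width(
    dmps: Sequence[DMPRecord],
    chrom_lengths: Mapping[str, int],
    widths: Iterable[int] = range(100, 2001, 100),
    phase: int = 0,
) -> tuple[WidthScan, list[DMRRecord]]:
    """Scan window widths and keep the one maximizing the DMR count.

    Ties go to the smallest width and are flagged. With no DMPs the scan is
    all zeros, the smallest width is chosen and a warning is raised.
    """
    widths = sorted(set(int(w) for w in widths))
    if not widths:
        raise ValueError("width grid must be non-empty")
    if not dmps:
        warnings.warn("no DMPs: width scan degenerates to zeros", stacklevel=2)
        return WidthScan(widths, [0] * len(widths), widths[0], tie=True), []
    results = {w: call_dmrs_at_width(dmps, w, chrom_lengths, phase) for w in widths}
    counts = [len(results[w]) for w in widths]
    best = max(counts)
    winners = [w for w, c in zip(widths, counts) if c == best]
    chosen = winners[0]
    scan = WidthScan(widths, counts, chosen, tie=len(winners) > 1)
    return scan, results[chosen]


def summarize_dmrs(
    dmps_by_comparison: Mapping[str, Sequence[DMPRecord]],
    dmrs_by_comparison: Mapping[str, Sequence[DMRRecord]],
) -> pd.DataFrame:
    """Per-comparison DMP/DMR counts split by direction, plus a Total row."""
    rows = []
    for name in dmps_by_comparison:
        dmps = dmps_by_comparison[name]
        dmrs = dmrs_by_comparison.get(name, [])
        rows.append(
            {
                "comparison": name,
                "dmps": len(dmps),
                "dmps_de_methylated": sum(d.direction == "de-methylated" for d in dmps),
                "dmps_methylated": sum(d.direction == "methylated" for d in dmps),
                "dmrs": len(dmrs),
                "dmrs_de_methylated": sum(r.direction == "de-methylated" for r in dmrs),
                "dmrs_methylated": sum(r.direction == "methylated" for r in dmrs),
            }
        )
    columns = [
        "comparison",
        "dmps", "dmps_de_methylated", "dmps_methylated",
        "dmrs", "dmrs_de_methylated", "dmrs_methylated",
    ]
    table = pd.DataFrame(rows, columns=columns).set_index("comparison")
    table.loc["Total"] = table.sum(axis=0)
    return table.astype(int)
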