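"""DMR-to-gene assignment.

Loads gene models from GFF3 or BED, derives strand-aware regulatory
extensions (2.5 kb beyond the transcription-orientation 5' end by default)
and intersects DMR intervals with gene bodies and regulatory regions.
Internal coordinates are 0-based half-open; GFF3 input (1-based inclusive)
is converted on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence
from urllib.parse import unquote

import numpy as np
import pandas as pd

from .dmr import DMRRecord

__all__ = [
    "GeneModel",
    "GeneHit",
    "load_annotation",
    "regulatory_interval",
    "intersect_dmrs",
    "gene_table",
]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open body span
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: empty span [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")


@dataclass(frozen=True)
class GeneHit:
    gene_id: str
    dmr: DMRRecord
    site: str  # "body" | "regulatory"
    direction: str
    comparison: str


def _gff3_attributes(raw: str) -> dict[str, str]:
    out = {}
    for item in raw.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = unquote(value.strip())
    return out


def load_annotation(path: str | Path, fmt: str = "gff3") -> list[GeneModel]:
    """Read gene models. GFF3 keeps only ``gene`` features; BED is taken as-is.

    Duplicate gene ids are a hard error; malformed lines are reported with
    their line number.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    fmt = fmt.lower()
    if fmt not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if fmt == "gff3":
                if len(fields) < 9:
                    raise ValueError(f"expected 9 columns, got {len(fields)}")
                if fields[2] != "gene":
                    continue
                attrs = _gff3_attributes(fields[8])
                gene_id = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
                if not gene_id:
                    raise ValueError("gene feature without ID/gene_id/Name attribute")
                gene_id = gene_id.removeprefix("gene:")
                start = int(fields[3]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(fields[4])
                strand = fields[6]
            else:
                if len(fields) < 6:
                    raise ValueError(f"BED needs 6 columns (name/strand), got {len(fields)}")
                gene_id = fields[3]
                start = int(fields[1])
                end = int(fields[2])
                strand = fields[5]
            if gene_id in seen:
                raise ValueError(f"duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, fields[0], start, end, strand))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return genes


def regulatory_interval(
    gene: GeneModel,
    extension: int = 2500,
    chrom_length: int | None = None,
    minus_policy: str = "promoter",
) -> tuple[int, int] | None:
    """Regulatory extension anchored at the transcription-orientation 5' end.

    ``+`` genes get [start − extension, start). For ``-`` genes the default
    ``promoter`` policy mirrors that upstream-of-TSS logic onto the
    higher-coordinate end, [end, end + extension); the ``literal`` policy
    instead takes the interval below the gene's lower coordinate. Intervals
    are clipped to [0, chrom_length) and None is returned when clipping
    leaves nothing.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    if extension == 0:
        return None
    if gene.strand == "+":
        lo, hi = gene.start - extension, gene.start
    elif minus_policy == "promoter":
        lo, hi = gene.end, gene.end + extension
    elif minus_policy == "literal":
        lo, hi = gene.start - extension, gene.start
    else:
        raise ValueError(f"unknown minus_policy {minus_policy!r}")
    lo = max(lo, 0)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    if lo >= hi:
        return None
    return lo, hi


def intersect_dmrs(
    dmrs: Sequence[DMRRecord],
    genes: Sequence[GeneModel],
    extension: int = 2500,
    chrom_lengths: Mapping[str, int] | None = None,
    min_overlap: int = 1,
    minus_policy: str = "promoter",
) -> tuple[list[GeneHit], list[DMRRecord]]:
    """Overlap DMRs with gene bodies and regulatory extensions.

    A DMR overlapping both the body and the regulatory interval of the same
    gene is reported once with site ``body`` (body precedence). One DMR may
    hit several genes and vice versa; DMRs hitting nothing (including those
    on chromosomes absent from the annotation, which trigger a warning) are
    returned unassigned.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[GeneModel]]] = {}
    for chrom, glist in by_chrom.items():
        L = chrom_lengths.get(chrom) if chrom_lengths else None
        body_lo = np.array([g.start for g in glist])
        body_hi = np.array([g.end for g in glist])
        reg = [regulatory_interval(g, extension, L, minus_policy) for g in glist]
        reg_lo = np.array([r[0] if r else -1 for r in reg])
        reg_hi = np.array([r[1] if r else -1 for r in reg])
        arrays[chrom] = (body_lo, body_hi, reg_lo, reg_hi, glist)

    hits: list[GeneHit] = []
    unassigned: list[DMRRecord] = []
    warned: set[str] = set()
    for dmr in dmrs:
        if dmr.chrom not in arrays:
            if dmr.chrom not in warned:
                warnings.warn(
                    f"chromosome {dmr.chrom!r} absent from annotation; DMRs left unassigned",
                    stacklevel=2,
                )
                warned.add(dmr.chrom)
            unassigned.append(dmr)
            continue
        body_lo, body_hi, reg_lo, reg_hi, glist = arrays[dmr.chrom]
        body_ov = np.minimum(body_hi, dmr.end) - np.maximum(body_lo, dmr.start)
        reg_ov = np.where(
            reg_lo >= 0,
            np.minimum(reg_hi, dmr.end) - np.maximum(reg_lo, dmr.start),
            0,
        )
        matched = False
        for j in np.flatnonzero((body_ov >= min_overlap) | (reg_ov >= min_overlap)):
            site = "body" if body_ov[j] >= min_overlap else "regulatory"
            hits.append(
                GeneHit(
                    gene_id=glist[j].gene_id,
                    dmr=dmr,
                    site=site,
                    direction=dmr.direction,
                    comparison=dmr.comparison,
                )
            )
            matched = True
        if not matched:
            unassigned.append(dmr)
    return hits, unassigned


def gene_directions(hits: Sequence[GeneHit]) -> dict[str, str]:
    """Per-gene direction over a hit collection; both directions → ``mixed``."""
    dirs: dict[str, set[str]] = {}
    for h in hits:
        dirs.setdefault(h.gene_id, set()).add(h.direction)
    return {g: (next(iter(d)) if len(d) == 1 else "mixed") for g, d in dirs.items()}


def gene_table(hits: Sequence[GeneHit], comparisons: Sequence[str]) -> pd.DataFrame:
    """Per-comparison differentially methylated gene counts plus a union row.

    Mixed-direction genes count toward the gene total but toward neither
    direction column.
    """
    rows = []
    all_hits = list(hits)
    for name in ["All", *comparisons]:
        sub = all_hits if name == "All" else [h for h in all_hits if h.comparison == name]
        dirs = gene_directions(sub)
        rows.append(
            {
                "comparison": name,
                "n_genes": len(dirs),
                "n_de_methylated": sum(d == "de-methylated" for d in dirs.values()),
                "n_methylated": sum(d == "methylated" for d in dirs.values()),
                "n_mixed": sum(d == "mixed" for d in dirs.values()),
            }
        )
    return pd.DataFrame(rows).set_index("comparison")
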