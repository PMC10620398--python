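"""Readers and writers for the plain-text formats used across the pipeline.

Counts TSV: ``chrom  pos  <sample>...``; design TSV: ``sample  bulk
timepoint  library_size``; methylation TSV (long): ``chrom  pos  sample
meth_level  coverage``; BED intervals are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .counts import MethylationMatrix
from .dmp import DMPRecord
from .dmr import DMRRecord, WidthScan
from .genemap import GeneHit


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.reset_index().to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df.set_index(["chrom", "pos"])


def write_design_tsv(design: pd.DataFrame, path: str | Path) -> None:
    design.reset_index().to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "timepoint": str}).set_index(
        "sample"
    )


def write_cluster_bed(
    spans: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, direction in spans:
            fh.write(f"{chrom}\t{start}\t{end}\t{direction}\n")


def write_meth_tsv(meth: MethylationMatrix, path: str | Path) -> None:
    long = (
        meth.meth_level.stack()
        .rename("meth_level")
        .reset_index()
        .rename(columns={"level_2": "sample"})
    )
    cov = meth.eff_coverage.reset_index().rename(columns={"eff_coverage": "coverage"})
    long = long.merge(cov, on=["chrom", "pos"])
    long.to_csv(path, sep="\t", index=False)


def write_dmp_tsv(records: Sequence[DMPRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "comparison": r.comparison,
            "meth_diff": r.meth_diff,
            "pvalue": r.p_value,
            "qvalue": r.q_value,
            "direction": r.direction,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "comparison", "meth_diff", "pvalue", "qvalue", "direction"],
    ).to_csv(path, sep="\t", index=False)


def read_dmp_tsv(path: str | Path) -> list[DMPRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        DMPRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            comparison=row.comparison,
            meth_diff=float(row.meth_diff),
            p_value=float(row.pvalue),
            q_value=float(row.qvalue),
            direction=row.direction,
        )
        for row in df.itertuples()
    ]


def write_dmr_bed(records: Sequence[DMRRecord], path: str | Path) -> None:
    """BED6+: name = comparison:direction, score = concordant DMP count,
    extra columns carry the member-DMP span."""
    with open(path, "w") as fh:
        for r in records:
            span_lo, span_hi = r.span
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.comparison}:{r.direction}\t"
                f"{r.n_dmps_concordant}\t.\t{span_lo}\t{span_hi}\t{r.n_dmps_discordant}\n"
            )


def read_dmr_bed(path: str | Path) -> list[DMRRecord]:
    """Read the BED6+ written by :func:`write_dmr_bed`.

    Member DMPs are reconstructed minimally (position and direction only) —
    enough for downstream interval work.
    """
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ValueError(f"{path}:{lineno}: expected 9 BED columns, got {len(fields)}")
        chrom, start, end, name, score, _strand, span_lo, span_hi, n_disc = fields[:9]
        comparison, _, direction = name.rpartition(":")
        n_conc = int(score)
        lo, hi = int(span_lo), int(span_hi)
        members = tuple(
            DMPRecord(chrom, pos, comparison, 0.0, 0.0, 0.0, direction)
            for pos in ([lo] * (n_conc - 1) + [hi - 1])
        )
        records.append(
            DMRRecord(
                chrom=chrom,
                start=int(start),
                end=int(end),
                comparison=comparison,
                direction=direction,
                n_dmps_concordant=n_conc,
                n_dmps_discordant=int(n_disc),
                members=members,
            )
        )
    return records


def write_width_scan_tsv(scan: WidthScan, path: str | Path) -> None:
    df = scan.to_frame()
    df["chosen"] = df["width"] == scan.chosen_width
    df.to_csv(path, sep="\t", index=False)


def write_gene_hits_tsv(hits: Sequence[GeneHit], path: str | Path) -> None:
    rows = [
        {
            "gene_id": h.gene_id,
            "chrom": h.dmr.chrom,
            "dmr_start": h.dmr.start,
            "dmr_end": h.dmr.end,
            "comparison": h.comparison,
            "direction": h.direction,
            "site": h.site,
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "dmr_start", "dmr_end", "comparison", "direction", "site"],
    ).to_csv(path, sep="\t", index=False)
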