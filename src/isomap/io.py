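"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open.  The isochore and gene TSV
dialects written here round-trip exactly; CCDS-style gene tables with
1-based inclusive coordinates are converted at this boundary.  SAM uses
pysam (POS is 1-based in the file, converted on read/write); BED is
0-based half-open already.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .genome import FamilyThresholds, DEFAULT_THRESHOLDS, GeneModel, Isochore
from .simulate import AlignmentRecord

logger = logging.getLogger(__name__)

ISOCHORE_COLUMNS = ["name", "chrom", "start", "end", "GC"]
GENE_COLUMNS = ["ccds_id", "chrom", "strand", "exons", "first_codon"]


def write_isochore_table(isochores: Sequence[Isochore], path: str | Path) -> None:
    """Isochore map as TSV: name, chrom, start, end (0-based half-open), GC%."""
    df = pd.DataFrame(
        {
            "name": [i.name for i in isochores],
            "chrom": [i.chrom for i in isochores],
            "start": [i.start for i in isochores],
            "end": [i.end for i in isochores],
            "GC": [i.gc for i in isochores],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_isochore_table(
    path: str | Path, thresholds: FamilyThresholds = DEFAULT_THRESHOLDS
) -> list[Isochore]:
    df = pd.read_csv(path, sep="\t")
    missing = set(ISOCHORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"isochore table {path}: missing columns {sorted(missing)}")
    return [
        Isochore(
            name=str(r["name"]),
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            gc=float(r["GC"]),
            thresholds=thresholds,
        )
        for _, r in df.iterrows()
    ]


def _format_exons(exons: Iterable[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in exons)


def _parse_exons(text: str, one_based_inclusive: bool = False) -> tuple[tuple[int, int], ...]:
    exons = []
    for part in str(text).strip("[] ").split(","):
        s, e = part.strip().split("-")
        s, e = int(s), int(e)
        if one_based_inclusive:
            s, e = s - 1, e  # [s, e] 1-based -> [s-1, e) 0-based
        exons.append((s, e))
    return tuple(exons)


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Gene models as TSV mirroring the CCDS columns used: id, chrom, strand,
    exon list "start-end,start-end" (0-based half-open), first codon."""
    df = pd.DataFrame(
        {
            "ccds_id": [g.ccds_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "exons": [_format_exons(g.exons) for g in genes],
            "first_codon": [g.first_codon or "" for g in genes],
            "GC_ccds": [g.gc for g in genes],
            "GC3_ccds": [g.gc3 for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_table(
    path: str | Path, one_based_inclusive: bool = False
) -> list[GeneModel]:
    """Read a gene TSV.  Set ``one_based_inclusive`` for CCDS-style tables
    whose exon coordinates are 1-based inclusive."""
    df = pd.read_csv(path, sep="\t")
    missing = {"ccds_id", "chrom", "strand", "exons"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path}: missing columns {sorted(missing)}")
    genes = []
    for _, r in df.iterrows():
        genes.append(
            GeneModel(
                ccds_id=str(r["ccds_id"]),
                chrom=str(r["chrom"]),
                strand=str(r["strand"]),
                exons=_parse_exons(r["exons"], one_based_inclusive),
                gc=float(r["GC_ccds"]) if "GC_ccds" in df.columns else float("nan"),
                gc3=float(r["GC3_ccds"]) if "GC3_ccds" in df.columns else float("nan"),
                first_codon=(
                    str(r["first_codon"])
                    if "first_codon" in df.columns and pd.notna(r["first_codon"])
                    and str(r["first_codon"])
                    else None
                ),
            )
        )
    return genes


def write_sam(
    reads: Sequence[AlignmentRecord],
    chrom_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Minimal single-end SAM: one mapped record per read, CIGAR "<len>M"."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, read in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i:08d}"
            a.flag = 0
            a.reference_id = out.header.get_tid(read.chrom)
            a.reference_start = read.pos
            a.mapping_quality = 255
            a.cigarstring = f"{read.length}M"
            out.write(a)


def read_sam(path: str | Path, tissue: str) -> list[AlignmentRecord]:
    """Read mapped primary alignments from SAM/BAM; unmapped and secondary
    records are skipped (with a logged count)."""
    reads: list[AlignmentRecord] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as f:
        for a in f:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                skipped += 1
                continue
            length = a.query_length or a.infer_query_length() or 0
            if not length and a.cigartuples:
                length = sum(n for op, n in a.cigartuples if op in (0, 7, 8))
            if length < 1 or a.reference_start is None or a.reference_start < 0:
                skipped += 1
                continue
            reads.append(
                AlignmentRecord(a.reference_name, a.reference_start, length, tissue)
            )
    if skipped:
        logger.info("read_sam %s: skipped %d unmapped/secondary records", path, skipped)
    return reads


def write_bed(reads: Sequence[AlignmentRecord], path: str | Path) -> None:
    """Reads as 6-column BED (chrom, start, end, name, score, strand)."""
    with open(path, "w") as out:
        for i, r in enumerate(reads):
            out.write(f"{r.chrom}\t{r.pos}\t{r.pos + r.length}\tr{i:08d}\t0\t+\n")


def read_bed(path: str | Path, tissue: str) -> list[AlignmentRecord]:
    reads: list[AlignmentRecord] = []
    skipped = 0
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                skipped += 1
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                skipped += 1
                continue
            if end <= start or start < 0:
                skipped += 1
                continue
            reads.append(AlignmentRecord(parts[0], start, end - start, tissue))
    if skipped:
        logger.info("read_bed %s: skipped %d malformed lines", path, skipped)
    return reads


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    """Plain FASTA writer for the optional synthetic sequences."""
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    """Expression tables as TSV; undefined (NaN) levels become empty fields."""
    df.to_csv(path, sep="\t", na_rep="")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
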