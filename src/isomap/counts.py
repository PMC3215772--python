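"""Assignment of aligned reads to isochores and coding sequences.

A read is assigned by its leftmost mapped base alone: the isochore whose
half-open interval contains that base gets the read, and every CDS with an
exon containing that base gets it too (overlapping CDSs all count the read,
but the per-tissue total of reads in coding sequences counts it once).
Reads falling in assembly gaps or on chromosomes absent from the isochore
map still count toward the per-tissue total.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GeneModel, Isochore
from .simulate import AlignmentRecord

logger = logging.getLogger(__name__)


class IsochoreIndex:
    """Sorted-array point lookup over a non-overlapping isochore map."""

    def __init__(self, isochores: Sequence[Isochore]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._names: dict[str, list[str]] = {}
        by_chrom: dict[str, list[Isochore]] = defaultdict(list)
        for iso in isochores:
            by_chrom[iso.chrom].append(iso)
        for chrom, isos in by_chrom.items():
            isos.sort(key=lambda i: i.start)
            for a, b in zip(isos, isos[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"isochores {a.name} and {b.name} overlap on {chrom}"
                    )
            self._starts[chrom] = np.array([i.start for i in isos])
            self._ends[chrom] = np.array([i.end for i in isos])
            self._names[chrom] = [i.name for i in isos]

    def locate(self, chrom: str, pos: int) -> str | None:
        """Name of the isochore containing (chrom, pos), or None."""
        starts = self._starts.get(chrom)
        if starts is None:
            return None
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < self._ends[chrom][i]:
            return self._names[chrom][i]
        return None

    def locate_many(self, chrom: str, positions: np.ndarray) -> list[str | None]:
        starts = self._starts.get(chrom)
        if starts is None:
            return [None] * len(positions)
        idx = np.searchsorted(starts, positions, side="right") - 1
        names = self._names[chrom]
        ends = self._ends[chrom]
        return [
            names[i] if i >= 0 and p < ends[i] else None
            for i, p in zip(idx, positions)
        ]


class ExonIndex:
    """Interval-tree lookup from a genomic point to the CDSs whose exons
    contain it (several, when CDSs overlap)."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for gene in genes:
            for s, e in gene.exons:
                self._trees[gene.chrom][s:e] = gene.ccds_id

    def genes_at(self, chrom: str, pos: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree[pos])


@dataclass
class CountTable:
    """Per-isochore and per-CDS read counts, with per-tissue totals.

    ``total_reads`` is the per-tissue count of aligned reads (R_t of the
    isochore-level normalization); ``total_cds_reads`` is the per-tissue
    count of reads whose leftmost base lies in at least one CDS exon (R't of
    the genic normalization).
    """

    isochore_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    cds_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    total_reads: dict[str, int] = field(default_factory=dict)
    total_cds_reads: dict[str, int] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)
    skipped: dict[str, int] = field(default_factory=dict)

    @property
    def tissues(self) -> list[str]:
        return sorted(self.total_reads)

    def isochore_frame(self, isochores: Sequence[Isochore]) -> pd.DataFrame:
        """Counts as a DataFrame indexed by isochore name, one column per
        tissue, zero-filled."""
        idx = [iso.name for iso in isochores]
        df = pd.DataFrame(0, index=idx, columns=self.tissues, dtype=int)
        for tissue, counts in self.isochore_counts.items():
            for name, n in counts.items():
                if name in df.index:
                    df.loc[name, tissue] = n
        return df

    def cds_frame(self, genes: Sequence[GeneModel]) -> pd.DataFrame:
        idx = [g.ccds_id for g in genes]
        df = pd.DataFrame(0, index=idx, columns=self.tissues, dtype=int)
        for tissue, counts in self.cds_counts.items():
            for name, n in counts.items():
                if name in df.index:
                    df.loc[name, tissue] = n
        return df


def count_reads_per_isochore(
    reads: Iterable[AlignmentRecord],
    isochores: Sequence[Isochore],
    index: IsochoreIndex | None = None,
) -> CountTable:
    """Count reads per isochore by leftmost-base containment.

    Each read increments exactly one isochore (half-open intervals: a read at
    an isochore's end coordinate belongs to the next one).  Reads in gaps or
    on unknown chromosomes count only toward the tissue total.
    """
    index = index or IsochoreIndex(isochores)
    table = CountTable()
    for read in reads:
        tissue = read.tissue
        table.total_reads[tissue] = table.total_reads.get(tissue, 0) + 1
        name = index.locate(read.chrom, read.pos)
        if name is None:
            table.unassigned[tissue] = table.unassigned.get(tissue, 0) + 1
            continue
        table.isochore_counts.setdefault(tissue, {})
        table.isochore_counts[tissue][name] = (
            table.isochore_counts[tissue].get(name, 0) + 1
        )
    return table


def count_reads_per_cds(
    reads: Iterable[AlignmentRecord],
    genes: Sequence[GeneModel],
    index: ExonIndex | None = None,
) -> CountTable:
    """Count reads per CDS by leftmost-base exon containment.

    A read inside exons of k overlapping CDSs increments all k, but the
    per-tissue total of reads aligned to coding sequences (R't) counts it
    once.
    """
    index = index or ExonIndex(genes)
    table = CountTable()
    for read in reads:
        tissue = read.tissue
        table.total_reads[tissue] = table.total_reads.get(tissue, 0) + 1
        hits = index.genes_at(read.chrom, read.pos)
        if not hits:
            continue
        table.total_cds_reads[tissue] = table.total_cds_reads.get(tissue, 0) + 1
        counts = table.cds_counts.setdefault(tissue, {})
        for ccds_id in hits:
            counts[ccds_id] = counts.get(ccds_id, 0) + 1
    return table


def build_count_table(
    reads_by_tissue: dict[str, Iterable[AlignmentRecord]],
    isochores: Sequence[Isochore],
    genes: Sequence[GeneModel],
) -> CountTable:
    """Run both assignments over per-tissue read sets and merge the results."""
    iso_index = IsochoreIndex(isochores)
    exon_index = ExonIndex(genes)
    table = CountTable()
    for tissue, reads in reads_by_tissue.items():
        reads = list(reads)
        iso_part = count_reads_per_isochore(reads, isochores, iso_index)
        cds_part = count_reads_per_cds(reads, genes, exon_index)
        table.total_reads[tissue] = iso_part.total_reads.get(tissue, 0)
        table.total_cds_reads[tissue] = cds_part.total_cds_reads.get(tissue, 0)
        table.unassigned[tissue] = iso_part.unassigned.get(tissue, 0)
        table.isochore_counts[tissue] = iso_part.isochore_counts.get(tissue, {})
        table.cds_counts[tissue] = cds_part.cds_counts.get(tissue, {})
        logger.info(
            "%s: %d reads, %d in isochores, %d in coding sequences",
            tissue,
            table.total_reads[tissue],
            table.total_reads[tissue] - table.unassigned[tissue],
            table.total_cds_reads[tissue],
        )
    return table
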