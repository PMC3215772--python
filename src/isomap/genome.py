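"""Core genomic data model: isochores, GC families, gene models.

Isochores are long (>= 0.2 Mb) genomic segments of fairly homogeneous base
composition.  They fall into five families -- L1, L2, H1, H2, H3 in order of
increasing GC level -- separated by fixed GC breakpoints.  Genes (CDSs with
exon coordinates) are assigned to the isochore hosting the majority of their
exonic bases.

All coordinates are 0-based half-open; 1-based inputs are converted at the
reader boundary (:mod:`isomap.io`).
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Family labels in order of increasing GC level.
FAMILY_ORDER = ("L1", "L2", "H1", "H2", "H3")

#: Rank of each family in the L1 < L2 < H1 < H2 < H3 order.
FAMILY_RANK = {name: i for i, name in enumerate(FAMILY_ORDER)}


class ConfigurationError(ValueError):
    """Raised when a configuration value is invalid; names the field."""


@dataclass(frozen=True)
class FamilyThresholds:
    """GC breakpoints (percent) partitioning isochores into the five families.

    The half-open convention puts each breakpoint into the upper family:
    L1 = [0, b1), L2 = [b1, b2), H1 = [b2, b3), H2 = [b3, b4), H3 = [b4, inf).
    The H3 boundary of 53% GC is fixed by the mouse isochore literature; the
    lower breakpoints follow the standard human/mouse family definitions.
    """

    b1: float = 37.0
    b2: float = 41.0
    b3: float = 46.0
    b4: float = 53.0

    def __post_init__(self) -> None:
        bps = (self.b1, self.b2, self.b3, self.b4)
        if not all(math.isfinite(b) for b in bps):
            raise ConfigurationError("thresholds: breakpoints must be finite")
        if not (self.b1 < self.b2 < self.b3 < self.b4):
            raise ConfigurationError(
                "thresholds: breakpoints must be strictly increasing, got "
                f"{bps}"
            )

    @property
    def breakpoints(self) -> tuple[float, float, float, float]:
        return (self.b1, self.b2, self.b3, self.b4)

    def interval(self, family: str, lo: float = 30.0, hi: float = 58.0) -> tuple[float, float]:
        """GC interval of a family, with outer bounds for the open-ended ones."""
        edges = (lo, *self.breakpoints, hi)
        i = FAMILY_RANK[family]
        return edges[i], edges[i + 1]


DEFAULT_THRESHOLDS = FamilyThresholds()


def classify_family(gc: float, thresholds: FamilyThresholds = DEFAULT_THRESHOLDS) -> str:
    """Classify a GC percentage into its isochore family.

    Intervals are half-open, so a GC level exactly on a breakpoint belongs to
    the upper family (gc = 53.0 -> H3).
    """
    if not math.isfinite(gc) or gc < 0:
        raise ValueError(f"gc must be finite and non-negative, got {gc!r}")
    # bisect_right puts gc == breakpoint into the upper family
    i = bisect.bisect_right(thresholds.breakpoints, gc)
    return FAMILY_ORDER[i]


@dataclass
class Isochore:
    """A named genomic interval of homogeneous base composition.

    ``family`` is derived from ``gc`` at construction; ``gene_count`` is
    filled in by gene-to-isochore assignment and drives ``gene_density``
    (genes per Mb, the quantity the density-normalized expression level
    divides by).
    """

    name: str
    chrom: str
    start: int
    end: int
    gc: float
    family: str = ""
    gene_count: int = 0
    thresholds: FamilyThresholds = field(default=DEFAULT_THRESHOLDS, repr=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"isochore {self.name}: need 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if not (20.0 <= self.gc <= 70.0):
            raise ValueError(
                f"isochore {self.name}: GC {self.gc} outside sanity bounds [20, 70]"
            )
        if not self.family:
            self.family = classify_family(self.gc, self.thresholds)

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        """Length in megabases (the L of the length-normalized level)."""
        return (self.end - self.start) / 1e6

    @property
    def gene_density(self) -> float:
        """Genes per Mb (the D of the density-normalized level)."""
        return self.gene_count / self.length_mb


def _validate_exons(exons: Sequence[tuple[int, int]], ccds_id: str) -> tuple[tuple[int, int], ...]:
    exons = tuple((int(s), int(e)) for s, e in exons)
    if not exons:
        raise ValueError(f"gene {ccds_id}: needs at least one exon")
    prev_end = -1
    for s, e in exons:
        if not (0 <= s < e):
            raise ValueError(f"gene {ccds_id}: bad exon [{s}, {e})")
        if s < prev_end:
            raise ValueError(f"gene {ccds_id}: exons overlap or are unsorted")
        prev_end = e
    return exons


@dataclass
class GeneModel:
    """A coding sequence defined by its exon coordinates.

    ``length_bp`` is the summed exon length (the l of the genic expression
    level).  ``gc``/``gc3`` are the CDS GC percentage overall and at third
    codon positions.  ``first_codon`` may be carried as metadata when the
    spliced sequence itself is not held in memory.
    """

    ccds_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    gc: float = math.nan
    gc3: float = math.nan
    host_isochore: str | None = None
    first_codon: str | None = None
    cds_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.ccds_id}: strand must be '+' or '-'")
        self.exons = _validate_exons(self.exons, self.ccds_id)

    @property
    def length_bp(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def compute_gc(sequence: str) -> float:
    """GC percentage of a sequence; ambiguous bases (N etc.) are excluded
    from both numerator and denominator."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    total = gc + at
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * gc / total


def compute_gc3(cds_sequence: str) -> float:
    """GC percentage restricted to third codon positions of a CDS."""
    if len(cds_sequence) % 3 != 0:
        raise ValueError(
            f"CDS length {len(cds_sequence)} is not divisible by 3"
        )
    return compute_gc(cds_sequence.upper()[2::3])


def filter_cds_lacking_start(
    genes: Iterable[GeneModel],
    sequences: Mapping[str, str] | None = None,
) -> tuple[list[GeneModel], int]:
    """Remove CDSs whose spliced, strand-corrected sequence does not begin
    with a literal ATG start codon.

    ``sequences`` maps ccds_id to the spliced CDS sequence; when omitted, each
    gene must carry ``cds_sequence`` or a precomputed ``first_codon``.
    Returns the kept genes and the number removed.
    """
    kept: list[GeneModel] = []
    removed = 0
    for gene in genes:
        if sequences is not None and gene.ccds_id in sequences:
            codon = sequences[gene.ccds_id][:3]
        elif gene.cds_sequence is not None:
            codon = gene.cds_sequence[:3]
        elif gene.first_codon is not None:
            codon = gene.first_codon
        else:
            raise ValueError(
                f"no sequence or first codon available for gene {gene.ccds_id}"
            )
        if codon.upper() == "ATG":
            kept.append(gene)
        else:
            removed += 1
    return kept, removed


def assign_gene_to_isochore(
    gene: GeneModel, isochores: Sequence[Isochore]
) -> str | None:
    """Assign a gene to the isochore containing the most of its exonic bases.

    Ties are broken toward the lower-coordinate isochore, which makes the
    result independent of isochore input order.  Returns ``None`` (with a
    logged warning) when no isochore overlaps the gene's exons or the
    chromosome is absent from the map.
    """
    candidates = [iso for iso in isochores if iso.chrom == gene.chrom]
    if not candidates:
        logger.warning(
            "gene %s: chromosome %s absent from isochore map", gene.ccds_id, gene.chrom
        )
        return None
    best_name: str | None = None
    best_overlap = 0
    best_start = -1
    for iso in candidates:
        overlap = 0
        for s, e in gene.exons:
            overlap += max(0, min(e, iso.end) - max(s, iso.start))
        if overlap > best_overlap or (
            overlap == best_overlap and overlap > 0 and iso.start < best_start
        ):
            best_name, best_overlap, best_start = iso.name, overlap, iso.start
    if best_name is None:
        logger.warning("gene %s overlaps no isochore", gene.ccds_id)
    return best_name


def assign_genes_to_isochores(
    genes: Iterable[GeneModel], isochores: Sequence[Isochore]
) -> list[GeneModel]:
    """Assign every gene in place (sets ``host_isochore``) and update each
    isochore's ``gene_count``.  Genes overlapping no isochore keep
    ``host_isochore = None`` and are excluded from isochore-level statistics.
    """
    by_name = {iso.name: iso for iso in isochores}
    for iso in isochores:
        iso.gene_count = 0
    genes = list(genes)
    for gene in genes:
        host = assign_gene_to_isochore(gene, isochores)
        gene.host_isochore = host
        if host is not None:
            by_name[host].gene_count += 1
    return genes


def compute_gene_density(isochore: Isochore, assigned_genes: Iterable[GeneModel]) -> float:
    """Genes per Mb: the count of CDSs assigned to the isochore over its
    length in megabases."""
    if isochore.length_mb <= 0:
        raise ValueError(f"isochore {isochore.name} has non-positive length")
    count = sum(1 for g in assigned_genes if g.host_isochore == isochore.name)
    return count / isochore.length_mb
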