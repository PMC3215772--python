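"""Synthetic data generator: isochore maps, gene models and aligned reads.

The generator emulates the statistical structure of the mouse genome and of
multi-tissue short-read RNA-seq as seen by an isochore-level analysis:

* chromosomes tiled contiguously by isochores (0.2-2 Mb) with mouse-like
  family proportions -- L1 under-represented, H3 nearly absent;
* gene density increasing linearly with isochore GC;
* per-tissue read counts whose expected log2 rate increases with isochore GC,
  with a tissue-specific strength (brain > muscle > liver by default), drawn
  from a negative-binomial (gamma-multinomial) count model.

Everything is a pure function of (config, seed): two runs with the same seed
produce byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genome import (
    ConfigurationError,
    DEFAULT_THRESHOLDS,
    FAMILY_ORDER,
    FamilyThresholds,
    GeneModel,
    Isochore,
)

logger = logging.getLogger(__name__)

#: Mouse-like family proportions: L1 small, H3 almost absent.
DEFAULT_FAMILY_WEIGHTS = {
    "L1": 0.07,
    "L2": 0.45,
    "H1": 0.31,
    "H2": 0.166,
    "H3": 0.004,
}

#: log2 expected reads per GC point, ordered brain > muscle > liver.
DEFAULT_TISSUE_EFFECTS = {"brain": 0.06, "muscle": 0.04, "liver": 0.02}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic genome and read simulation.

    The defaults aim at a mouse-scale toy genome: 19 chromosomes of 137 Mb
    tiled by ~2,300 isochores of 0.2-2 Mb, ~17,000 genes whose density rises
    with GC, and one million 25-bp reads per tissue.
    """

    n_chromosomes: int = 19
    chromosome_length: int = 137_000_000
    isochore_length_range: tuple[int, int] = (200_000, 2_000_000)
    family_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_WEIGHTS)
    )
    gc_within_family_jitter: float = 2.0
    gene_density_intercept: float = 5.9  # genes per Mb at the 40% GC reference
    gene_density_slope: float = 0.3  # genes per Mb per GC point
    tissue_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_EFFECTS)
    )
    read_length: int = 25
    total_reads_per_tissue: int = 1_000_000
    dispersion: float = 0.1  # NB overdispersion a: var = mu + a*mu^2; 0 = Poisson
    background_fraction: float = 0.0  # intergenic reads, fraction of the total
    emit_sequences: bool = False
    thresholds: FamilyThresholds = DEFAULT_THRESHOLDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes: must be >= 1")
        lo, hi = self.isochore_length_range
        if lo < 200_000:
            raise ConfigurationError(
                "isochore_length_range: minimum isochore length is 200,000 bp"
            )
        if hi < lo:
            raise ConfigurationError("isochore_length_range: max < min")
        if self.chromosome_length < lo:
            raise ConfigurationError(
                "chromosome_length: shorter than the minimum isochore"
            )
        if set(self.family_weights) != set(FAMILY_ORDER):
            raise ConfigurationError(
                f"family_weights: must cover exactly the families {FAMILY_ORDER}"
            )
        if any(w < 0 for w in self.family_weights.values()):
            raise ConfigurationError("family_weights: weights must be >= 0")
        if abs(sum(self.family_weights.values()) - 1.0) > 1e-9:
            raise ConfigurationError("family_weights: weights must sum to 1")
        if self.gc_within_family_jitter < 0:
            raise ConfigurationError("gc_within_family_jitter: must be >= 0")
        if self.gene_density_slope < 0:
            raise ConfigurationError("gene_density_slope: must be >= 0")
        if self.gene_density_intercept < 0:
            raise ConfigurationError("gene_density_intercept: must be >= 0")
        if not self.tissue_effects:
            raise ConfigurationError("tissue_effects: at least one tissue required")
        if self.read_length < 1:
            raise ConfigurationError("read_length: must be >= 1")
        if self.total_reads_per_tissue <= 0:
            raise ConfigurationError("total_reads_per_tissue: must be > 0")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion: must be >= 0")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ConfigurationError("background_fraction: must be in [0, 1)")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def generate_isochore_map(config: SimulationConfig) -> list[Isochore]:
    """Tile each chromosome contiguously with isochores.

    Family labels are drawn from ``family_weights``; each isochore's GC is
    drawn around its family's GC midpoint with ``gc_within_family_jitter``
    spread, clipped to stay inside the family interval so the label is
    consistent with :func:`isomap.genome.classify_family`.  The trailing
    remainder of a chromosome (shorter than the minimum isochore) is merged
    into the previous isochore, so isochores tile [0, chromosome_length)
    exactly.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.isochore_length_range
    families = list(FAMILY_ORDER)
    weights = np.array([config.family_weights[f] for f in families])
    isochores: list[Isochore] = []
    for c in range(config.n_chromosomes):
        chrom = _chrom_name(c)
        chrom_num = c + 1
        pos = 0
        starts: list[int] = []
        while pos < config.chromosome_length:
            length = int(rng.integers(lo, hi + 1))
            if config.chromosome_length - (pos + length) < lo:
                length = config.chromosome_length - pos  # absorb the remainder
            starts.append(pos)
            pos += length
        for j, start in enumerate(starts):
            end = starts[j + 1] if j + 1 < len(starts) else config.chromosome_length
            family = families[int(rng.choice(len(families), p=weights))]
            f_lo, f_hi = config.thresholds.interval(family)
            mid = (f_lo + f_hi) / 2.0
            gc = mid + rng.uniform(-config.gc_within_family_jitter,
                                   config.gc_within_family_jitter)
            gc = float(np.clip(gc, f_lo, f_hi - 1e-6))
            isochores.append(
                Isochore(
                    name=f"{chrom_num} Mm{j + 1}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    gc=round(gc, 4),
                    thresholds=config.thresholds,
                )
            )
    return isochores


def expected_gene_density(gc: float, config: SimulationConfig) -> float:
    """Expected genes per Mb at a given isochore GC (linear, floored at 0)."""
    return max(0.0, config.gene_density_intercept
               + config.gene_density_slope * (gc - 40.0))


_BASES_AT = np.array(list("AT"))
_BASES_GC = np.array(list("GC"))


def _random_cds_sequence(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Random CDS starting with ATG whose composition targets the given GC%."""
    n = 3 * n_codons
    is_gc = rng.random(n) < gc / 100.0
    choice = rng.integers(0, 2, n)
    bases = np.where(is_gc, _BASES_GC[choice], _BASES_AT[choice])
    bases[0], bases[1], bases[2] = "A", "T", "G"
    return "".join(bases)


def generate_gene_models(
    isochores: Sequence[Isochore],
    config: SimulationConfig,
    seed: int | None = None,
) -> list[GeneModel]:
    """Draw gene models per isochore with density increasing in GC.

    Per-isochore gene counts are Poisson with mean density(GC) x length;
    every CDS starts with ATG and has length a multiple of 3 (100-500
    codons over 1-8 exons, exons confined to the host isochore).  Genes
    that do not fit in their isochore are skipped and logged.
    """
    if not isochores:
        raise ValueError("generate_gene_models: empty isochore list")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    genes: list[GeneModel] = []
    skipped = 0
    for iso in isochores:
        mean = expected_gene_density(iso.gc, config) * iso.length_mb
        n_genes = int(rng.poisson(mean))
        for g in range(n_genes):
            n_codons = int(rng.integers(100, 501))
            cds_len = 3 * n_codons
            n_exons = int(rng.integers(1, 9))
            # random composition of the CDS length into exon pieces >= 3 bp
            if n_exons > 1:
                cuts = np.sort(rng.choice(
                    np.arange(3, cds_len - 2, 3), size=n_exons - 1, replace=False
                ))
                pieces = np.diff(np.concatenate(([0], cuts, [cds_len])))
            else:
                pieces = np.array([cds_len])
            max_span = iso.length_bp
            intron_budget = max_span - cds_len
            if intron_budget < 0:
                skipped += 1
                logger.info("isochore %s too short for a gene; skipped", iso.name)
                continue
            introns = (
                rng.integers(0, max(1, intron_budget // (4 * n_exons)), n_exons - 1)
                if n_exons > 1 else np.array([], dtype=int)
            )
            span = cds_len + int(introns.sum())
            if span > max_span:
                skipped += 1
                continue
            offset = iso.start + int(rng.integers(0, max_span - span + 1))
            exons = []
            pos = offset
            for k, piece in enumerate(pieces):
                exons.append((pos, pos + int(piece)))
                pos += int(piece)
                if k < len(introns):
                    pos += int(introns[k])
            strand = "+" if rng.random() < 0.5 else "-"
            gc = float(np.clip(iso.gc + rng.normal(0.0, 3.0), 25.0, 75.0))
            gc3 = float(np.clip(gc + rng.normal(3.0, 5.0), 20.0, 95.0))
            seq = None
            if config.emit_sequences:
                seq = _random_cds_sequence(rng, n_codons, gc)
            genes.append(
                GeneModel(
                    ccds_id=f"CCDS{len(genes) + 1}.1",
                    chrom=iso.chrom,
                    strand=strand,
                    exons=tuple(exons),
                    gc=round(gc, 4),
                    gc3=round(gc3, 4),
                    host_isochore=iso.name,
                    first_codon="ATG",
                    cds_sequence=seq,
                )
            )
    if skipped:
        logger.info("generate_gene_models: skipped %d genes that did not fit", skipped)
    return genes


@dataclass
class AlignmentRecord:
    """A mapped read: chromosome, 0-based leftmost base, length, tissue."""

    chrom: str
    pos: int
    length: int
    tissue: str

    def __post_init__(self) -> None:
        if self.pos < 0 or self.length < 1:
            raise ValueError(f"bad alignment record {self!r}")


def _tissue_rng(config: SimulationConfig, tissue: str, seed: int | None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    tissue_index = sorted(config.tissue_effects).index(tissue)
    return np.random.default_rng([base, 7919 + tissue_index])


def simulate_gene_counts(
    isochores: Sequence[Isochore],
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    tissue: str,
    seed: int | None = None,
) -> tuple[np.ndarray, int]:
    """Draw per-gene exonic read counts for one tissue.

    Expected counts are proportional to 2^(beta * GC_isochore) x CDS length,
    with beta the tissue's GC effect (log2 reads per GC point).  Dispersion a
    adds gamma noise (shape 1/a) to the per-gene rate before a multinomial
    draw, giving negative-binomial-like marginal counts; a = 0 is Poisson.
    Returns the count vector (aligned with ``genes``) and the number of
    intergenic background reads set aside by ``background_fraction``.
    """
    if tissue not in config.tissue_effects:
        raise ValueError(
            f"unknown tissue {tissue!r}; configured tissues: "
            f"{sorted(config.tissue_effects)}"
        )
    rng = _tissue_rng(config, tissue, seed)
    beta = config.tissue_effects[tissue]
    gc_by_iso = {iso.name: iso.gc for iso in isochores}
    gc = np.array([gc_by_iso[g.host_isochore] for g in genes])
    lengths = np.array([g.length_bp for g in genes], dtype=float)
    log2_w = beta * gc + np.log2(lengths)
    w = np.exp2(log2_w - log2_w.max())
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        w = w * rng.gamma(shape, 1.0 / shape, size=w.size)
    n_background = int(round(config.background_fraction * config.total_reads_per_tissue))
    n_genic = config.total_reads_per_tissue - n_background
    counts = rng.multinomial(n_genic, w / w.sum())
    return counts, n_background


def simulate_alignments(
    isochores: Sequence[Isochore],
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    tissue: str,
    seed: int | None = None,
) -> list[AlignmentRecord]:
    """Simulate aligned reads for one tissue.

    Per-gene counts come from :func:`simulate_gene_counts`; read start
    positions are uniform over the gene's exonic bases, so reads inherit the
    exons' containment in a single isochore.  Background reads (if any) start
    uniformly on a random chromosome.
    """
    counts, n_background = simulate_gene_counts(isochores, genes, config, tissue, seed)
    rng = _tissue_rng(config, tissue, seed)
    rng = np.random.default_rng(rng.integers(2**31))  # fresh stream for placement
    records: list[AlignmentRecord] = []
    for gene, count in zip(genes, counts):
        if count == 0:
            continue
        exon_lens = np.array([e - s for s, e in gene.exons])
        cum = np.concatenate(([0], np.cumsum(exon_lens)))
        offsets = rng.integers(0, gene.length_bp, int(count))
        exon_idx = np.searchsorted(cum, offsets, side="right") - 1
        starts = np.array([s for s, _ in gene.exons])
        positions = starts[exon_idx] + (offsets - cum[exon_idx])
        records.extend(
            AlignmentRecord(gene.chrom, int(p), config.read_length, tissue)
            for p in positions
        )
    for _ in range(n_background):
        c = int(rng.integers(0, config.n_chromosomes))
        pos = int(rng.integers(0, config.chromosome_length - config.read_length))
        records.append(AlignmentRecord(_chrom_name(c), pos, config.read_length, tissue))
    return records


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[Isochore], list[GeneModel], dict[str, list[AlignmentRecord]]]:
    """Generate the full toy input set: isochore map, gene models, and reads
    for every configured tissue."""
    isochores = generate_isochore_map(config)
    genes = generate_gene_models(isochores, config)
    for iso in isochores:
        iso.gene_count = 0
    counts_by_iso: dict[str, int] = {}
    for g in genes:
        counts_by_iso[g.host_isochore] = counts_by_iso.get(g.host_isochore, 0) + 1
    for iso in isochores:
        iso.gene_count = counts_by_iso.get(iso.name, 0)
    reads = {
        tissue: simulate_alignments(isochores, genes, config, tissue)
        for tissue in sorted(config.tissue_effects)
    }
    return isochores, genes, reads
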