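"""Normalized log2 expression levels for isochores and coding sequences.

Three measures, all log2 of a count ratio scaled by an optional factor f:

* ``E_L = log2(f * R_i / (R_t * L))`` -- isochore expression normalized by
  the isochore length L (Mb); R_i is the isochore's read count and R_t the
  tissue's total aligned reads.
* ``E_D = log2(f * R_i / (R_t * D))`` -- the same count ratio normalized by
  the isochore's gene density D (genes/Mb) instead of its length, isolating
  the GC effect from the higher gene concentration of GC-rich isochores.
* ``E_CDS = log2(f * R_CDS / (R't * l))`` -- genic expression; R_CDS is the
  read count in the CDS exons, R't the tissue total of reads in coding
  sequences, and l the CDS length (Mb).

Because the normalized counts are small the values are negative, but higher
expression still corresponds to peaks: each measure is strictly increasing
in the count.  Zero counts yield NaN (emitted as an empty field in tables),
never -inf.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .counts import CountTable
from .genome import GeneModel, Isochore

#: Count at or above which a gene is called expressed (per tissue).
EXPRESSED_THRESHOLD = 10

STATUS_EXPRESSED = "expressed"
STATUS_NON_EXPRESSED = "non_expressed"
STATUS_INDETERMINATE = "indeterminate"


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


def expression_el(r_i: int, r_t: int, length_mb: float, f: float = 1.0) -> float:
    """Isochore expression normalized by length: log2(f * R_i / (R_t * L)).

    Returns NaN when the isochore has no reads (undefined, not -inf).
    """
    _check_positive(R_t=r_t, L=length_mb, f=f)
    if r_i < 0:
        raise ValueError(f"R_i must be >= 0, got {r_i}")
    if r_i == 0:
        return math.nan
    return math.log2(f * r_i / (r_t * length_mb))


def expression_ed(r_i: int, r_t: int, gene_density: float, f: float = 1.0) -> float:
    """Isochore expression normalized by gene density: log2(f * R_i / (R_t * D)).

    Callers must restrict to isochores containing at least one CDS (D > 0);
    a non-positive density raises.
    """
    _check_positive(R_t=r_t, D=gene_density, f=f)
    if r_i < 0:
        raise ValueError(f"R_i must be >= 0, got {r_i}")
    if r_i == 0:
        return math.nan
    return math.log2(f * r_i / (r_t * gene_density))


def expression_ecds(r_cds: int, r_t_cds: int, length_mb: float, f: float = 1.0) -> float:
    """Genic expression: log2(f * R_CDS / (R't * l)) with l the CDS length in Mb."""
    _check_positive(R_t_cds=r_t_cds, length_mb=length_mb, f=f)
    if r_cds < 0:
        raise ValueError(f"R_CDS must be >= 0, got {r_cds}")
    if r_cds == 0:
        return math.nan
    return math.log2(f * r_cds / (r_t_cds * length_mb))


def classify_expression_status(r_cds: int, threshold: int = EXPRESSED_THRESHOLD) -> str:
    """Call a gene expressed (count >= threshold), non-expressed (count 0),
    or indeterminate (in between).

    The default threshold of 10 reads guards against misalignment noise; 100
    is the conventional stricter re-run.  The 1..threshold-1 band is left
    unclassified on purpose: such genes enter neither the expressed nor the
    non-expressed distributions.
    """
    if r_cds < 0:
        raise ValueError(f"read count must be >= 0, got {r_cds}")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if r_cds == 0:
        return STATUS_NON_EXPRESSED
    if r_cds >= threshold:
        return STATUS_EXPRESSED
    return STATUS_INDETERMINATE


def isochore_expression_table(
    table: CountTable,
    isochores: Sequence[Isochore],
    f: float = 1.0,
) -> pd.DataFrame:
    """Per-isochore expression table (one row per isochore).

    Columns: chrom, start, end, GC, Length (Mb), CDS_count, GeneDensity,
    family, then per tissue the raw count, the count ratio (count over the
    tissue total, both as fraction and percent) and the two log2 levels
    ``E_L_<tissue>`` and ``E_D_<tissue>`` (the latter NaN for isochores
    without CDSs, which are excluded from density-normalized analyses).
    """
    rows = {
        "name": [iso.name for iso in isochores],
        "chrom": [iso.chrom for iso in isochores],
        "start": [iso.start for iso in isochores],
        "end": [iso.end for iso in isochores],
        "GC": [iso.gc for iso in isochores],
        "family": [iso.family for iso in isochores],
        "Length": [iso.length_mb for iso in isochores],
        "CDS_count": [iso.gene_count for iso in isochores],
        "GeneDensity": [iso.gene_density for iso in isochores],
    }
    df = pd.DataFrame(rows).set_index("name")
    counts = table.isochore_frame(isochores)
    lengths = np.array(rows["Length"])
    density = np.array(rows["GeneDensity"])
    for tissue in table.tissues:
        r_t = table.total_reads[tissue]
        r_i = counts[tissue].to_numpy()
        df[f"count_{tissue}"] = r_i
        with np.errstate(divide="ignore"):
            ratio = r_i / r_t
            df[f"ratio_{tissue}"] = ratio
            df[f"ratio_pct_{tissue}"] = 100.0 * ratio
            el = np.log2(np.where(r_i > 0, f * r_i / (r_t * lengths), np.nan))
            ed = np.log2(
                np.where(
                    (r_i > 0) & (density > 0),
                    f * r_i / (r_t * np.where(density > 0, density, np.nan)),
                    np.nan,
                )
            )
        df[f"E_L_{tissue}"] = el
        df[f"E_D_{tissue}"] = ed
    return df


def gene_expression_table(
    table: CountTable,
    genes: Sequence[GeneModel],
    isochores: Sequence[Isochore],
    f: float = 1.0,
    threshold: int = EXPRESSED_THRESHOLD,
) -> pd.DataFrame:
    """Per-CDS expression table (one row per gene).

    Columns mirror the genic supplementary layout: chromosome, host isochore
    and its GC/coordinates, the CDS id, span, GC, GC3 and length, then per
    tissue the exonic read count, ``E_CDS_<tissue>`` and the expression
    status at the given threshold.
    """
    iso_by_name = {iso.name: iso for iso in isochores}
    rows = {
        "ccds_id": [g.ccds_id for g in genes],
        "chrom": [g.chrom for g in genes],
        "isochore": [g.host_isochore for g in genes],
        "isochore_GC": [
            iso_by_name[g.host_isochore].gc if g.host_isochore in iso_by_name else np.nan
            for g in genes
        ],
        "isochore_start_mb": [
            iso_by_name[g.host_isochore].start / 1e6 if g.host_isochore in iso_by_name else np.nan
            for g in genes
        ],
        "isochore_end_mb": [
            iso_by_name[g.host_isochore].end / 1e6 if g.host_isochore in iso_by_name else np.nan
            for g in genes
        ],
        "family": [
            iso_by_name[g.host_isochore].family if g.host_isochore in iso_by_name else None
            for g in genes
        ],
        "cds_from": [g.start for g in genes],
        "cds_to": [g.end for g in genes],
        "GC_ccds": [g.gc for g in genes],
        "GC3_ccds": [g.gc3 for g in genes],
        "Length_ccds": [g.length_bp for g in genes],
    }
    df = pd.DataFrame(rows).set_index("ccds_id")
    counts = table.cds_frame(genes)
    lengths_mb = np.array(rows["Length_ccds"], dtype=float) / 1e6
    for tissue in table.tissues:
        r_t_cds = table.total_cds_reads.get(tissue, 0)
        r = counts[tissue].to_numpy()
        df[f"count_{tissue}"] = r
        if r_t_cds > 0:
            with np.errstate(divide="ignore"):
                e = np.log2(np.where(r > 0, f * r / (r_t_cds * lengths_mb), np.nan))
        else:
            e = np.full(len(genes), np.nan)
        df[f"E_CDS_{tissue}"] = e
        df[f"status_{tissue}"] = [classify_expression_status(int(c), threshold) for c in r]
    return df
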