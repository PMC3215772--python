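"""End-to-end orchestration: simulate or load inputs, count, normalize,
analyze, and export, with a manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from . import io as iio
from .analysis import (
    correlation_summary,
    distribution_across_families,
    expressed_mask,
    family_mean_genic_expression,
    fraction_isochores_without_cds,
    never_expressed_mask,
    non_detected_in_one_tissue_mask,
)
from .counts import build_count_table
from .expression import gene_expression_table, isochore_expression_table
from .genome import (
    DEFAULT_THRESHOLDS,
    FamilyThresholds,
    assign_genes_to_isochores,
    filter_cds_lacking_start,
)
from .maps import export_map_tracks
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and knobs of a full run.

    Either ``simulate`` is true (inputs are generated from ``sim``), or
    ``isochore_table``/``gene_table``/``reads`` name the input files, with
    ``reads`` mapping tissue -> SAM or BED path.
    """

    out_dir: str = "isomap_out"
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    isochore_table: str | None = None
    gene_table: str | None = None
    reads: dict[str, str] = field(default_factory=dict)
    genes_one_based: bool = False
    scale_f: float = 1.0
    threshold: int = 10
    alt_threshold: int = 100
    thresholds: FamilyThresholds = DEFAULT_THRESHOLDS
    seed: int = 0
    export_bedgraph: bool = False

    def config_hash(self) -> str:
        fields = asdict(self)
        fields.pop("out_dir")  # where the run lands does not change what it computes
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and return the artifact directory.

    Stages: (simulate?) -> genome model -> read counting -> expression
    tables -> correlations, family summaries and distributions -> map
    tracks, plus a manifest recording version, seed, config hash and input
    checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    if config.simulate:
        sim = config.sim.with_(seed=config.seed, thresholds=config.thresholds)
        isochores, genes, reads_by_tissue = simulate_dataset(sim)
        iio.write_isochore_table(isochores, out / "isochores.tsv")
        iio.write_gene_table(genes, out / "genes.tsv")
        for tissue, reads in reads_by_tissue.items():
            iio.write_bed(reads, out / f"reads_{tissue}.bed")
    else:
        if not (config.isochore_table and config.gene_table and config.reads):
            raise ValueError(
                "without --simulate, isochore_table, gene_table and reads "
                "must all be provided"
            )
        isochores = iio.read_isochore_table(config.isochore_table, config.thresholds)
        genes = iio.read_gene_table(config.gene_table, config.genes_one_based)
        reads_by_tissue = {}
        for tissue, path in config.reads.items():
            if str(path).endswith((".sam", ".bam")):
                reads_by_tissue[tissue] = iio.read_sam(path, tissue)
            else:
                reads_by_tissue[tissue] = iio.read_bed(path, tissue)
            checksums[str(path)] = _file_checksum(path)
        checksums[str(config.isochore_table)] = _file_checksum(config.isochore_table)
        checksums[str(config.gene_table)] = _file_checksum(config.gene_table)

    genes, removed = filter_cds_lacking_start(genes)
    logger.info("start-codon filter: removed %d CDSs, kept %d", removed, len(genes))
    genes = assign_genes_to_isochores(genes, isochores)

    table = build_count_table(reads_by_tissue, isochores, genes)
    tissues = table.tissues

    expr = isochore_expression_table(table, isochores, f=config.scale_f)
    gene_expr = gene_expression_table(
        table, genes, isochores, f=config.scale_f, threshold=config.threshold
    )
    iio.write_expression_table(expr, out / "isochore_expression.tsv")
    iio.write_expression_table(gene_expr, out / "gene_expression.tsv")

    correlation_summary(expr, tissues).to_csv(
        out / "correlations.tsv", sep="\t", index=False
    )

    fam_summary = pd.DataFrame({"fraction_without_cds_pct": fraction_isochores_without_cds(isochores)})
    for t in tissues:
        fam_summary[f"mean_E_CDS_{t}"] = family_mean_genic_expression(gene_expr, t)
        fam_summary[f"n_expressed_{t}"] = (
            gene_expr.loc[expressed_mask(gene_expr, t), "family"]
            .value_counts()
            .reindex(fam_summary.index, fill_value=0)
        )
    fam_summary.to_csv(out / "family_summary.tsv", sep="\t", na_rep="")

    dists = {"all_cds": distribution_across_families(gene_expr)}
    dists["never_expressed"] = distribution_across_families(
        gene_expr[never_expressed_mask(gene_expr, tissues)]
    )
    for t in tissues:
        dists[f"non_detected_only_{t}"] = distribution_across_families(
            gene_expr[non_detected_in_one_tissue_mask(gene_expr, t, tissues)]
        )
        dists[f"expressed_{t}"] = distribution_across_families(
            gene_expr[expressed_mask(gene_expr, t)]
        )
    pd.DataFrame(dists).T.to_csv(out / "family_distributions.tsv", sep="\t")

    export_map_tracks(expr, out / "map", tissues, bedgraph=config.export_bedgraph)

    manifest = {
        "isomap_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "tissues": tissues,
        "n_isochores": len(isochores),
        "n_genes": len(genes),
        "cds_removed_no_start": removed,
        "total_reads": table.total_reads,
        "total_cds_reads": table.total_cds_reads,
        "unassigned_reads": table.unassigned,
        "input_checksums": checksums,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return out
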