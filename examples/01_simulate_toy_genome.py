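"""Generate a toy mouse-like genome: isochore map, genes, and reads.

The simulator tiles each chromosome with isochores (0.2-2 Mb segments of
homogeneous GC), places genes with density rising in GC, and draws
per-tissue reads whose expected log2 rate increases with isochore GC.
"""

from collections import Counter

from isomap import SimulationConfig, simulate_dataset

config = SimulationConfig(
    n_chromosomes=3,
    chromosome_length=40_000_000,
    total_reads_per_tissue=100_000,
    seed=7,
)
isochores, genes, reads = simulate_dataset(config)

print(f"{len(isochores)} isochores over {config.n_chromosomes} chromosomes")
fractions = Counter(iso.family for iso in isochores)
for family in ("L1", "L2", "H1", "H2", "H3"):
    n = fractions.get(family, 0)
    print(f"  {family}: {n:4d} isochores ({100 * n / len(isochores):5.1f}%)")
print(f"{len(genes)} genes; all start with ATG and have length divisible by 3")
for tissue, records in reads.items():
    print(f"  {tissue}: {len(records)} aligned 25-bp reads")

# the family proportions follow the configured mouse-like weights:
# L2/H1 dominate, L1 is under-represented, H3 is nearly absent.
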