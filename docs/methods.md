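# Methods

## Scope and data model

`isomap` analyses the relationship between base composition and expression
at two levels: genomic segments (isochores) and genes (CDSs with exon
coordinates). It consumes a pre-computed isochore map and pre-aligned
reads; it does not align reads, segment genomes into isochores, or handle
splice-aware alignment. Coordinates are 0-based half-open internally;
CCDS-style 1-based inclusive inputs are converted at the reader boundary.

Isochores are classified into the five families by GC breakpoints
b1 < b2 < b3 < b4, default **37 / 41 / 46 / 53** (% GC). Only the H3
boundary (GC > 53%) is firmly fixed in the mouse isochore literature; the
lower three follow the standard human/mouse family definitions and are
config-overridable. Intervals are half-open upward, so a GC exactly on a
breakpoint belongs to the upper family — classification is total and
monotone in GC.

## Read assignment

The assignment point is the leftmost mapped base only. 25-mers essentially
never straddle Mb-scale isochore boundaries, so whole-read assignment to
one interval is the appropriate granularity; the same point rule is used
for exons, as a deterministic proxy for "read aligned in the exons of a
CDS". Consequences embraced deliberately:

- a read in the exons of k overlapping CDSs increments all k counts, but
  the per-tissue total of reads in coding sequences (R′_t) counts it once;
- duplicate reads are counted (no deduplication);
- SAM records flagged unmapped, secondary or supplementary are ignored;
- reads in assembly gaps or on chromosomes absent from the isochore map
  count toward the tissue total R_t but toward no isochore, so
  Σ_i R_i + unassigned = R_t always holds.

Isochore lookup is a per-chromosome sorted-array bisection (maps are
non-overlapping by construction and validated on load); exon lookup is an
interval tree. Both are verified against an O(n·m) per-read linear scan in
the test suite.

## Expression measures

All three measures are log2 of a normalized count ratio with a scaling
factor f (default 1, exposed as `--scale-f`):

    E_L    = log2( f · R_i   / (R_t  · L) )      L = isochore length, Mb
    E_D    = log2( f · R_i   / (R_t  · D) )      D = genes per Mb
    E_CDS  = log2( f · R_CDS / (R′_t · ℓ) )      ℓ = CDS exonic length, Mb

Lengths are in Mb for isochores *and* CDSs. The unit choice only shifts
every defined value by a constant and therefore leaves all downstream
correlations invariant (property-tested); Mb is used uniformly for
consistency between the isochore and genic tables. Zero counts yield an
explicit undefined marker (NaN in memory, empty TSV field), never −∞, and
undefined records are dropped from correlations. E_D is computed only for
isochores with ≥ 1 CDS; density-normalized analyses are restricted to that
subset.

Expression status per tissue: **expressed** at ≥ 10 reads (noise guard
against misalignments), **non-expressed** at exactly 0, indeterminate in
between. The stricter 100-read threshold is available for robustness
re-runs; raising the threshold can only demote genes, never promote them
(tested as a monotonicity property).

## Statistics

Correlations are Pearson product-moment coefficients on complete pairs.
Fewer than two pairs, or zero variance, is reported as undefined with a
warning; two points compute (degenerately ±1) with a warning. Permuting GC
labels across isochores centers the correlation at zero (permutation sanity
check in the suite).

Family significance uses **Cochran's Q** on the expressed/non-expressed
binary indicator (via `statsmodels`, cross-checked in tests against the
direct formula Q = k(k−1)·Σ(C_j−C̄)² / (k·ΣR_i − ΣR_i²)) as the default,
with a Mann–Whitney U on defined E_CDS values as a flagged alternative —
the choice of test on such data is genuinely ambiguous, so both readings
are provided. For between-tissue comparisons within a family the genes
form a naturally matched design. For between-family comparisons the groups
are unequal and unmatched; the matched binary matrix is built by truncating
each family's indicator vector to the common minimum length in family
order. This is a pragmatic construction, not a claim that families are
paired; users wanting a pure two-sample reading should use the
Mann–Whitney mode. No multiple-testing correction is applied; raw p-values
are reported.

Family distributions (expressed genes, never-expressed genes, genes
non-detected in exactly one tissue, all CDSs) are percentages over the five
families and sum to 100 by construction; genes with indeterminate status
belong to neither the expressed nor the non-expressed subsets.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume, at
mouse scale by default:

| parameter | default | meaning |
|---|---|---|
| `n_chromosomes` × `chromosome_length` | 19 × 137 Mb | mouse-sized genome (~2.6 Gb, ~2,350 isochores) |
| `isochore_length_range` | 0.2–2 Mb | isochore sizes, uniform; minimum 0.2 Mb enforced |
| `family_weights` | L1 .07, L2 .45, H1 .31, H2 .166, H3 .004 | mouse-like proportions: L1 under-represented, H3 nearly absent |
| `gc_within_family_jitter` | 2 GC points | spread around the family GC midpoint, clipped inside the family interval |
| `gene_density_intercept`, `gene_density_slope` | 5.9 genes/Mb at GC 40, +0.3 per GC point | linear density–GC trend giving ~17,000 genes and a density–GC correlation near 0.4 |
| `tissue_effects` (β) | brain 0.06, muscle 0.04, liver 0.02 | log2 expected reads per GC point; ordering brain > muscle > liver |
| `total_reads_per_tissue` | 10⁶ | sequencing depth |
| `read_length` | 25 bp | truncated short reads |
| `dispersion` | 0.1 | NB overdispersion a (var = μ + aμ²); 0 gives Poisson |
| `background_fraction` | 0 | intergenic reads; the fraction in real data is unknown, so it is a free parameter defaulting to none |

Counts are drawn gamma-multinomial: per-gene weights ∝ 2^(β·GC_iso)·ℓ,
multiplied by Gamma(1/a, a) noise, then a multinomial of the tissue's read
total — negative-binomial-like marginals with an exact total. Read starts
are uniform over the gene's exonic bases, and exons are confined to one
isochore, so reads never straddle isochore boundaries — matching the
one-isochore-per-read assignment granularity. Genes are 100–500 codons
over 1–8 exons, always starting ATG with length divisible by 3; CDS
sequences are materialized only when `emit_sequences` is set (GC/GC3 are
otherwise carried as metadata). All generators are pure functions of
(config, seed); no global RNG state.

What the generator does **not** emulate: sequencing errors and quality
strings, splice junctions and paired ends, mappability structure, isoform
mixtures, intra-isochore GC gradients, and the developmental silencing that
produces a large never-expressed gene class in real adult tissues (at the
default depth virtually every synthetic gene collects reads). Passing
tests therefore demonstrate that the pipeline's accounting, normalization
and statistics are correct and that injected composition–expression
effects of realistic size are recovered — not that any particular
biological coefficient will be reproduced on real data.

## Numerical and design choices

- Gene-to-isochore assignment: the isochore with the largest exonic-base
  overlap; exact ties break toward the lower-coordinate isochore, making
  the result independent of input order. Genes overlapping no isochore are
  logged and excluded from isochore-level statistics.
- Start-codon filter: literal ATG on the spliced, strand-corrected CDS
  (from a supplied sequence or a precomputed first-codon field); alternative
  start codons are out of scope.
- GC/GC3: ambiguous bases are excluded from numerator and denominator;
  GC3 requires a length divisible by 3.
- Map export flips the sign of E_L at write time only (tracks plot below
  the GC axis); the stored value is preserved in a companion column.
- Determinism: the pipeline writes a manifest (version, seed, config hash,
  input checksums); two runs with the same seed and config are
  byte-identical apart from their location.

## Problem sizes used in the shipped checks

The test suite exercises unit operations on hand-built fixtures, module
interactions on simulations of 75–150 isochores at 10⁴–10⁵ reads per
tissue, and effect/null recovery plus the replicate ordering study at the
full default scale (~2,350 isochores, ~17,000 genes, 10⁶ reads per tissue)
using the count-level simulation layer, which draws per-gene counts without
materializing individual reads; read placement and leftmost-base counting
are covered end-to-end at the smaller scales and by brute-force oracle
equivalence on 100 random fixtures. `scripts/acceptance.py` runs the full
read-level pipeline once at the default scale and the ordering study over
100 replicate seeds.
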