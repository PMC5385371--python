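# Methods

## The model

A cultivar genome is treated as a diploid mosaic of ancestral haplotype
blocks over a shared reference coordinate system. Two block classes are
distinguished by variant density against the reference: dense variation
blocks (dVBs) and sparse variation blocks (sVBs). Two biological
assumptions drive everything downstream:

1. **dVBs are inherited largely intact.** Per-bp recombination inside a
   dVB is several-fold lower than in sVBs (the simulator's default sVB:dVB
   ratio is 6.6), so a dVB usually passes through a cross as one unit.
2. **dVBs recur across cultivars as a small set of ancestral types.** Two
   overlapping dVBs in different cultivars that share nearly all their
   variants descend from a common parental genome and are "the same type".

A single well-chosen InDel inside a dVB then acts as a proxy for the whole
block, and a cultivar's ordered vector of per-marker codes relative to a
reference cultivar is its barcode.

## Segmentation

Sliding windows (default 10 kb wide, 2 kb step) are classified dense when
variant density ≥ `density_threshold` (default 1.5 variants/kb, compared
inclusively, as are all thresholds in the package). The dense region is
the union of dense windows; dense runs separated by ≤ `merge_gap_bp`
(10 kb) are merged, and merged runs shorter than `min_block_bp` (10 kb)
are reclassified sparse. Blocks tile the chromosome exactly, alternating
classes. Defaults were chosen so that realistic resequencing densities
yield dVBs on the sub-100 kb scale typical of gene-rich regions; all are
config/CLI overridable. Note the density guarantee holds at window scale:
a merged dense block can contain a sub-threshold merge gap by design.

The tests verify segmentation against an independent brute-force oracle
(exhaustive per-bp window classification followed by the same merge
rules), plus tiling, class alternation, and monotonicity in the threshold.

## Cross-cultivar typing

Candidate pairs are dense blocks with reciprocal overlap ≥
`min_reciprocal_overlap` (default 0.5 of each block's length). A pair is
linked when:

- **SNV concordance** ≥ 0.8. The published criterion gives only the
  threshold; here concordance is defined as the Jaccard index of the two
  blocks' (position, alt-allele) sets restricted to the blocks'
  intersection interval, with two empty sets scoring 1.0.
- **Sequence identity** ≥ 99.8%. True identity needs consensus sequences,
  which a VCF does not carry; it is approximated as
  1 − (discordant variant positions / intersection length) and the
  approximation is logged. Typing on concordance alone is available via
  `TypingParams(use_identity=False)`; exact identities can be supplied per
  block pair when sequences exist.

Type labels are the connected components of the link graph — transitive
closure, mirroring same-colour block typing across a panel of cultivars.
Concordance is not transitive, so a component can contain pairs that fail
the pairwise thresholds; such non-metric clusters are reported as
warnings rather than split. Because it is ambiguous whether a "dVB count"
means per-cultivar blocks or reference-anchored loci, the typing result
reports both (`per_cultivar_count`, `per_locus_count`).

## Marker discovery

Candidates are InDels (any record with an alt allele whose length differs
from the reference allele's) of 5–20 bp lying inside a dense block; SNVs
and sVB variants are excluded. For gel scoring, each candidate gets
expected amplicon sizes `flank_left + allele_length + flank_right` per
allele; default flanks centre the InDel so the reference amplicon is
100 bp. A candidate passes the amplicon filter only if *every* allele's
product falls in 80–120 bp — short products resolve small length
differences cleanly on agarose.

Markers are scored as band patterns: alleles are binned by amplicon
length, so equal-length alleles collapse into one pattern (a gel cannot
separate them). Discriminating power is

    PIC_i = 1 − Σ_j p_ij²

over pattern frequencies p_ij, with heterozygous calls contributing both
patterns and missing calls dropped (not imputed). PIC is reported to two
decimals by convention; 0.5 is the biallelic maximum.

Selection takes at most `per_dvb_quota` (default 1) markers per dVB,
ranking by (PIC desc, allele-size difference desc, position asc) —
deterministic and stable under input shuffling. Genotyping success is a
wet-lab property a desk pipeline cannot observe; its panel-computable
proxy here is a missingness cap (candidates missing in > 10% of cultivars
are ineligible). dVBs with no passing candidate are listed in a gap
report. An optional `per_chrom_cap` reduces a panel to a fixed number of
markers per chromosome by the same ranking.

## Barcode encoding

Per marker, the reference cultivar's pattern codes `a`; alternative
patterns are ranked by panel frequency — the most common becomes `b`, any
further pattern `c` (real panels are overwhelmingly biallelic, so `c` is
rare and typically appears in only a handful of cultivars). Two distinct
patterns in one call code `h`; missing propagates as `.`. If the
reference cultivar's own call is missing at a marker, the column is keyed
to the declared reference-genome pattern, with a warning.

Rendered barcodes (1D stripe per marker; 2D wrapped one row per
chromosome, trailing cells grey) embed their layout in PNG metadata so
every image decodes back to its exact code string; the text serialization
carries a panel checksum (hash of the marker id list) so codes from
different panels cannot be silently compared.

## Panel analyses

- **Distance**: simple matching. For two rows, distance = differing
  markers / comparable markers, where comparable means both codes in
  {a,b,c}. Heterozygous and missing codes are excluded from identity
  comparisons by default (`h` signals incomplete fixation, not a distinct
  identity); `mismatch` and `match-either` policies are available.
- **Clustering**: classical Saitou–Nei neighbor joining, deterministic
  tie-breaking by lexicographic taxon id, negative branch lengths clamped
  to zero with the deficit moved to the sister branch. The published
  "weighted" NJ variant differs only in tie handling at this scale, so
  classical NJ with explicit deterministic ties is used; on additive
  matrices the generating topology and branch lengths are recovered
  exactly (property-tested, and cross-checked against scikit-bio's NJ).
  A branch-length threshold cut (`cut_tree_groups`) reads major groups
  off the tree; the threshold is user-chosen.
- **Minimal discriminating set**: greedy set cover over unordered
  cultivar pairs (a marker covers the pairs it distinguishes), ties by
  higher PIC then genomic order, stopping when no marker adds coverage.
  Pairs with identical rows are reported unresolved. An exhaustive exact
  mode exists for panels ≤ 20 markers and is used as the oracle in tests;
  greedy can exceed the optimum (by the classical ln-factor bound) but
  matches it on ≥ 90% of small random panels.
- **Pedigree consistency**: a marker is consistent when the offspring
  code matches either parent, the offspring is `h` with parents carrying
  different codes, or a parent is itself `h` (either allele could have
  been transmitted). The rate is inconsistencies / comparable markers.
- **Fixation**: cultivars with any `h` marker are flagged not fully
  fixed, their het markers grouped into consecutive (chromosome, dVB)
  runs.

## The synthetic panel

The simulator generates the statistical structure the pipeline assumes,
not sequence: planted dVB/sVB layouts, per-founder variant sets, and
founder-mosaic descendants.

- **Layout**: per chromosome, `n_dvb_per_chrom` (8) dVBs with lengths ~
  Normal(40 kb, 8 kb) clipped to 15–90 kb, separated by sVB gaps ≥ 40 kb —
  dVB scale and spacing chosen to match sub-100 kb blocks in a Mb-scale
  toy genome.
- **Variants**: dense regions 3 variants/kb, sparse 0.05/kb; 35% of
  variants are InDels with sizes uniform on 1–30 bp (so the 5–20 bp
  filter sees both passes and failures), the rest SNVs.
- **Ancestral types**: per dVB, each founder either reuses a uniformly
  chosen earlier founder's haplotype (probability `founder_share_prob`,
  0.3) or draws a fresh one; same-type blocks therefore carry identical
  variant sets. Sparse variants are founder-private.
- **Meiosis**: crossover count per chromosome ~ Poisson(2); positions by
  inverse CDF over a piecewise-constant intensity of 1 per bp in dVBs and
  6.6 in sVBs. No crossover interference is modelled.
- **Crosses**: F1, selfing chains (default 4 generations for "inbred"
  cultivars), and backcrossing; a BC_n genome retains an expected
  (½)^(n+1) of the donor genome, and BC5 followed by selfing differs from
  the recurrent parent at ≈ (½)⁶ ≈ 1.6% of differing markers — the
  magnitude at which a real backcross derivative sits a few markers from
  its recurrent parent on a ~200-marker panel.
- **Emission**: genotype tables of band patterns (allele lengths) and
  multi-sample variant records with placeholder allele strings of the
  simulated lengths. One seed fixes every draw; output is byte-identical
  across reruns.

What the simulator does **not** emulate: nucleotide sequences (so
sequence identity is always the VCF approximation), genotyping error and
allele dropout beyond a simple per-call mutation knob, crossover
interference, realistic genetic maps or chromosome counts, and
population-level linkage structure beyond the founder-sharing process.
Passing tests therefore demonstrate algorithmic correctness and
self-consistency at desk scale, not performance on real resequencing
panels, whose genome-scale block and marker counts depend on data this
package does not ship.

## Problem sizes used in the checks

The test suite runs the full pipeline at 30 founders → 150 cultivars over
two 1 Mb chromosomes (16 planted dVBs), recovers the crossover-rate ratio
from 10⁴ simulated meioses, and measures BC5 convergence over 200
replicates — sizes chosen to make the statistical assertions sharp (3
standard errors; 10% relative tolerance on the ratio) while keeping the
whole suite comfortably fast on one CPU.

## Numerical and degenerate-input conventions

All thresholds compare inclusively. Empty variant sets are fully
concordant (1.0). A chromosome with no variants is one sparse block. PIC
of an all-zero count vector is an error, as is a distance between rows
with no comparable markers. Two-taxon NJ returns a single edge split
across the representation root; three taxa use the closed form. The BED
writer is the only 1-based ↔ 0-based translation point.
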