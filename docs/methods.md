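# Methods

This note documents the models and procedures implemented in `haplotx`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Coordinates and interval arithmetic

All internal coordinates are 0-based half-open `[start, end)`. BED I/O is
native; GTF is converted from 1-based inclusive at the file boundary.
Region-level set operations (merge, subtract, intersect, overlap) are
strand-agnostic and single-count overlapping features via merge; strand is
consulted only where the biology demands it (5' ends, promoters,
bidirectionality). Chromosome names are matched verbatim — no silent
`chr` aliasing, because aliasing failures surface as wrong zero-overlaps
rather than errors. Every operation is validated in the test suite against
a per-base boolean-mask oracle.

## Haploblock delineation

A haploblock is delimited from a table of proxy SNPs carrying r² to the
index SNP, plus recombination hotspot positions.

**Main rules** (defaults: `r2_extend = 0.5`, `r2_sufficient = 0.6`,
`side_cap_bp = 500 000`): each boundary is the most distant proxy with
r² > `r2_extend` on that side, clipped to the per-side cap. A side is
*insufficient* when no within-cap proxy on that side has
r² < `r2_sufficient` — LD never decays below threshold, so the boundary
cannot be located — and such a side is extended to the nearest hotspot
beyond the current boundary. Open choices resolved here: the sufficiency
test is restricted to within-cap proxies (an empty side counts as
insufficient); hotspots inside the current block are ignored; interval
hotspot inputs are reduced to their proximal edge; block end = outermost
retained SNP position + 1, so the boundary SNP base is included. A side
requiring extension with no available hotspot keeps its proxy-extent
boundary and the block carries a warning record.

**Pilot rules** (`total_cap_bp = 1 000 000`): proxy extent, unconditional
hotspot extension on both sides, then a total-size cap. The cap is applied
*after* hotspot extension by trimming each side proportionally to its
overhang beyond half the cap from the index SNP — the least-surprising
distribution of a total cap the source rule does not specify.

Blocks shorter than 3 kb or overlapping any coding exon by ≥ 1 base are
excluded; surviving blocks are collapsed into non-redundant regions with
per-region index-SNP provenance.

## Capture space and controls

The capture target is the block union minus the union of exons of
`protein_coding` and `lincRNA` genes (union across all transcripts of a
gene — exclusion is by gene type, not per transcript). A second annotation
source can contribute additional coding exons to the exclusion set.
Intron controls pick at most one window per locus: introns are tried in
random order, a window of length uniform in [200, 1000] nt is placed
uniformly inside the intron, and accepted when its repeat-covered *base
fraction* (repeat content is not defined more precisely upstream; base
fraction is the natural reading) is ≤ 0.75. Selection is reproducible
under the seed.

## Expression and transcript filtering

Size factors are median-of-ratios: for transcripts with positive counts in
every condition, factor_j = median_i(count_ij / geometric-mean_i), the
median taken in real space. FPKM_ij = (count_ij / sf_j) /
((length_i/10³)·(normalized column total_j/10⁶)), with length the exonic
length. A transcript is retained iff it is multi-exonic, overlaps the
capture target by ≥ 1 exonic base, reaches FPKM > 1 in at least one
condition, and contributes > 1% of its locus's expression. The isoform
share is computed in the condition where the locus's summed FPKM is
maximal — the upstream rule does not say per-condition vs pooled, and the
dominant-tissue convention avoids averaging artifacts. Loci are formed by
transitively clustering transcripts that share ≥ 1 exonic base on the same
strand, mirroring assembler locus merging. Expression tiers are
max-FPKM tertiles with boundary ties resolved to the lower tier (no
principled cutoffs exist upstream). A block is *occupied* when ≥ 1
retained transcript with max FPKM > 1 has an exonic base inside it.

## Enrichment statistics

For region set R and annotation A over a genome of G bases, with an
optional exclusion set removed from R, A, and G alike:
a = |R∩A|, b = |A|−a, c = |R|−a, d = G−a−b−c (all in nucleotides; SNP
analyses count SNPs instead). OR = (a/b)/(c/d); SE(log OR) =
√(1/a+1/b+1/c+1/d); 95% CI = log OR ± 1.96·SE. P values use the χ² test
with Yates continuity correction (the conventional 2×2 default; a flag
disables it). Zero cells get the Haldane–Anscombe +0.5 on all four cells
for OR/CI only, never inside the χ² — the correction is opt-in. Multiple
classes are adjusted by Benjamini–Hochberg. The SNP-element analysis is
one-sided ("greater") against the intronic reference class.

Randomized controls re-place the ROI intervals uniformly at random in the
allowed genome (outside exclusions, inside chromosomes), preserving
lengths and chromosome assignment (a flag allows cross-chromosome
placement), and recompute the statistic per replicate. TSS enrichment uses
strand-aware 5'-end windows ±500 bp as ROI and excludes annotated promoter
windows (TSS ±500 bp — no upstream width being specified, the same flank
is used) plus annotated exons padded by 200 bp.

A calibration caveat documented deliberately: a χ² test on nucleotide
tables assumes exchangeable bases. It is calibrated when annotation
elements are point-like and independently placed (the regime the null
calibration test uses); for long, autocorrelated annotations the
randomized-placement controls — not the analytic p value — are the honest
null reference.

## Tissue specificity (Tau)

τ = Σᵢ (1 − x̂ᵢ)/(n − 1) with x̂ᵢ = xᵢ/max(x) over n ≥ 2 conditions:
0 for uniform expression, 1 for single-condition expression, invariant to
positive rescaling. Expression is stabilized as log2(normalized count + 1)
on size-factor-normalized counts; this package does not reproduce a
model-based variance-stabilizing transform, which shifts absolute τ values
slightly but not the formula or its closed forms. All-zero vectors are
flagged (τ = NaN), not scored. The per-condition components 1 − x̂ᵢ are
emitted as a matrix for external clustering; cluster significance testing
is out of scope.

## Aggregate profiles and bidirectionality

Metaplots count peak elements by midpoint (avoiding double-counting wide
peaks across bins) in strand-oriented offsets from the 5' end, bins of
100 bp over ±5 kb by default, restricted to transcripts expressed in the
track's condition, and normalized by the number of included transcripts —
so normalized counts × n is always the integer raw count. Promoter
occupancy is the fraction of 5' ±500 bp windows touched by ≥ 1 peak.
Positive-control candidates are ranked by |median expression − target
median| and size-matched. A transcript is bidirectional iff its span,
extended 500 bp at the 5' end, overlaps the extended span of an
opposite-strand transcript; the relation is symmetric by construction.

## Allelic imbalance

Given per-SNP reference/alternative read counts on heterozygous sites,
SNPs with depth < 30 are removed (inclusive threshold). Each SNP gets a
two-sided exact binomial p against a configurable null ratio (default 0.5;
supply a bias-adjusted value when reference-mapping bias is a concern —
no aligner is in scope here). Per transcript, p values are combined with
Fisher's method (−2Σln p ~ χ²(2k)) and transcripts are flagged at BH
FDR < 0.1. The imbalance magnitude is |0.5 − median allelic ratio| ∈
[0, 0.5]. This is a deliberately simplified per-SNP model: haplotype phase
is ignored and SNPs are treated as independent, which overstates the
effective number of observations when SNPs share haplotypes.

## Synthetic-data generator

The generator emulates every pipeline input on a coordinate-only toy
genome (default 2 chromosomes × 2 Mb; the acceptance script uses
3 × 4 Mb with 60 blocks; recovery tests use 4 × 10 Mb with 200 blocks —
sizes chosen so per-base oracles and multi-seed loops stay cheap while
leaving blocks of realistic ~20 kb width):

* **LD panels** — proxies every 1 kb out to ±60 kb with
  r²(d) = exp(−d/15 000) plus uniform noise (±0.05), truncated to [0, 1];
  a 15% fraction of index SNPs sit on an r² ≈ 0.9 plateau, which
  deterministically exercises the hotspot-extension branch. Hotspots every
  40 kb with jitter. Coalescent realism is deliberately not attempted:
  block construction consumes only an r² column. Ground-truth boundaries
  are emitted by an independent literal scan.
* **Transcriptome** — 85% of blocks (the planted occupancy) receive a
  multi-exonic locus (two isoforms, three exons each, main isoform
  fraction uniform in [0.6, 0.9]) whose maximum FPKM clears the threshold;
  81% of loci get single-condition count profiles (τ = 1 by construction),
  the rest broad Poisson profiles; 34% of occupied blocks also get a
  divergent head-to-head partner locus with 5' gap 150–700 bp, giving
  planted bidirectionality. Unoccupied blocks receive decoys that the
  filters must remove (expressed single-exon models, or silent multi-exon
  models); housekeeping loci outside the blocks keep every condition's
  library non-degenerate. Defaults (21 conditions, 0.85, 0.81, 0.34)
  mirror the study design being emulated.
* **Marks and SNPs** — promoter peaks (200 bp wide, ±50 bp jitter) are
  planted at 60% of promoter *sites* (clusters of overlapping 5' ±500 bp
  windows — per-transcript planting would make the fraction unrecoverable
  because isoforms and divergent partners share promoters), plus a sparse
  Poisson background (2×10⁻⁶ peaks/bp). GWAS vs common SNP catalogs are
  placed over disjoint promoter/exon/intron element classes with class
  weights bases × OR (planted OR = 2 for promoters and exons, introns as
  reference), realizing the element odds ratio in expectation.
* **Allele-specific counts** — 5 SNPs per transcript, depth
  ~ Poisson(50); 30% of transcripts are planted imbalanced with reference
  fraction 0.8, the rest draw from the balanced null.

All stages are deterministic under the configured seed (stage seeds are
spawned from it), emitted files round-trip through the package's own
readers, and truth tables are sufficient to score recovery without
re-deriving ground truth.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: genotype-derived r² structure and
population stratification, sequence content (no FASTA), read-level noise
and mapping bias, assembler artifacts beyond the two decoy classes,
correlated epigenetic tracks, haplotype phase in allelic counts, and
genome-scale annotation density. Recovery results certify the *pipeline's
arithmetic and decision rules*, not the biology of any particular dataset.

## Numerical choices

Bookended intervals merge (half-open convention). Empty chi-square margins
return p = 1. Degenerate all-zero expression vectors are flagged rather
than scored. Tier and tau thresholds are strict inequalities. The exact
binomial test uses the minlike two-sided convention (scipy's default), and
Fisher's combination clips p values at the smallest positive float before
taking logs. Randomized placement weights candidate gaps by the number of
valid start positions, giving an exactly uniform distribution over
placements.
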