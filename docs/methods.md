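# Methods

This note records the models, conventions and parameter choices behind
`tetlrr`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and gene models

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive)
and RepeatMasker `.out` (1-based) are converted at the I/O boundary and
nowhere else. "Exon" always means CDS segment: intron phases and
translation are defined only on coding sequence, and UTR structure is
never used. A multi-transcript gene collapses to its longest-CDS
transcript (ties broken by the lexicographically smallest transcript id) —
a deterministic rule chosen because the analyses assume one model per
gene. Genes whose CDS length is not a codon multiple are excluded with a
warning rather than aborting a run, since annotation dialects routinely
contain partial models.

Translation defaults to the ciliate nuclear code (TAA/TAG → Gln, TGA the
only stop), the code *Tetrahymena* uses; the standard code is available
per call. An internal stop under the selected code truncates the
translation with a warning instead of raising, so a single degenerate
model cannot abort a genome-wide scan.

## Phases, arrays and frames

The phase of intron *i* is the cumulative length of exons 1..*i* mod 3;
phase 2 means the intron interrupts a codon after its second nucleotide.
A "90-bp exon array" is a maximal run of ≥3 consecutive exons of exactly
90 bp — exact length, not 89–91, because the phenomenon under study is the
strict 90-bp mode. For an exon of length *L* between introns of phases
*p*₁, *p*₂, the frame arithmetic is

- leading junction nucleotides: (3 − *p*₁) mod 3,
- complete codons: (*L* − leading) // 3,
- touched residues: complete codons plus one per non-empty junction,

which for the canonical (90, 2, 2) case gives 29 complete codons
(nucleotides 2–88) and 31 touched residues. Repeat units are counted per
consecutive pair of array exons — exon plus the intron separating it from
the next array exon — so an *n*-exon array yields *n* − 1 units; this is
the reading under which a 90-bp exon and a 257-bp intron produce a 347-bp
unit, and the last exon of an array (whose following intron leaves the
array) contributes no unit.

Length histograms use 1-bp bins, a centred moving average (window 5 bp)
and a peak prominence threshold of 10% of the smoothed maximum; detected
peaks are snapped to the raw-count argmax within the smoothing window.
These choices are deliberately simple and deterministic: they resolve the
sharp 90/56/257/122-bp modes the analyses rely on without fitting any
distribution.

## Age-group classification

A gene is "masked" by a repeat family when the covered bp of its genomic
span (CDS plus introns) by that single family reaches `min_masked_bp`
(default 50 bp — below one array exon's length, so an isolated spurious
hit cannot trigger group III; configurable). Group I = no 90-bp exon and
unmasked, group II = 90-bp exons but unmasked, group III = 90-bp exons and
masked. Masked genes without 90-bp exons are surfaced as "unclassified"
rather than forced into the dichotomy. Group III genes are assigned to the
family with the largest sum of overlapping hit scores (ties: larger masked
bp, then lexicographically smallest family id); the score sum is our
concrete reading of "highest masking score" for RepeatMasker-style
Smith–Waterman scores.

## Conservation profiles

Because all rows are exactly 90 bp, exon matrices are alignment-free. The
amino-acid view drops nucleotide 1 and nucleotides 89–90 (junction
material) and translates the remaining 29 codons; codon *k* spans
nucleotides 3*k*−1..3*k*+1, mapping the conserved leucine centres
{36, 48, 66, 75, 81, 87} to residues {12, 16, 22, 25, 27, 29}. Consensus
calls break frequency ties by fixed symbol order so output is
deterministic.

The two-sample logo test compares sample A against the symbol frequency of
sample B as the null proportion, one-sided binomial in each direction at
α = 10⁻⁵. The null frequency is floored at 1/(|B|+2) and symmetrically
capped at 1 − 1/(|B|+2): the floor avoids a zero null proportion and the
cap avoids the mirror degeneracy in the depletion tail; both follow the
same pseudo-count logic. B-only (not pooled) frequencies define the null —
an explicit design choice.

Near-identity exon clustering treats "≥97% identity over 90 bp" as a
Hamming distance of at most 2 (no gaps are possible between equal-length
rows) and takes single-linkage connected components, the reading of
"cluster" that is checkable against a brute-force union-find oracle; the
suite performs exactly that comparison.

## Ortholog categories, expansions, tandem runs

A cluster's category is the number of species with ≥1 member (displayed as
Roman numerals for the canonical 10-species set; internally an integer so
any species count works). The inparalog-expansion test is our own
concrete construction: for clusters with ≥5 members spanning ≥2 species,
each species' count *k* is tested with the one-sided tail
P[X ≥ *k*], X ~ Binomial(N, 1/S_present), Bonferroni-corrected within
the cluster, α = 0.01. The test is calibrated by construction (family-wise
type-I ≤ α under a multinomial-uniform null, verified on 10⁴ simulated
clusters) and each species is flagged independently. Species-specific
genes are the union of singletons, category-1 cluster members and the
flagged species' members of expanded clusters.

Tandem linkage counts intervening *genes* in annotation order (not bp) and
ignores strand: two same-cluster genes link when ≤ `max_gap` other genes
lie between them (0 = strict, 3 = relaxed); groups are the resulting
chains. Singletons link to other singletons under the same rule.

## Chromosome landscape

MDS (IES-omitted) position = MIC position − total IES bp strictly before
it; positions inside an IES collapse to the IES's left edge and are
flagged (flagged genes are excluded from bin tracks). Genes are positioned
by CDS start. Bins tile each chromosome's MDS length at 1 Mb (last bin may
be short). Regions, in MDS coordinates: pericentromeric = ±1 Mb around the
centromere-interval midpoint, subtelomeric = terminal 1 Mb at each end,
arm = the rest, with pericentromeric taking precedence — deliberately
coarse descriptive cut-offs, all configurable. Enrichment uses a
subset-vs-complement chi-squared over the three regions; per-gene values
(Ka/Ks, FPKM — consumed as input tables, never computed here) are compared
between regions with two-sided Mann–Whitney U tests.

## REP analysis

The 54-bp tail is scanned as Hamming windows on both strands with ≤5
mismatches by default (~90% identity over 54 bp — conserved yet tolerant
of neutral divergence; configurable), no indels; overlapping same-strand
windows merge keeping the lowest-mismatch one. "Flanking" is edge distance
≤1000 bp by default, with a sensitivity sweep over {250, 500, 1000, 2000}
emitted. A REP copy is *colocalized* with the designated LRR-repeat family
when a hit of that family lies within the window on at least one side,
whether or not another family is nearer; the nearest-family-per-side
ranking is reported separately. Functionality (ORF1 ∧ ORF2 intact) comes
from input annotation; a helper can check for an uninterrupted reading
frame of configurable length.

## Synthetic data: what it emulates and what it does not

The generator writes complete multi-species bundles (FASTA, GFF3, mask
BED, domain TSV, OrthoMCL groups, chromosome metadata, REP BED, FPKM and
Ka/Ks TSVs) plus ground-truth tables, deterministically
(same spec + seed ⇒ byte-identical output). Its defaults are the study
conditions:

- per species 300 background genes and 120/220/330 group I/II/III LRR
  genes; three species (reference profile, a 232-bp-intron relative, and a
  245-bp-intron third) give ~2,000 LRR genes in the default fixture;
- background introns ~N(56, 8) bp; group III intron mixtures per species —
  reference 257 bp with a 122-bp secondary mode (weight 0.15), relative
  232 bp; all discretized normals;
- 90-bp exon count per array gene Poisson(10) truncated ≥3;
- phase-2 probability 0.99 for introns preceding 90-bp exons. Because
  90 ≡ 0 (mod 3) forces every intron in an array to share one phase, the
  probability acts per gene through the lead-exon length (11 bp ⇒ phase 2;
  a compensating tail exon keeps the CDS a codon multiple);
- a leucine template (TTA) at nucleotide centres {36,48,66,75,81,87} with
  retention 0.95 (group III) / 0.85 (group II) and background per-site
  substitution 0.02 / 0.08, creating the group III > group II conservation
  gradient; non-template codons are drawn excluding leucine codons so the
  template positions are the only conserved-leucine truth; junction
  nucleotides A‥TT make every junction codon read TTA;
- four CRS families per species at 5% divergence from the species
  template; group III genes get per-repeat-unit mask hits (plus a
  germline-level `tLRR-MIC-CRS` array hit in the reference species),
  group II genes get none beyond sub-threshold noise;
- a reference species with 5 chromosomes of 6 Mb MDS, IESs denser in
  pericentromeric/subtelomeric regions (25% vs 10% of sequence), ~12% of
  its genes carrying an intronic IES, and placement weights
  pericentromeric:subtelomeric:arm = 5:5:1 per bp for group III genes and
  REP copies (all other genes uniform);
- 400 REP copies (two ORFs + the 54-bp tail, tail mutated at 2% per site),
  each adjacent to a group III gene's repeat units with probability 0.8,
  functional fraction 0.25; non-adjacent copies are padded ≥1.5 kb from
  LRR repeat hits so the adjacency truth is unambiguous;
- ortholog structure assigned by label (not sequence): conserved clusters
  spanning all species, partial-category clusters, species-specific
  clusters, singletons, two dominant-species expansions (61 and 29
  inparalogs), and strict (17-gene) plus relaxed (≤3 intervening genes)
  tandem blocks;
- FPKM log-normal with a lower median for species-specific genes; Ka/Ks
  log-normal with medians 0.3 (specific) vs 0.05 (conserved).

Intron and intergenic sequence is random at 75% AT with only GT‥AG forced —
there is no splice-signal model, no evolutionary simulation along a
phylogeny, no IES-excision machinery, and ortholog clusters carry no
sequence signal. Gene density on the reference chromosomes is far below
real *Tetrahymena* density (a scale compromise that keeps Mb-scale region
analyses meaningful at ~2,000 genes). Passing tests therefore demonstrate
that the analysis code recovers known structure under the stated
statistical model — not that it would be robust to real-data artifacts
such as mis-annotation, assembly gaps or repeat-library incompleteness.

## Problem sizes and runtime

The test suite and the acceptance script use three fixture sizes: `toy`
(2 species, ~30 genes — smoke tests, <10 s for the full pipeline),
`default` (3 species, ~2,000 LRR genes, ~50 MB of sequence — parameter
recovery; generates in ~4 s and runs the full pipeline in ~30 s on one
CPU), and `stress` (10 species — ortholog-category coverage). Oracle
comparisons (near-identity clustering, tail scanning) run at 200 rows and
5-kb sequences, sizes at which brute force is exact and fast. Statistical
calibration uses 10⁴ simulated null clusters and 360 column-symbol logo
tests.

## Known limitations

- The expansion test's exact form (binomial vs uniform, within-cluster
  Bonferroni) is one defensible construction among several; its thresholds
  are configurable and its calibration is enforced by test.
- Hamming-only tail scanning misses indel-containing REP tail copies.
- Region labels assume a single centromere interval per chromosome.
- `two_sample_logo` swap-symmetry (A↔B exchanging enriched↔depleted) is
  exact only for clear-cut differences when |A| ≠ |B|, since the test
  count is taken in A against B's frequencies.
- The near-identity clustering is quadratic in row count; the pipeline
  caps it (default 6,000 rows per species) and the cap is configurable.
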