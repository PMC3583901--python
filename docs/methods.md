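# Methods

`mirnome` re-implements, as a tested library, the computational core of a
small-RNA deep-sequencing analysis of the human cardiac miRNome: from raw
cloning-library reads to a catalogue of known and novel miRNAs with
expression thresholds, group statistics and qPCR companion arithmetic.
Because the original raw sequencing data are not deposited, every stage is
exercised against a synthetic-data generator that plants ground truth in a
toy genome; this note records the model at each stage, the defaults and why,
and what the synthetic benchmark does and does not establish about real data.

## Library model and preprocessing

The simulated cloning protocol mirrors 454-style small-RNA library
construction: size selection of the 15–30 nt fraction, poly(A) tailing, and
ligation of a synthetic adapter to the 5′ phosphate. Each read is therefore
`adapter + insert + poly(A)`. Preprocessing removes the adapter by exact
prefix match (or a suffix of the adapter of ≥ 6 nt at the read start, for
reads beginning mid-adapter; the tolerance is configurable and exact by
default for determinism), strips a maximal terminal A-run of ≥ 4 nt
(shorter terminal runs are kept as genuine 3′ adenosines), retains inserts
of 18–30 nt, and collapses identical inserts into counted records ordered
by descending count. Reads without a detectable adapter are discarded by
default (flag to retain).

## Mapping

Collapsed reads are placed by exact full-length matching on both strands
via a sorted 2-bit-encoded 18-mer index over the forward genome; minus-
strand hits are found by querying the reverse complement, which preserves
strand symmetry exactly. Exact matching is the deterministic reduction of
the seed-and-extend alignment used on real genomes and is verified against
a naive string-scan oracle. Reads mapping to more than 5 loci are excluded
from discovery; for quantification and composition, multi-mapped reads
contribute fractional weight 1/n_hits per placement so that totals are
conserved.

## Annotation triage

Each alignment receives exactly one class by fixed precedence:
known miRNA > (rRNA | tRNA | snRNA | snoRNA | other siRNA) > exon >
repeat > intron > intergenic, requiring ≥ 50% of the read inside the
annotation; miRNA/ncRNA classes are strand-aware, repeats/exons/introns are
not (repeat annotations are typically unstranded). Only intergenic,
intronic and repeat-derived reads enter de-novo discovery; known-miRNA
reads are quantified as known, and the remaining ncRNA classes are set
aside. Known miRNAs are annotated over their whole precursor so that
star-arm reads classify as known rather than re-entering discovery as
false novels.

## Folding model

Secondary structure is computed by an exact dynamic program that minimises
a base-pair-weighted score: G:C = −3, A:U = −2, G:U = −1, with a minimum
hairpin loop of 3 nt, plus a helix-stacking bonus equal to the sum of the
two stacked pairs' weights. The stacking term rewards contiguous stems
over scattered isolated pairs and — critically — widens the fold-score
distribution across dinucleotide shuffles (score s.d. ≈ 6.8 vs ≈ 1.7
without it, exact-tie rate ≈ 5% vs ≈ 16%), which is what makes the
randfold significance test calibrate (below). The score is an MFE proxy,
not nearest-neighbour thermodynamics; its optimum is verified against
exhaustive enumeration of all nested structures for sequences ≤ 14 nt.
Ties are broken deterministically (pairing the 5′-most base preferred,
shortest-range partner first).

Abstract shapes follow the RNAshapes convention: every maximal unbranched
helix nesting collapses to `[]`, multiloops nest (`[[][]]`), unpaired-only
structures are `_`. Because base-pair maximisation forms isolated pairs
and 2-stacks that no thermodynamic model would keep, shapes are computed
after pruning helices shorter than 3 stacked pairs (the lonely-pair
prohibition); the pure abstraction is still available for explicit
dot-bracket input.

## Randfold

`randfold_p` asks whether a sequence folds more stably than
dinucleotide-preserving shuffles of itself:
p = (1 + #{shuffled score ≤ native}) / (n_shuffles + 1), ties counted
against significance. Shuffles use the Altschul–Erickson Eulerian-path
method and provably preserve the first base, last base and the full
dinucleotide count vector (asserted on every call); sampling uniformity
over the enumerable arrangements of an 8-mer is checked by chi-square.
Under the null (random sequences) p is approximately uniform
(Kolmogorov–Smirnov check with 49 shuffles); designed 25-bp stems reach
the p ≤ 0.05 floor. Default n_shuffles = 100 with significance at
p ≤ 0.05, the usual randfold convention.

## Hairpin discovery

Discovery-gated alignments are merged into read blocks (same strand,
overlap ≥ 1 bp; half-open intervals, so abutting reads do not merge).
Blocks longer than 120 nt cannot be one precursor arm and are dropped.
Each block is embedded in sliding windows of 80, 100 and 120 nt (step
10 nt, all placements containing the block; minus-strand blocks are
reverse-complemented into small-RNA sense). A window's fold rarely is a
single stem-loop — flanking sequence folds into extra helices, and flanks
can even pair around the precursor — so the discovery step descends
through enclosing helices to the stem-loop component that contains the
block (≥ 80% of its bases, ≥ 50 nt, i.e. two ~22-nt arms plus a loop),
refolds that trimmed interval and requires the `[]` shape on the refold.
This realises shape-matched hairpin identification within sliding windows
rather than demanding that a whole window fold into one hairpin.

Features per candidate: read count; weighted median read length; 5′/3′-end
heterogeneity (1 − modal-end weight fraction); GC content; randfold p
(seeded, cached per precursor interval); arm location (5p/3p/loop/spanning
by ≥ 80% of block bases relative to the innermost pair of the pruned
structure); and the Drosha/Dicer processing signature — homogeneous 5′
ends (heterogeneity ≤ 0.2) and, when opposite-arm reads exist, a
mature/star duplex with 3′ overhangs of 2 ± 1 nt on both strands as
implied by the fold's pairing (small bulges tolerated by sliding ≤ 3 nt to
the nearest paired base).

Confidence is rule-based and fully configuration-exposed, the defaults
chosen to separate clean planted positives from degraded-fragment
negatives (the original pipeline names these features but not its
thresholds, which is the largest documented gap between this package and
its inspiration):

* confident — shape `[]`, block on one arm, ≥ 10 reads, median read
  length 20–24 nt, Dicer signature, randfold p ≤ 0.05, GC in [0.2, 0.8];
* candidate — shape `[]`, block on one arm, ≥ 2 reads, and randfold
  p ≤ 0.1 or a Dicer signature; an optional user-supplied homology table
  promotes candidate to confident (no sequence search is performed);
* non-confident — everything else.

Candidates overlapping an annotated miRNA (≥ 50% reciprocal, same strand)
are known, the rest novel; overlapping windows (all sizes over one block,
and the two arms of one hairpin) deduplicate to one call per locus keeping
the lowest randfold p, then most reads, then the smallest window.

## Quantification and group statistics

Counts are normalised to reads per million mapped reads (RPM); the
normalisation the original analysis used is not stated, and RPM is the
field default. The abundance cutoff retains every miRNA whose pooled
(mean over all libraries) RPM is at least 0.9× that of hsa-miR-195 —
the natural reading of "no more than 10% below the reference" — with the
reference row required and the pooling choice documented here because
per-library pooling is equally defensible. Fold changes are
(mean_A + c)/(mean_B + c) with pseudocount c = 1 RPM; etiology
specificity requires ≥ 3-fold against both other groups (a vs-baseline-
only mode is available by flag). Group tests are one-way ANOVA across
NF/DCM/HCM on log10(RPM + 1) followed by pairwise Student t tests, with
Benjamini–Hochberg q-values within each pairwise family (matching the
per-comparison q columns of the report format); log-transforming before
testing extends the log10 transform the correlation analysis prescribes
and is this package's choice. Rows with no reads, or comparisons with
fewer than two libraries per group, report NaN rather than p = 1.
Specificity flags in the pipeline summary are evaluated on the
cutoff-retained set, mirroring the cutoff-then-threshold order of the
analysis; at desk-scale library sizes low-count rows would otherwise flag
spuriously.

## qPCR arithmetic

Relative quantification is the comparative Ct method: dCt = target −
endogenous control (U6/RNU6B) per sample, ddCt referenced to the mean dCt
of the designated control samples (multiple controls averaged), quantity
= 2^−ddCt. The reads–Ct correlation is Pearson r on (log10 reads, Ct)
with the p-value from the t distribution on n − 2 degrees of freedom;
a flag accepts pre-log-transformed read values, since whether the original
correlation used raw or ΔCt-normalised cycle thresholds is ambiguous.

## Synthetic-data generator

The generator is first-class, tested code that defines the study
conditions. Defaults: 5 Mb uniform-random genome; 30 known miRNA hairpins,
20 novel (unannotated) hairpins, 40 tRNA, 6 rRNA, 20 snRNA/snoRNA loci,
80 repeat regions and 60 unannotated degraded-fragment loci, all placed
without overlap; three groups (NF/DCM/HCM) × 3 libraries × 50,000 reads.
Per-locus expression weights are lognormal(0, 1), shared across libraries;
group effects are multiplicative (×6 for three DCM-specific and five
HCM-specific known miRNAs); per-library locus counts are multinomial, so
library totals are exact. The known miRNA of median expression is named
hsa-miR-195 so the abundance cutoff has its reference.

The read-class mix approximates a deep-sequenced cardiac library: ~22% of
mapped reads from repeats and ~28% from the non-miRNA ncRNA fraction with
tRNA at 78% of it, known miRNAs ~31% pooled. The novel-hairpin share is
2% of reads — far above the ~0.02% of sequences such libraries actually
contain — because recovery of 20 planted loci must be measurable at
desk-scale library sizes. Fragment-class insert lengths are drawn from
the mappable 18–30 nt part of the 15–30 nt gel cut so that the configured
fractions are realised among mapped reads, the quantity composition
figures report. Because the disease groups deliberately upregulate known
miRNAs, composition is checked on the baseline NF libraries.

Planted hairpins are arm + {A,C}-only loop + reverse-complement arm
(the loop alphabet cannot pair with itself, so the precursor reliably
folds to `[]`), with the mature/star duplex built to exact 2-nt 3′
overhangs, three G:U wobbles on the star arm (so mature reads map
uniquely rather than also hitting their own reverse complement), and
non-A 3′ ends for mature, star and fragment inserts (so poly(A) trimming
is unambiguous and the simulate→preprocess round trip is exact).
Hairpin reads have 90% modal 5′ starts (10% ±1 nt) and fixed 3′ ends;
10% of hairpin reads come from the star arm.

What the synthetic benchmark does not emulate: sequencing error (optional
uniform substitution only; no 454 homopolymer artifacts), genuine repeat
multi-copy structure (repeats are represented by annotation, so the
multi-mapper path is exercised only lightly), nucleotide composition bias,
expression-dependent length profiles, and cross-species conservation.
Passing recovery/composition checks therefore demonstrates internal
consistency of the pipeline logic under the stated noise model, not
performance on real tissue libraries.

## Numerical and reproducibility choices

All randomness flows from explicit seeds (numpy Generator; per-library
streams derived from the configuration seed and a CRC of the library id);
identical configuration and seed reproduce every output byte for byte.
Fold-score arithmetic is integer; the DP uses span-indexed tables batched
across shuffles for the randfold inner loop. Degenerate inputs are
defined: all-A reads trim to empty and drop at the length filter; blocks
longer than 120 nt yield no windows; all-zero expression rows and
missing-replicate comparisons report NaN statistics; a missing miR-195
row is a configuration error, not a silent skip.

Problem sizes in the test-suite and acceptance script (5 Mb genome, nine
50k-read libraries, 500 oracle sequences, 200 randfold null sequences at
49 shuffles, 200 FDR replicates of 201 × 15 matrices, 100 qPCR draws)
were chosen so a full run completes in a few minutes on one CPU while
keeping every estimate's Monte-Carlo error well inside its acceptance
band.

## Known limitations

* The folding model ranks stems sensibly but its scores are not free
  energies; randfold p-values are calibrated, but structure details
  (bulge placement, tie-broken pairings) need not match thermodynamic
  folders.
* Discovery thresholds were tuned on synthetic positives/negatives and
  carry no claim of optimality on real libraries; they are all exposed in
  `DiscoveryThresholds`.
* Exact mapping means any sequencing error drops a read; with the default
  error rate of zero this is moot, but real-data use would need an
  external aligner upstream.
* The known/novel split depends entirely on the supplied annotation set;
  unannotated true miRNAs are reported as novel by construction.
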