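# Methods

`satkit` implements a satellitome analysis pipeline: annotation of satellite
DNA (satDNA) monomers on genome assemblies, divergence-landscape profiling
with peak calling, array-flank conservation analysis, transcription
quantification against dimer references, distance-based monomer phylogenies,
and MRCA-based minimal-age dating. A synthetic-data module generates all
inputs with machine-readable truth, so every stage is validated end to end
against planted ground truth. This note records the models, the parameter
choices, and the places where a design was genuinely open.

## Monomer annotation

A satDNA family is represented by a consensus monomer; copies in a genome are
rotations (circular permutations) of that consensus on either strand,
accumulated substitutions included. The annotator detects every genomic
segment matching some rotation at alignment divergence ≤ `max_divergence`
(default **0.45**, the conventional screen for monomer variants).

The detector is seed-and-extend over the cyclic consensus:

1. **Seeding.** Every exact k-mer (k = 7) shared between the genome and any
   rotation of the consensus (both strands) becomes a seed. Each seed carries
   a *phase*: the genome offset of the implied monomer lattice modulo the
   monomer length. Within a tandem array all seeds share one phase; random
   background seeds scatter uniformly over phases, which keeps clusters from
   chaining across unrelated loci.
2. **Clustering and extent.** Seeds sharing a phase are clustered (gap ≤ 2
   monomer lengths; ≥ 2 seeds per cluster). Around each cluster, the
   maximal-scoring segment (+1 match / −1 mismatch against the phase-implied
   consensus lattice) gives the array extent; this trims stray same-phase
   background seeds instead of letting them drag the boundary outward.
3. **Tiling.** The array start is snapped (±8 bp) to the offset maximizing
   the identity of the terminal monomer, and monomers are tiled at
   consensus-length periodicity from the snapped start — so boundary noise in
   one monomer cannot desynchronize the rest of a long array. Each tiled
   monomer is scored against its rotation of the consensus; edge monomers
   failing the divergence ceiling by ≤ 0.10 are re-examined with the gapped
   aligner (degraded array edges), but isolated borderline windows with no
   accepted neighbor are discarded — under the affine scoring a random 142-bp
   window occasionally aligns below 0.45, and such windows are alignment-tail
   noise, not monomers.

Divergence at this stage is **alignment divergence** — (mismatches + indel
columns)/alignment length, N counting as mismatch — a similarity screen, not
an evolutionary distance. Overlaps within a family are resolved greedily by
ascending divergence (ties: leftmost start, then + strand). Arrays are
maximal runs of same-family, same-strand hits with inter-hit gaps ≤
`gap_tolerance` (default one monomer length: a single degenerate monomer
should not split an array; the value is configurable and logged).

*Limitation:* the lattice model assumes substitution-dominant arrays (the
simulator's default process). An indel inside an array shifts the phase
mid-array and the detector will see two clusters; recall contracts are stated
for substitution-only truth. The per-monomer divergence still uses gapped
alignment, so small indels inside individual monomers are tolerated.

## Divergence landscapes

Each annotated monomer (read 5'→3' on its own strand) is compared to the
consensus rotated to the monomer's phase; the Kimura 2-parameter distance

    d = −½ ln[(1 − 2P − Q) √(1 − 2Q)]

(P transitions, Q transversions per compared site; gap and N columns
excluded) corrects the observed proportions for multiple hits. Saturated
pairs (log argument ≤ 0) are flagged infinite and excluded from landscapes
with a logged count. Distances are binned at `bin_width` = **0.01** (1%
divergence classes); abundance is monomer count by default, with a bp-weighted
track emitted alongside.

### Peak calling

A peak is a bin, or series of neighboring bins, standing `peak_factor` =
**1.5** (50%) above the bins flanking it. The comparison is implemented as a
prominence rule:

* local-maximum plateaus are found within each positive-support segment of
  the landscape;
* two adjacent maxima separated by a valley shallower than 1.5× (relative to
  the smaller apex) are merged, the smaller apex absorbed;
* a surviving apex qualifies if, on each side, it is either open (landscape
  edge or empty bin — the condition is one-sided there) or ≥ 1.5× the
  minimum bin separating it from its neighbor, with at least one side
  offering a positive comparison bin (a region bounded by empty bins on both
  sides is the whole local distribution, not a maximum within it);
* the reported run is the maximal run around the apex whose bins all clear
  1.5× the largest positive flanking minimum.

A stricter variant (`rule="adjacent"`: every bin of the run must stand 1.5×
above the bins immediately outside it) is available; it cannot bound smooth
modes — a broad peak declining by < 1.5× per bin never presents a qualifying
cut — which is why prominence is the default.

Finite samples add one artifact: in sparse tail or valley bins, Poisson noise
produces isolated few-monomer bins that are genuine 1.5× local maxima. A
called run must therefore hold ≥ `min_peak_fraction` = **2%** of total
abundance; at the scales where landscapes are interpretable (thousands of
monomers) real secondary modes hold an order of magnitude more. Shape labels
from small samples (tens of monomers) remain noisy and should not be
over-read. Peak positions are summarized both by apex bin (argmax) and by the
abundance-weighted centroid of the run; the centroid is the stabler mode
estimator when neighboring bins are near-equal.

Shape classes: `unimodal_low` (single peak, apex below the 10% bin),
`unimodal_shifted` (single peak at ≥ 10%), `bimodal` (two peaks),
`multimodal` (≥ 3), `flat` (none). Low-divergence peaks read as recent
amplification or ongoing homogenization; shifted or secondary peaks as older,
non-homogenized variant sets.

## Flank conservation

Arrays are extracted with `flank_length` = **1,000 bp** of upstream and
downstream sequence, oriented 5'→3' relative to the array strand
(minus-strand arrays yield swapped, reverse-complemented flanks);
contig-edge truncation is flagged, never padded. For a flank set the
reference is the longest member (ties: smallest source coordinate), and every
member is globally aligned to it with the package-wide scoring (match +1,
mismatch −1, gap open −2, extend −1). The conserved block is the largest
prefix from the array boundary whose every `window` = 100-bp chunk has ≥
`member_fraction` = 0.75 of flanks at ≥ `identity_threshold` = 0.95 identity
to the reference — thresholds consistent with conserved cassettes in the
> 95–99% identity range while tolerating a minority of disrupted members.
Members failing over the block are reported as outliers with a classified
cause: truncation, insertion (longest contiguous member-only run ≥ 50 bp), or
early similarity loss. Insertion detection re-aligns the outlier with an
indel-sensitive scoring (near-free gap extension): under the standard
scoring, a long random insertion scores better as a mismatch diagonal than as
a gap and would never surface as one.

## Transcription quantification

Reads are counted against each family's head-to-tail **dimer** (consensus
concatenated with itself), so reads spanning the monomer junction align
end-to-end without clipping. A read counts for a family if it matches the
dimer ungapped at any offset, either strand, with ≤ `mismatch_limit` = **1**
mismatch; base qualities are ignored (the criterion is the mismatch count). A
fragment counts at most once per family but may count for several families
(all-alignments semantics); paired fragments count once if either mate
matches. The matcher is exhaustively verifiable — it is compared against a
per-read brute-force oracle in the tests.

Counts are normalized as FPKM = C·10⁹/(L·N) with L the dimer length and N
the library-size denominator — by default the total fragments in the library,
overridable with genome-mapped fragment counts where an external mapping
exists. Because genomic copy number differs enormously between satellites,
FPKM is valid only longitudinally (one family across stages/sexes); the
report API refuses cross-family ranking unless forced. Profiles report mean,
sample SD (missing — not zero — for single replicates) and replicate count
per family × stage × sex; libraries under a minimum depth are excluded with a
log line, a deliberately simple stand-in for library-level QC.

## Phylogeny and dating

For each family, up to `subsample_n` = **100** monomers are subsampled
uniformly without replacement (deterministic under seed). Pairwise K2P
distances (gapped alignment for unaligned monomers; column-wise on MSA rows)
feed a neighbor-joining tree built in-repo: ties in the Q criterion break to
the lexicographically first pair, branch lengths are not clamped, and on
additive matrices the tree's path-length matrix reproduces the input to
machine precision — the property the tests assert exactly. Monomers causing
saturated pairs are dropped, most-offending first, with a log. Bootstrap
supports resample alignment columns with replacement (**100** replicates by
default) and report, for each bipartition of the full-alignment tree, the
fraction of replicate trees containing it. Maximum-likelihood inference and
MSA construction are consumed as external inputs, not reimplemented.

Taxonomic presence is a coverage filter: a taxon carries a family if its best
BLAST-style query coverage of the consensus **strictly exceeds**
`coverage_threshold` = 0.5 ("exceeded" read literally). Species-level hits
can be collapsed to a coarser rank (e.g. order) by a mapping table, taking
the best coverage per rank; one qualifying species suffices for its order.
The **minimal age** of a family is the age of the MRCA of its qualifying
taxa plus the focal taxon on a time-calibrated tree — equivalently the
maximum pairwise divergence time, which the tests use as a brute-force
oracle. A family present only in the focal taxon has minimal age 0 and an
upper bound equal to the configured emergence age of the focal lineage's
clade (165 MY for Tenebrionidae). Dated trees are read from Newick either as
ultrametric branch lengths in MY (leaf-depth deviation beyond tolerance is an
error) or as internal-node age labels; node ages must be monotone along every
root-to-leaf path. The bundled insect-order tree carries TimeTree-style ages:
Coleoptera splits from Blattodea at 380 MY, Hemiptera 360 MY, Hymenoptera
340 MY, Lepidoptera+Diptera 327 MY, Lepidoptera–Diptera 295 MY; the two
Holometabola-internal ages do not affect any reported minimal age.

## Synthetic data

The simulators define the validation conditions; all are deterministic under
a fixed seed.

**Genomes.** Background is i.i.d. uniform DNA (GC knob available) — the
simplest null that cannot spuriously match consensus k-mers at a high rate.
Arrays are planted under four placement modes (interspersed across
chromosomes, terminal blocks within the outer 5% of ≥ 3 chromosomes, a
single block, or all arrays on one chromosome), each array starting at a
random rotation of the consensus and on a random strand, with ≥ 5 monomer
lengths of separation between planted units. Per-monomer divergence is drawn
from a weighted normal mixture (clipped to [0, 0.45)), so landscapes come out
uni- or multimodal by construction. An optional cassette sequence is
duplicated around every array for flank-conservation experiments. Truth
tables record every monomer's coordinates, strand, rotation, target and
realized divergence.

**Substitution process.** Matched to the K2P estimator: per site, a
transition with probability P and each transversion with probability Q/2,
with P/Q equal to the transition:transversion count ratio κ (default **2**,
so transitions are ⅔ of substitutions) and (P, Q) solved from the K2P closed
form. Because d(P̂, Q̂) is convex, finite monomers measure slightly high; the
solver subtracts the delta-method (second-order) bias for the monomer length,
making the *measured* distance unbiased — the property the Monte-Carlo tests
assert within 3 SE across the divergence grid. Substitution-only by default:
the divergence math and the 45% ceiling are defined over substitutions, and
indels exercise alignment robustness separately.

**Reads.** Satellite reads start uniformly along the dimer (both strands), so
a read_length/monomer_length fraction spans the junction; per-base
substitution error defaults to **0.002** (a conventional short-read scale;
the data this emulates states no error model); background reads are random
DNA. The stage × sex design covers eggs, early/mid/late larvae, early/late
pupae and early/late adults for both sexes, with a five-fold planted
elevation in late male pupae as the default peak condition.

**Presence.** Given a dated tree and a planted MRCA node per family, present
taxa are the focal taxon, one leaf from a planted-node subtree not containing
the focal taxon (pinning the MRCA exactly), and a random subset of the rest
of the planted clade; present taxa draw coverage strictly above the
threshold, sampled absent taxa strictly below.

What the simulators do **not** emulate: transposable-element or low-complexity
backgrounds, assembly collapse of long arrays, higher-order repeats, indel
drift within arrays, library-preparation biases, or strandedness. Passing
tests therefore demonstrate correctness of the computations under the stated
generative model, not robustness to every artifact of real assemblies — on
real data, assembly collapse in particular makes monomer counts
assembly-dependent.

## Validation scale

The test suite validates at desk scale: 2-Mb genomes with ~2,000 planted
monomers for annotator recovery (recall and precision ≥ 0.995,
reciprocal-overlap ≥ 50% matching), 50 seeded replicates of 5,000 monomers
for landscape-shape recovery (≥ 95% correct shape; peak centroids within ±1
bin of planted means), 10,000 reads for the error-loss closure (binomial
within 3 SE), and the full 4⁸ grid of length-8 landscapes for peak-caller /
oracle equivalence. `scripts/acceptance.py` recomputes the dated-tree minimal
ages (380 / 360 / 340 MY and the 165 MY bound) from the bundled tree and
synthesized coverage tables.
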