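# Methods

`tdgf` implements a desk-scale reconstruction of a transcription-derived
gene-fusion (TDGF) discovery analysis: finding genes that arose by
transcriptional readthrough of two adjacent parent genes, validating them
with junction-spanning reads, testing whether fusion loci concentrate in
segmental duplications (SD), and placing each fusion's origin on a species
tree. Every stage is exercised end to end on synthetic data with planted
ground truth; this note records the models, the parameters that matter, and
the design choices made where the design was genuinely open.

## Detection model

**Sequence similarity network (SSN).** Nodes are genes; an edge records a
best-reciprocal local-alignment hit at or above a percent-identity
threshold (the SI tier; 70, 80 and 90 are the conventional tiers).
Reciprocal bests are resolved per target gene set when genes carry species
tags — each query keeps its best partner within every species — and
globally otherwise. Tie-breaks (bit score, then e-value, then lexicographic
subject) are deterministic so runs reproduce exactly.

**Composite genes as non-transitive triplets.** A fused gene c appears as
the middle of a triplet a–c–b: both parent relatives hit c, in different
regions of c, while a and b share no edge. Triplets tolerate an interval
overlap of up to 20% of the shorter interval (`max_overlap_fraction = 0.2`)
because local alignments fray at the junction; a zero tolerance would
reject genuine fusions whose parent alignments overrun the breakpoint by a
few nucleotides. Candidates are verified as *clique separators*: the
composite induces a clique (trivially, for a single node) and its removal
splits its component into at least two parts that each contain a former
neighbor — the graph-theoretic signature of a gene bridging two otherwise
unrelated families. Parent families are the connected components of the
neighborhood after removing the composite.

**Distant-homology filtering.** A candidate is discarded when any
cross-family pair shares a pre-threshold hit at ≥ 30% identity (one
ancestral family masquerading as two parents) or when the family intervals
on the composite overlap by more than 20% of the shorter (both "parents"
explain the same region). This automates what is otherwise a manual
curation step.

## Alignment engine

Local alignment is optimal affine-gap Smith–Waterman (via biotite's
`align_optimal`). Scoring schemes:

| scheme     | matrix            | gap open / extend | min score |
|------------|-------------------|-------------------|-----------|
| protein    | BLOSUM62          | 11 / 1            | 60        |
| nucleotide | match 2 / mismatch −3 | 10 / 4        | 50        |

Identity is matches divided by all alignment columns, gap columns included
in the denominator. The nucleotide gap penalties are deliberately stiffer
than the BLAST defaults for this matrix (5/2): with cheap gaps the optimal
local path occasionally wanders tens of nucleotides past a fusion junction
through chance matches, which both depresses the reported identity of a
genuinely 90%-identical segment and shifts the parent interval used for
breakpoint inference. Raw scores are converted to bit scores and e-values
with Karlin–Altschul statistics (λ = 0.267, K = 0.041 for protein;
λ = 0.625, K = 0.41 for nucleotide); these feed only the reciprocal-best
e-value cutoff (10⁻⁵), where true and spurious hits differ by orders of
magnitude, so approximate constants are adequate. Minimum raw scores (60
protein, 50 nucleotide) are set so that unrelated random sequences of the
lengths simulated here (hundreds of residues) essentially never produce a
hit.

## Breakpoint inference and probes

Each parent is locally aligned to the composite nucleotide sequence. The
junction is the boundary between the two parent intervals: abutting
intervals put it at the shared coordinate; a gap or overlap (alignment
fraying) is resolved by the floor-midpoint of the uncovered/doubly-covered
stretch — unbiased, deterministic, and symmetric under exchanging the
parents. One parent interval containing the other is ambiguous and is an
error. Probes take `flank` nucleotides each side of the junction: 50 for
RNA-seq reads (100-nt probe), 8 for ribosome footprints (16-nt probe);
probes are clipped and flagged at sequence boundaries. Breakpoints live in
nucleotide coordinates because probes and reads do; protein-space intervals
map through the coding frame (×3).

## Junction-spanning read counting

Reads are QC-filtered first: trim a fixed number of leading bases
(default 13 for RNA data with poor leading cycles; 0 for footprints), then
drop reads with mean Phred < 20 or post-trim length < 36 (RNA) / < 26
(footprints, i.e. >25 nt retained). "Phred < 20" is read as *mean* read
quality; a per-base reading would discard essentially every read from a
low-quality run, which cannot be what a usable filter does.

A read supports a junction iff its best ungapped placement on the probe —
either strand, any offset — has at most 2 mismatches within the overlap
and the overlap covers at least `min_overhang = 8` nt on *both* sides of
the junction. Reads matching one parent flank only never count. An
ungapped mismatch-bounded scan is exact and sufficient at probe scale
(≤ 100 nt); a gapped or spliced mapper would add failure modes without
adding sensitivity here. 8 nt of overhang balances specificity against the
16-nt footprint probes, where the overhang equals the whole flank.

Counts become tiered calls: expressed at tier k iff count ≥ k, for
k ∈ {1, 3, 5}. The primary tier is 1 ("at least one read"); all tiers are
always computed. Tissue enrichment uses the pooled-variance two-proportion
z statistic comparing one tissue's expressed proportion against all other
tissues pooled; one-tailed p is the upper normal tail and two-tailed
p = min(1, 2·min(p₁, 1−p₁)); a degenerate pooled variance yields z = 0,
p = 1. TPM is count/length rates scaled to sum to 10⁶.

## SD enrichment

Gene–SD overlap is binary: any ≥ 1 nt intersection on the same chromosome
(0-based half-open; abutment is not overlap). The null samples gene sets of
the focal size uniformly without replacement from the whole gene universe,
10,000 replicates by default, and the empirical p-value uses the
(+1)/(+1) correction so it is never zero. Because the null is sampling
without replacement, the overlap count is exactly hypergeometric;
`hypergeometric_tail` (log-space summation of the mass function) is kept as
an independent closed-form check and agrees with the permutation p to
Monte-Carlo error. The focal size is always an explicit argument, never
defaulted.

## Origin mapping

Junction evidence per species collapses to presence (expressed at the tier
in ≥ 1 tissue), absence (read data, no expression) or missing (no read
data). Missing is *not* absence: species without data are ignored when
computing the origin. The origin of a fusion is the most recent common
ancestor of its present species — a single-gain, Dollo-style placement; a
fusion present in one species sits on that tip. Per-branch counts sum to
the number of fusions. Loss modeling is out of scope; a fusion lost in an
ingroup species will be assigned to the correct (or an older) node only as
far as single-gain logic allows.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
transcriptome realism. Defaults (one bundle):

- 30 unrelated parent pairs, coding sequences of 300–600 nt drawn
  uniformly over non-stop codons (frame-0 translations have no internal
  stop);
- 10 readthrough fusions: prefix of parent A (50%) + suffix of parent B
  (50%), each retained segment independently point-mutated to 90% identity
  against its parent. The substitution count is ⌊(1−target)·len⌋ so
  realized identity never falls below the target — a segment "at 90%"
  reliably passes a 90% threshold instead of coin-flipping on rounding;
- parent-A genes, parent-B genes and fusions carry three distinct species
  tags, so per-gene-set reciprocal-best resolution links a fusion to both
  parents, as a cross-species ortholog search does;
- 76-nt single-end reads, 20 background reads per transcript per tissue
  over six tissues, constant per-read Phred (Q = −10·log₁₀(error rate),
  Q40 cap, +33 encoding), substitution errors only (default error rate 0);
  tissue and species ride in the read name (`|tissue=X|species=Y`), a
  documented dialect since FASTQ has no such fields;
- 5 planted junction reads per fusion per tissue, each keeping ≥ 16 nt on
  both sides of the junction; background reads on fusion transcripts never
  cross the junction. Planted counts are therefore exactly recoverable at
  zero error rate even when breakpoint inference is off by up to ±8 nt —
  without this separation the counter's 8-nt overhang rule would make
  exact recovery depend on sub-nucleotide luck in breakpoint localization;
- a 1-Mb genome with 30 SD blocks of 10 kb (30% SD fraction). Every gene
  is placed inside SD with probability p_sd = 0.3, except fusion loci which
  use min(1, p_sd · enrichment) with enrichment 3 by default. Placement is
  rejection sampling into non-overlapping half-open intervals;
- a fixed 7-species tree (great apes, macaque, marmoset, mouse) with
  My-scale branch lengths.

What passing tests on this generator do **not** show: robustness to
splicing and isoforms, paralogous families larger than pairs, indel
sequencing errors, platform quality profiles, paired-end data, or GC/length
confounding in the SD test. The generator is the study condition, not a
claim about real transcriptomes.

## Problem sizes and determinism

The shipped analyses run one default bundle (70 genes, ~8,700 reads;
all-vs-all alignment ≈ 2,400 pairwise Smith–Waterman problems), a
10,000-replicate permutation test, a 20-configuration
permutation-vs-hypergeometric comparison, and a 100-seed null-calibration
study with 2,000 replicates per seed and focal sets of 100–200 loci in
universes of 800–1,500 genes. Larger focal sets are used for calibration
deliberately: the permutation p-value is discrete, and with small focal
sets the lattice spacing of its null support (pmf ≈ 0.2) dominates a
uniformity comparison; at 100–200 loci the spacing (≲ 0.08) is well inside
the resolution of a 100-sample KS test. All randomness flows from a single
integer seed per run; identical configurations reproduce byte-identical
fixture bundles.

## Known limitations

- Composite detection seeds on triplet middles, not full minimal-separator
  decomposition; multi-node clique separators are handled only insofar as
  each member is itself a triplet middle.
- Fusions of more than two parents are represented structurally (≥ 2
  families) but not specifically optimized or tested.
- The SI tier compares the single best local hit per pair; chained HSPs
  are not merged.
- Segments at *exactly* the tier identity sit on a measurement knife edge:
  alignment-column identity can jitter a fraction of a percent around the
  nominal segment identity, so detection of 90%-identity fusions is run at
  the 80% tier in the shipped end-to-end analyses while tier gating is
  demonstrated at 75%/95% where margins are real.
- The enrichment null is unmatched for gene length, GC or chromosome;
  this mirrors the unrestricted random-gene-set design it reconstructs.
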