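# Methods

This note documents the models, procedures and design choices behind
`enhancergain`, in the order the pipeline applies them.

## Enhancer construction

Enhancers are fixed 1000-bp windows centred on the midpoint of an H3K27ac
peak (floor of the midpoint for even-width peaks — a deterministic
tie-break; the geometric centre is used because summit positions are not
part of the input contract). Windows overlapping any promoter — the closed
interval ±1000 bp around every supplied TSS, alternative TSSs included —
are removed. Windows that would run off a chromosome edge are clamped and
flagged; downstream stages drop clamped windows by default because every
later step assumes the fixed 1-kb width. Coordinates are 0-based half-open
throughout (BED native); any 1-based input must be converted at the
boundary.

## The sequence-to-activity scorer

The scorer is a 1-D convolutional network over one-hot DNA (channel order
A, C, G, T; ambiguous bases encoded as 0.25 in every channel):
same-padding convolutions with ReLU and max-pooling, a fully connected
ReLU layer, and a sigmoid (1 unit) or softmax (2 unit) output. It is
implemented directly in numpy — im2col convolutions with hand-derived
gradients, verified against numerical differentiation — and trained with
Adam (defaults: learning rate 10⁻³, batch size 64, up to 20 epochs) on
binary cross-entropy.

**Data split.** Chromosomes 8 and 9 are held out as the test set and
chromosome 6 is the validation set used for early stopping (patience 3);
all other chromosomes train. Every training sequence is also presented as
its reverse complement.

**Strand invariance.** At inference the score is the mean of the forward
and reverse-complement passes, which makes `score(s) ==
score(revcomp(s))` an exact identity rather than an approximation.

**Activity threshold.** A sequence is called active when its score reaches
the cutoff calibrated on inactive (negative) sequences: the smallest
observed score t with `mean(negatives >= t) <= fpr`, default FPR 0.1. A
published cutoff for one trained model (such as 0.197) is meaningful only
for that model's score distribution, so every retrained model recalibrates.

**Two architectures.** The *reference* architecture has five convolution
layers with 320/320/240/240/480 kernels, a 180-unit dense layer and
1000-bp input, totalling 3,631,401 trainable parameters. Its kernel
widths, pool sizes and output-unit count are not part of the public
description, so `solve_reference_architecture` searches them
deterministically (lexicographic over output units, then pool tuples, then
width tuples; widths 2–26, pools 1–8, outputs 1–2) for a configuration
whose closed-form parameter count matches the target exactly. Parity of
the total forces a single sigmoid output unit. The search returns
widths (8, 3, 3, 3, 2) with pools (1, 1, 1, 4, 8); other configurations in
bounds also reach the same total — the count, not the specific widths, is
the anchored quantity. The *scaled-down* default (two conv layers of 32
kernels, width 8, pool 4, 32 dense units, 200-bp input) exists because the
test suite trains models end to end; it reaches auROC > 0.99 on the
separable planted-motif construction in under a minute on one CPU.

**Problem sizes.** Training checks use 2000 positives + 2000 negatives of
200 bp; the parameter-recovery suite uses 200 trios of 1 kb; the
equal-fraction selection simulation uses 1000 replicates of 60 sites per
class. These sizes make the statistical assertions stable while keeping
the default suite fast.

## Trio classification

For each enhancer with a reciprocal macaque ortholog (length difference
≤ 50 bp; conflicting duplicate mappings are dropped) and an ancestral
reconstruction, the status call uses peak evidence and the three scores
s_h, s_m, s_a against one threshold t:

- **gained** — human peak, s_h ≥ t, no macaque peak, s_m < t and s_a < t;
- **lost** — macaque peak, s_m ≥ t and s_a ≥ t, no human peak, s_h < t;
- **conserved** — peaks in both species and min(s_h, s_m, s_a) ≥ t;
- **ambiguous** — everything else, including every pair without an
  ancestral sequence (the ancestor is what polarizes gain against loss).

"Active" is ≥ t and "inactive" is < t everywhere, so the partition is
total and deterministic. Mutation extraction walks the aligned pair
column-by-column; gap columns yield no site (the mutation model is
single-nucleotide substitutions only).

## Essential mutations and minimal activating sets

Starting from an *inactive* macaque ortholog (an active start is an error
— essentiality is undefined there), each human allele is introduced singly
and the score change recorded; the mutation is essential when the edited
score crosses the threshold. The minimal activating set search iterates
m = 1, 2, …: all C(n, m) combinations are evaluated when that count is at
most 10,000, otherwise exactly 10,000 distinct combinations are sampled
without replacement over combination ranks (combinatorial-number-system
unranking; reproducible from the seed). Among activating combinations at
the minimal m, the largest score delta wins, ties broken by lexicographic
position order. The mirrored single-variant test (`deactivating_essential`)
asks whether one variant alone silences an active human enhancer; the full
mirrored minimal-set search for lost enhancers is intentionally not
implemented.

## Allelic imbalance

Replicate read counts are summed per site before testing (summation is
associative, so replicate order cannot matter). A site with ≥ 6 total
reads is imbalanced when the human:macaque ratio exceeds 1.3 *and* the
exact binomial test against 0.5 gives P ≤ 10⁻³. The test is two-sided by
default — the conservative reading, since the ratio filter already
enforces direction — and switchable to one-sided. Zero macaque reads give
an infinite ratio (which passes the ratio filter) with the p-value
computed normally. Per-class imbalance fractions are compared against the
activity-preserved background (signal ratio ≤ 1.2 between species) with
Fisher's exact test.

## Direction of selection

DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps), bounded in [−1, 1], undefined when either
margin is empty (an error, not a silent NaN). Fixed-versus-polymorphic
status is an input column: deriving it requires population data that is
upstream of this package. The neutral background is mutated
fourfold-degenerate sites, identified from the standard genetic code
(table-driven, so alternate codes can be supplied); minus-strand CDSs are
reverse complemented before codon reading and positions mapped back.
Derived-allele-frequency comparisons use the Mann–Whitney test, exact for
combined n ≤ 20 and the tie-corrected normal approximation otherwise.

## Motif scanning and the TF network

PWMs score by base-2 log-odds against the background composition, with a
10⁻³ pseudocount per cell before the logarithm. Hit thresholds are
calibrated empirically: the smallest observed score on ≥ 100 kb of random
background such that the hit count (both strands) stays within 5 per
10 kb; a degenerate motif ends up with a prohibitive cutoff rather than an
error. Enrichment of a motif in gained versus conserved enhancers is a
region-level 2×2 Fisher test (regions with/without ≥ 1 hit).

A TF is an **activator** when the binding-site gain:loss ratio caused by
essential mutations exceeds 1.2× the same ratio for common SNPs, a
**repressor** in the mirrored case, otherwise undetermined; a 0.5
pseudocount (Haldane–Anscombe) on all four counts keeps the ratios finite.

Network edges connect a source TF to a target TF gene when the source
motif's hit density (hits/kb) in the gained enhancers assigned to the
target (nearest-TSS assignment) is enriched over its density in the
conserved enhancers at the same locus. No canonical statistical rule
exists for this call, so the default — ratio ≥ 1.5 and one-sided Poisson
p ≤ 0.05 with the background per-kb rate as the expectation (floored at
half a hit when the background is empty) — is explicit and configurable.
Self-edges are allowed and count toward both degrees; the master regulator
is the maximum out-degree TF, ties broken lexicographically.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with exact
ground truth:

- **Trios.** Ancestral sequence is i.i.d. uniform ACGT, scrubbed of chance
  motif hits. For a *gained* trio, the activator motif consensus is
  planted with its most informative position broken, and the human branch
  restores it — that single substitution is the designated essential
  mutation. *Lost* mirrors this; *conserved* plants the intact motif in
  all three sequences; *neutral* plants nothing. All substitutions lie on
  the human branch (macaque retains the ancestral allele), with the total
  count Poisson-distributed at 50 per kb — the observed substitution
  density in both gained and conserved enhancers. Neutral substitutions
  are re-drawn whenever they would create or destroy a motif hit, so
  planted truth is exact rather than probabilistic.
- **Reads.** Heterozygous-site depths are Poisson with mean 30; the
  human-allele count is Binomial(depth, r/(1+r)) with r the configured
  imbalance ratio (r = 1 for balanced sites).
- **Selection tables.** Each site is fixed with its class's probability;
  polymorphic sites draw a derived allele frequency from Beta(1, 3)
  (rare-variant-skewed, as expected under drift).
- **Expression.** Each TF has an independent latent factor; a regulated
  TF's expression sums its regulators' factors plus its own scaled by the
  noise SD, so planted edges correlate positively and unlinked pairs stay
  independent.
- **Signals.** H3K27ac peak intensity carries log-normal noise (SD 0.5 on
  the log scale) — a documented stand-in, since no noise model for the
  signal is part of the input contract.

Every quantity is a pure function of the seed via fixed per-operation
substreams, so regenerated files are byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: indels and alignment error (trios are gap-free
by construction), dinucleotide/GC composition and repeats, cooperative or
soft motif grammar (activity is driven by one sharp motif), read-mapping
reference bias at heterozygous sites, and linkage between sites in the
selection tables. Results on real data depend on upstream choices (peak
calling, liftOver quality, ancestral reconstruction) that are consumed
here as inputs.

## Numerical conventions

- Rounding of printed percentages is half-away-from-zero at the stated
  number of decimals, computed in decimal arithmetic for bit-stability.
- "90% bootstrapping 50 times" is implemented as subsampling 90% of items
  *without* replacement per replicate (matching the "90%" qualifier), with
  the classical with-replacement bootstrap available by flag.
- Fisher's two-sided p sums tables with conditional probability at most
  that of the observed table (standard conditional test); the odds ratio
  gets a 0.5 pseudocount only when a cell is zero, and is flagged as
  adjusted.
- Threshold calibrations return the smallest *observed* score meeting the
  budget; when ties make every observed value too permissive, the cutoff
  moves just above the maximum so nothing passes.
- Score-threshold comparisons use ≥ for activity everywhere (gain,
  essentiality, motif hits), so boundary scores are active.

## Known limitations

- The minimal-set search is exact only up to its sampling cap; for n ≫ 20
  mutations the reported m is an upper bound with high probability, not a
  certificate.
- The numpy network trains comfortably at test scale but is not built for
  genome-wide corpora; the architecture search anchors the full-scale
  parameter count without training the full-scale model.
- `solve_reference_architecture` reports the first matching configuration
  in a deterministic order; the true unpublished hyperparameters of the
  reference model are not identifiable from the parameter count alone.
- The activator/repressor rule compares ratios only; it attaches no
  uncertainty to the 1.2-fold margin.
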