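# Methods

This note documents the models and procedures implemented in `tumap`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Coordinate convention

All internal coordinates are 1-based inclusive on the forward reference;
span length is `end − start + 1`. This convention is load-bearing: the
package's span arithmetic reproduces the published lengths of the three
housekeeping sRNA regions it uses as worked examples (346, 396 and 104 bp),
which a half-open convention would miss by one. BED and bedGraph files are
converted to their native 0-based half-open form at the file boundary, and
every output file states its convention in a header line.

## Synthetic genome generator

The generator emulates the statistical structure of a high-GC bifidobacterial
chromosome during exponential growth. It is first-class, tested code: its
planted truth is the reference against which every downstream stage is
scored.

**Sequence composition.** Default GC 0.59. Intergenic segments are generated
8 percentage points more AT-rich than coding segments, with the coding GC
raised so the genome-wide fraction stays at the target (±2% is asserted in
the tests).

**TU structure.** Each unit carries, in transcription sense: a −35 hexamer
(TTGACA), a spacer of 14–20 bp drawn from a distribution peaked at 17 bp, a
−10 hexamer (TATAAT), a 10 bp gap to the TSS, a 5′-UTR (mean 100 bp for
high-class units, 60 bp otherwise, sd 50 bp — leaders are broadly dispersed
in real data), one or two genes of 500–1500 bp, and a 3′-UTR of mean 38 bp.
Fold-changes are drawn uniformly inside per-class ranges nested within the
class boundaries (high > 10, medium [3, 10], low < 3).

**Promoter degradation.** Consensus hexamers are degraded by independent
per-position substitution with probability `class_rate × susceptibility`,
class rates 0.05/0.20/0.40 (high/medium/low). The susceptibility vectors
encode the conservation pattern described for this organism: the −10
conserves positions 1, 2 and 6 (T, A, T) best while its core degenerates
first, and the −35 is the overall weaker element with its first three
positions the most recurrent. At degradation 0 the planted hexamers are
exactly the consensus. The spacer distribution widens with falling
expression (temperature 0.4/1.5/5.0 of an exponential kernel around 17 bp),
reflecting the observed drift of weak promoters across the legal range.
Published descriptions of promoter degradation in this organism are
qualitative; these rates and shapes are the package's own quantification.

**Terminators.** A per-class fraction of units (defaults 70/83, 81/153,
73/177 — the observed per-class rho-independent fractions) ends in a planted
hairpin (stem 6–9 bp, ≥ 70% GC, G/C terminal bases, loop 3–8 nt) followed
within ≤ 3 nt by six T's. G/C stem ends keep the arm from annealing into the
flanking tails, so planted elements always satisfy the detector's minimum
rule set and noiseless recall can be 100%. Convergent (tail-to-tail) pairs
are planted in two flavours: a shared bidirectional terminator
(polyA–stem–loop–stem–polyT) or overlapping 3′-UTRs with no termination
signal. Two gene-free, very highly transcribed transcripts (fc 46–60, body
100–400 bp) model housekeeping sRNAs.

**Array channel model.** gDNA = baseline·2^N(0,σ); mRNA = gDNA · r ·
2^N(0,σ), where r is the overlap-weighted fold-change of the transcripts
covering the probe (weight = covered fraction of the probe; r = 1 off
transcript) and σ = 0.2 log₂ units by default. No noise magnitudes are
published for either platform; σ is a free parameter chosen so that medium
units are called confidently while low units sit near the detection floor,
mirroring the reported difficulty of detecting weakly transcribed genes.

**Coverage model.** Expected depth over a transcript is
fc · depth · bias(p), with a sinusoidal positional bias (period 300 bp,
amplitude 0.5) standing in for the hexamer-priming and fragmentation biases
the platform is known for; the first T bases of each transcript get zero
coverage with T geometric (mean 20 bp), matching the documented 5′-end loss;
off-transcript background is Poisson (mean 0.1); per-base counts are Poisson
draws of the expectation (switchable off for noiseless tests). Read counts
per gene are Poisson with expectation fc·depth·L/100.

## Array signal

Probes are tiled from position 1 every 22 nt, both strands, keeping only
probes fully inside the genome (the published per-strand probe count is not
exactly reproducible from the stated tiling because the edge handling was
never specified; the rule here is the simplest consistent one). Significance
of the mRNA channel against the gDNA baseline is a one-sided z-test of the
log₂ ratio against a null located and scaled by the genome-wide
median/MAD — a single two-channel array offers no replicate variance for an
empirical-Bayes moderated test, and the robust null uses the fact that most
probes are untranscribed. BH correction at FDR ≤ 10⁻⁴; a probe must also
have a positive log-ratio. Segments are maximal runs of significant probes
bridging at most one non-significant probe (isolated dropout); boundaries
are the first and last base of the member probes, and a segment's
fold-change is the mean of 2^log₂ratio over its significant members (gap
probes are dropout victims and would bias the estimate down). An optional
repeat mask (BED) excludes probes from calling.

## Coverage signal

RPKM follows the standard formula with a 150-RPKM expression call.
Boundary detection is a windowed step rule (window 25 bp, ratio 4, minimum
coverage 5× an estimated background mean with a floor of 1): a start is the
leftmost base where the downstream window mean reaches the threshold and
exceeds the upstream window mean by the ratio; ends are the mirrored drops;
starts and ends pair left-to-right per strand, and intervals cut by a contig
edge are flagged truncated. The reported start is snapped to the first base
carrying at least half the post-rise plateau level, so isolated background
reads ahead of the rise cannot pull the boundary upstream — this preserves
the platform property that an RNA-seq start never precedes the true TSS.
Ties between adjacent step candidates resolve to the leftmost.

## TU assembly

Each array segment becomes one TU. Genes join by ≥ 50% same-strand overlap;
a segment also covering most of an opposite-strand gene is flagged ambiguous
and left unassigned. The TSS is the segment's 5′ boundary, refined to the
nearest same-strand coverage-interval 5′ end when the two agree within one
probe length (60 bp) — the platform's own TSS error bound; the TTS is the
segment's 3′ boundary (the array represents termination better than
coverage, which suffers 5′ enrichment and uneven depth). Fold-change
boundaries 3 and 10 are assigned to the medium class so the partition is
total. UTR statistics use a Mann–Whitney U test for the high-vs-rest 5′-UTR
comparison; UTR lengths are skewed, and at desk scale occasional fragment
artifacts would dominate a t-test's variance.

## Promoter model

A two-box model: 4×6 position-weight matrices for the −35 and −10 plus an
empirical spacer distribution over 14–20 bp. Fitting is
expectation-maximization over every legal two-box placement per training
window (E-step: softmax of log-odds scores plus the spacer log-probability;
M-step: posterior-weighted counts with pseudocount 0.5), initialized from
the most recurrent hexamer pair so the EM starts off the symmetric fixed
point. Convergence: max posterior change < 10⁻⁶.

Because the E-step selects among ~240 placements per window, EM sharpens
even featureless input into a crisp-looking PWM. The reported information
content is therefore the *excess* of the fitted model over a null fit — the
same EM run on per-window letter shuffles (composition preserved, structure
destroyed). Featureless input scores ≈ 0 excess bits and trips the
low-information warning (< 2 bits); planted-consensus input scores ~16 bits.

Scanning uses the PWM log-odds plus a spacer penalty of 0.25 log-odds units
per bp from the 17 bp optimum (the optimum and range are established; the
penalty form is the package's choice), ties broken toward spacer 17 and then
the smaller −10→TSS distance, with an acceptance threshold at the 5th
percentile of training-window scores (a stand-in for the manual curation of
borderline promoters that cannot be codified). Scan windows are 100 bp
ending at the TSS, accommodating −10→TSS distances up to ~20 bp. Training
windows are the 62 bp upstream of the TSS of the 75 highest-FC high/medium
units.

The 62-bp feature window is 24 bp upstream of the −35 + 6 + 17-column spacer
block + 6 + 9 bp downstream of the −10; spacers shorter than 17 are
centre-padded with an explicit gap state, longer ones centre-trimmed.

## Terminator detection

Hairpins are enumerated (vectorized over positions; stems 6–20 bp, loops
3–10 nt) under an explicit rule set chosen so a brute-force oracle can
reproduce the detector exactly: arms pair Watson–Crick (G·U wobble available
but off by default — detection operates on the DNA strand) with at most one
mismatch, never terminal, and an exactly-paired run of at least the minimum
stem; the 5′ arm must be ≥ 50% GC. Score = stem + 2·(GC pairs) − loop/2 —
an ad-hoc pairing score, not a nearest-neighbour free energy. Tails are
*maximal* A/T runs of ≥ 4 nt starting within 3 nt of the stem: defining
tails as maximal runs prevents the stem from "eating" a bidirectional
element's polyA/polyT (pairing them against each other scores higher but
destroys the call). Overlapping calls collapse to the highest score.

Classification runs two passes per TU over the window from the last gene end
to 200 bp downstream: polyT-anchored calls decide rho-independence, bare
hairpins support the stem-loop-only class (a pausing-site-like signal), and
a polyT call within one probe length (60 bp) of the TTS — the TTS carries up
to one probe of array overhang, so a tighter window would systematically
miss genuine terminators — classifies the TU rho-independent. Units with no
signal whose 3′-UTR overlaps a tail-to-tail neighbour's are classed
convergent-overlap; the remainder none.

## Feature ranking

Rows are promoter feature vectors — spacer length, leader length, five block
AT fractions, and the 62 aligned columns one-hot encoded with an explicit
gap state — labelled by expression class, plus intergenic 62-mers as
negatives (excluding called promoter footprints). A negative k-mer has no
annotated leader; it receives a leader length drawn from the promoter pool
(a neutral assignment — giving negatives their true distance-to-gene made
leader length a trivial negative discriminator) and the canonical spacer of
17. The forest is 500 bootstrap trees (configurable to 5000) with balanced
class weights; importance is mean impurity decrease with deterministic
tie-breaks, and the out-of-bag error is reported both for the full label set
and for the three-class (high/medium/low) sub-problem. Desk-scale defaults
are 500 trees and 5000 negatives; a `paper` profile scales to 5000 trees and
270 000 negatives.

## Scale profiles and problem sizes

The `desk` profile — 200 kb genome, 20 TUs per class, 4 convergent pairs, 2
sRNA transcripts, 500 trees, 5000 negatives — is the default problem size
for the tests and the acceptance script; a full run takes seconds on one
CPU. The `paper` profile (2.4 Mb, 83/153/177 TUs, 5000 trees, 270 000
negatives) exercises the same code at study scale and is slower. Validation
statistics that need more replication (e.g. the 5′-truncation mean) use
dedicated configurations of 60–90 TUs.

## What the synthetic validation shows — and does not

Passing tests demonstrate that each algorithm recovers the structure the
generator plants, at the noise levels and effect sizes configured: exact
consensus recovery at degradation 0, 100% terminator recall on noiseless
sequence, high-class TSS recovery within one probe, the onset-lag and
never-upstream properties of the coverage detector, and the qualitative
importance ordering (−10 AT fraction above spacer length above leader
length; −10 positions 1/2/6 above its core). They do not demonstrate
robustness to everything real data adds: cross-hybridization and
probe-affinity sequence effects, rRNA depletion artifacts, multi-mapping
reads, operon-internal promoters, condition-dependent (non-vegetative)
promoters, or rho-dependent termination, none of which the generator
models. The generator's noise magnitudes are free parameters, not published
values.

## Known limitations

- Weakly transcribed units fragment at the default noise level; fragment
  segments inflate the TU count and can be misclassified upward because a
  segment's FC is averaged over its *significant* probes. This mirrors the
  platform's real behaviour on weak signals but means desk-scale TU counts
  are not comparable to annotation-scale counts.
- The EM promoter model is single-motif; alternative sigma-factor motifs
  would be absorbed into the background or missed.
- The terminator score is a pairing heuristic; candidates with equal scores
  resolve by fixed tie-breaks, not thermodynamics.
- `classify_termination` needs gene-bearing TUs for the 3′-UTR overlap test;
  gene-free (sRNA) units only receive hairpin/polyT classes.
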