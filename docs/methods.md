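# Methods

## Synthetic loci

A locus is `flank5 + unit × N + flank3`. The built-in presets use the
geometry of the published reference material for the D4Z4 region: a 4,823-bp
centromeric flank, an 865-bp telomeric flank and a 3,306-bp unit, with 13
(BAC analog), 17 (chr4 analog) and 20 (chr10 analog) copies. Sequence
content is i.i.d. uniform over {A,C,G,T}: the real locus is GC-rich, but no
computation in the pipeline depends on composition, so uniform content keeps
the generator simple while the coordinates, copy numbers and flank classes
remain exact ground truth. Rejection sampling enforces the contracts that
make the assay work: flanks dissimilar from the unit (anchors unambiguous),
the three telomeric-flank variants A/AL/B pairwise ≤ 70% identical, ATTAAA
(the polyadenylation-signal analog) planted in A and AL and scrubbed from B.
One family seed also yields chr10-homolog flanks whose repeat-proximal 1 kb
stays ~97% identical to the chr4 version while the distal parts are
independent — the same proximal-homology / distal-divergence structure that
makes chr4/chr10 assignment non-trivial in real data.

The BAC analog is 48,666 bp (13 exact copies); the real excised EcoRI
fragment is 49,877 bp because its first partial repeat and pLAM region are
not exact unit copies. This divergence is deliberately not modelled: the
pipeline's claims are about recovery of a known truth, not about the exact
composition of one clone.

## Read simulation

Errors are applied per reference base: substitution with probability
`p_sub` (default 0.10), deletion `p_del` (0.01), and an independent
single-base insertion after the position with probability `p_ins` (0.01) —
about 12% total error, substitution-dominant, matching a MinION 1D profile.
A substitution is a transition (purine↔purine / pyrimidine↔pyrimidine) with
probability `ts_fraction` (default 0.70, the transition share observed in
nanopore consensus errors), otherwise a uniform transversion. Optionally,
`p_sub` is multiplied at CCNGG motif centers (`hotspot_multiplier`, default
1 = off) to emulate the context-dependent miscalls seen in real data.
Indels are single-base; real nanopore indels cluster in homopolymers, which
this generator does not model, so passing tests say nothing about
homopolymer-driven failure modes. Every edit is recorded in a ledger;
replaying the ledger reproduces each read byte-for-byte, which is the
anchor for all recovery tests.

Coverage-mode reads draw lognormal lengths (median 8,000 bp, σ = 0.45,
motivated by the ~7.6-kb average read length of the emulated run) and
uniform fragment positions; fragments overhanging the locus are truncated
at its boundary, so edge columns receive the same expected depth as the
middle — the behaviour of reads from an excised linear fragment.

## Alignment engine

Scores are log-odds in nats divided by `scale_lambda`:
`s(a,b) = log(P(b|a)/bg(b))/λ`. The untrained default is +1/−1 with gap
open −2 and extend −1 (a gap of length L costs `open + L·extend`); λ is
calibrated Karlin–Altschul style (`Σ p_i p_j e^{λ s_ij} = 1`), giving
λ = ln 3 for the default matrix under uniform background. Inputs up to
4 M cells are solved by exact affine-gap Smith–Waterman; larger pairs use
12-mer seeding, diagonal-bucket clustering (64-diagonal buckets), and
banded DP with a pad of 96 + 3% of the query length — generous against
indel drift at 2% indels. Ties between equal-scoring alignments break
deterministically (smaller ref start, then query start, then + strand).

Reads placed inside a tandem array are ambiguous modulo the unit length.
During consensus building, near-tied seed clusters (support ≥ 0.8 of the
best) are resolved by a seeded RNG so coverage spreads over equivalent
placements; during model training the choice is deterministic so that the
tally changes only with the model.

**Training** is Viterbi-style EM: align all reads with the current model,
tally substitution and gap events with pseudocount 1, convert tallies to
probabilities and log-odds, repeat (default 10 iterations, stop when all
probabilities move < 1e-4). The tally log-likelihood is checked
non-decreasing with a 1e-3 relative slack: with hard (Viterbi) alignments
strict EM monotonicity is not guaranteed, and the slack covers the small
re-alignment fluctuations observed in practice. On simulated data the
trained model recovers the planted substitution rate within ±20% relative
and the transition share within ±0.1.

**Mismap.** The placement posterior over candidate scores is
`softmax(λ·s)` with a null hypothesis of score 0 appended;
`mismap = 1 − max posterior`. A single candidate gives the closed form
`1/(e^{λs}+1)`. This is our analog of an aligner's mismap estimate; the
published tool's exact computation is not documented, so the construction
is stated rather than matched.

**Wraparound alignment** is global in the query; the start column within
the unit is free, and the diagonal move into column 1 comes from column m
at no cost. The traceback is split at wrap points into traversals. A
traversal counts as a copy when it covers ≥ `completeness` (default 0.9)
of the unit columns. The published analysis counts repeats from a dotplot
without stating a rule; 0.9 is our operationalization and is configurable.
Consequence: a segment whose two end traversals both fall just under the
threshold can have `fractional_copies − copy_count` approaching 1.8, which
is why the fractional estimate is always reported alongside the integer.

`switch_penalty` in split alignment defaults to 15 score units and the
haplotype margin to 25: both were fixed against the construction contracts
of the generator (30%-divergent flanks never tie; chimeric fixtures split
correctly) before being frozen.

## Pipeline thresholds

Anchor extraction keeps the published operating point as its CLI default
(alignment length > 2,000 bp, mismap ≤ 1e-10, designed for a 5.7-kb probe);
synthetic fixtures with small anchors pass `min_len=500`. Locus assignment
uses error probability ≤ 1e-5 on the softmax over per-reference chained
totals; repeat content shared between candidate loci cancels in that
posterior, so flank sequence carries the decision, and reads containing
only repeat are reported `ambiguous` rather than dropped.

Period estimation scans every shift p and takes the smallest p whose
normalized self-mismatch is within `max(0.005, 0.25·d_min)` of the
minimum: exact on noiseless arrays (distance 0 at the true period, ties at
multiples), and robust to the sampling noise between near-tied multiples on
noisy input. Indel-heavy input breaks the Hamming comparison and is out of
scope for this estimator.

## Consensus

Majority mode takes the per-column plurality over {A,C,G,T,deletion} with
the fixed tie order A<C<G<T<deletion. Weighted mode scores each truth
state `a` by `prior(a) · Π_reads P(obs|a)` using the trained substitution
matrix, with deletion as a fifth truth state governed by the trained gap
open probability and a deletion prior of 0.02; it assumes read errors are
independent across reads and positions given the truth — true of the
simulator, approximate for real pores. Insertions are emitted when more
than half the spanning reads agree. Zero-depth columns become `N` and are
flagged. Identity is `100 × match columns / all alignment columns` of a
global alignment (computed with edlib), mismatches and indels each costing
one column, end gaps on the consensus side free; with substitution-only
differences this reduces to `1 − diffs/length`, which makes the worked
example 75/49,877 → 99.85% exact.

Recurrent errors group substitutions by (unit offset, base change) and
require ≥ 3 distinct unit copies (`min_units`, configurable — the source
analysis reports recurrent errors without stating a threshold). Motif
context asks whether the truth 5-mer around the error matches CCNGG with
the error at the center.

## Problem sizes in the default test suite

The module suites run on geometry-scaled loci (600/300-bp flanks, 200-bp
unit, the same 13/17/20 copy numbers) so that the 20-seed recovery and
50-seed weighted-vs-majority properties stay cheap; the acceptance tests
and `scripts/acceptance.py` run the full-scale presets (3,306-bp unit, 30×
coverage for the consensus target). Training in the drivers uses 4
iterations, which is past the point where the log-likelihood plateaus on
this data.

## Known limitations

No signal-level simulation, basecaller emulation, homopolymer indel
modelling, quality-aware alignment, genome-scale indexing, diploid
genotyping/phasing, or methylation. The digest searches the forward strand
only (EcoRI's site is its own reverse complement, so this matches
double-strand behaviour for the default). Low-complexity masking is not
implemented; the generator's sequences are unmasked by construction.
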