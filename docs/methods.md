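# Methods

## Scope and design

The package models the desk side of a plant small-RNA sequencing study:
given four adapter-ligated sRNA libraries from a 2×2 control/NaCl-treated ×
root/shoot design, it identifies conserved miRNAs against a mature catalog,
discovers novel miRNAs by hairpin criteria, predicts their targets, and
quantifies relative expression from qPCR, densitometry and luciferase
measurements. Because the raw libraries of the motivating study were never
deposited, every stage is driven by a synthetic-data generator with a known
ground truth; the published hairpin-statistics and read-accounting tables
are carried as fixed reference inputs (`saltmir.published`) for arithmetic
cross-checks.

## Synthetic data generator

The generator defines the study conditions assumed everywhere else:

* **Genome**: 1 chromosome × 50 kb at GC 0.43 (rice-like), with 10 planted
  pre-miRNA hairpins by default. Each hairpin is built from a random 20–24 nt
  mature, a star that is its reverse complement with 0–3 programmed
  non-pairing substitutions (neither Watson–Crick nor G:U with the opposing
  base) and the canonical 2-nt 3' overhang, an 8–20 nt A/C-only loop (A and
  C cannot pair with each other, discouraging alternative loop structure),
  and an 18 nt perfectly paired lower stem. Every construct is validated by
  folding: the mature must sit in the requested arm with exactly the
  requested number of unpaired positions and the whole precursor must pass
  the discovery criteria; flanks are resampled within a retry budget
  otherwise. This "closure" property is asserted in tests.
* **Libraries**: 1e5 reads per library. Reads are insert + 3' adapter +
  deterministic fill, truncated to a 50 nt sequencer read with constant
  Phred 40 quality, so adapter read-through and the trimming path are always
  exercised. The default adapter is the Illumina TruSeq small-RNA 3'
  adapter `TGGAATTCTCGGGTGCCAAGG` (the assay emulated uses that kit; the
  adapter is configurable because the original sequences are not reported).
* **Composition**: 25% contaminant reads (windows of a synthetic
  tRNA/rRNA/snoRNA set), planted matures per programmed RPM, and random
  genomic background with a 16–35 nt length distribution peaking at
  23–24 nt, matching the non-redundant length profile typical of plant
  sRNA libraries (the 24 nt DCL3 class dominating).
* **Expression model**: each locus draws a log-uniform base abundance
  (200–2000 RPM) and per-locus tissue and salt-response multipliers from
  {1/3, 1, 3}, giving tissue-specific and salt-responsive planted truths.
* **Quota sampling**: per-library read composition uses exact quotas —
  `round(rpm × usable/1e6)` reads per mature, a rounded contaminant quota,
  background filling the remainder — followed by a seeded shuffle, rather
  than multinomial draws. Observed RPM therefore reproduces programmed RPM
  up to rounding (within 10% for RPM ≥ 100 at the default depth), which
  lets downstream recovery tests measure pipeline behaviour instead of
  generator sampling noise.
* **Randomness**: one integer seed fans out to fixed per-purpose substreams
  (`numpy.random.default_rng([seed, stream])`), making whole runs
  byte-reproducible. Bit-identity across library versions or platforms is
  not claimed.

What the generator does **not** emulate: sequencing errors beyond an
optional uniform substitution rate, base-quality structure, 5' adapters,
multi-locus miRNA families, isomiR end heterogeneity, RNA editing, and the
genomic repeat structure that makes multi-mapping a real problem at genome
scale. Passing recovery tests therefore demonstrate the correctness of the
pipeline's logic under clean conditions, not its performance on real
libraries.

## Filter cascade

Stages, in order, each conserving reads by reason code: mean-Phred ≥ 20
gate on the raw read; leftmost 3' adapter match (prefix overlap ≥ 8 nt,
≤ 1 mismatch per 10 aligned bases; adapterless reads longer than 35 nt are
rejected as read-through) with a ≥ 15 nt insert requirement; a second
mean-Phred ≥ 20 gate over the insert; ncRNA removal by exact substring
membership against the contaminant set (both strands, T/U-normalised —
deterministic and aligner-free); and a final 16–35 nt / no-N /
low-complexity filter. Low complexity is a DUST-like rule chosen for
testability: a single base covering ≥ 80% of positions or one tandem
dinucleotide repeat covering ≥ 80%. The two quality gates model the
"first/second QC" stages of standard sRNA accounting whose exact parameters
are never published; both thresholds are configurable. RPM uses the
post-cascade ("usable") read count of each library as denominator.

## Hairpin criteria

A candidate window (flank grid {(0,250), (250,0), (100,100)} around each
perfect genome hit, covering 5p and 3p placements up to ~275 nt precursors)
is folded with ViennaRNA's nearest-neighbour model; the precursor is then
trimmed to the stem-loop enclosing the mature/star duplex (walking outward
along enclosing base pairs) and refolded, so MFE, MFEI and A+U describe the
hairpin rather than arbitrary flanks. Verdicts: precursor ≥ 60 nt; a single
terminal loop within the duplex span; mature entirely in one arm (a mature
spanning the loop is a structural failure); duplex mismatches — unpaired
mature positions under the fold — ≤ 6; MFE ≤ −15 kcal/mol; MFEI ≥ 0.64;
A+U between 20 and 85%. The duplex-mismatch ceiling is 6 rather than 5
because the reference table itself prints a 6-mismatch duplex; the star is
evidence, not a criterion, so star-less candidates can still be called.
Novel calling requires a perfect (0-mismatch) genome hit and at most 20
loci per tag; tags need a total count ≥ 10 across libraries before folding
is attempted, the conventional abundance floor for miRNA qualification,
which also keeps discovery tractable. Best window per tag is chosen by
(all criteria passing, then lowest MFE).

Mapping is plain exact string search on both strands — appropriate at the
synthetic genome's scale; swapping in an aligner would only change the
`map_tags` internals.

## Target expectation score

The score follows the classical plant target-prediction convention
(2011-style psRNATarget schema): per aligned miRNA position 0 / 0.5 / 1 / 2
for Watson–Crick / G:U / mismatch / gap, doubled at miRNA positions 2–13
from the 5' end, at most one gap per alignment, cutoff 3.0 inclusive.
For a gap column the weight of the next miRNA base is used. The scan
enumerates every window of length m−1, m, m+1 and every registration; a
seed-first early-abort bound (sound because penalties are non-negative)
keeps this exact but fast. Hits are non-overlapping best-per-locus, sorted
by expectation then transcript and position. Cleavage is reported as the
transcript coordinate of the base paired with miRNA position 10 (the cut
falls 5' of it, i.e. between the partners of positions 10 and 11); a gap
opposite positions 10–11 degrades the prediction to an interval.

One stated symmetry — invariance of the score under simultaneous
reverse-complement of miRNA and target — cannot hold exactly: seed
weighting is anchored to the miRNA 5' end, which the transformation flips,
and a G:U wobble becomes a C:A mismatch on the complementary strands. The
implementation instead guarantees the underlying unordered pair-penalty
symmetry and is verified against an independent direct scorer and
exhaustive enumeration.

## Expression quantification

Pfaffl ratio `E_t^ΔCt_t / E_ref^ΔCt_ref` with ΔCt = mean Ct(control) −
mean Ct(treated), so treatment-induced up-regulation gives ratios > 1;
efficiencies default to 2.0 (the ratio then reduces to 2^−ΔΔCt).
Significance uses a two-sided paired t-test on per-replicate
ΔCt(target−reference) pairs (the modality's design: 2 biological × 3
technical replicates, n = 6); all-zero differences return p = 1 exactly.
Densitometry folds are (band_t/U6_t)/(band_c/U6_c), scale-invariant by
construction. Luciferase assays compare per-leaf F-Luc/R-Luc ratios between
sensor-only and sensor-plus-overexpressor groups (n = 9 leaves) with a
Welch two-sample test — unequal variances are the safe default when the
underlying test is unspecified — and report mean ± sd with ** / *** stars
at p ≤ 0.01 / 0.001. The parameter-recovery check simulates replicate
experiments at n = 6, σ(Ct) = 0.2 and requires the median estimate across
experiments to land within 15% of the programmed fold; a median over
replicate experiments is used because a single experiment's estimator has
~12% relative standard deviation at these settings, so a one-shot 15% check
would measure the noise realisation, not the estimator.

## Numerical choices and degenerate inputs

Folding accepts 40–500 nt over ACGTU (DNA input is transcribed on the fly);
non-ACGTU symbols are errors. A library with zero usable reads is an
explicit error state (RPM undefined). Catalog ties at equal mismatch count
break lexicographically by name and are flagged ambiguous. MFEI is
undefined at G+C ∈ {0, 100} and raises. Coordinates are 0-based half-open
internally and 1-based inclusive in GFF3; minus-strand precursors are
reported 5'→3' on the read strand. The dinucleotide shuffle used for the
empirical false-discovery check is the Altschul–Erickson Eulerian-walk
shuffle, preserving exact dinucleotide counts.

## Problem sizes

Default analysis and acceptance-test conditions: 1 × 50 kb genome, 10
planted hairpins, 4 × 1e5 reads, 8 × 400 nt transcripts. The end-to-end
determinism check runs at 20 kb / 5 hairpins / 4 × 2e4 reads, since it needs
two complete runs and byte-level comparison rather than statistical power.

## Known limitations

* The hairpin criteria reproduce the classical rule set, not a
  probabilistic model (no randfold-style shuffling p-value, no read-stack
  plausibility scoring à la miRDeep).
* Target scoring has no accessibility/energy (UPE) term and no
  translational-inhibition classification.
* Exact-substring ncRNA matching misses diverged contaminants a profile or
  alignment method would catch.
* The conserved/novel split depends entirely on the supplied catalog; no
  cross-species conservation analysis is attempted.
* No multiple-testing correction is applied to the expression p-values (the
  emulated workflow applies none); interpret per-gene stars accordingly.
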