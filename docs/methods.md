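# Methods

## Editor model

A base editor is represented purely as targeting data: conversion chemistry
(A→G or C→T on the protospacer strand), IUPAC PAM pattern and side,
protospacer numbering convention, and three nested position sets — the
*activity window* (positions edited at appreciable frequency), a
*precision window* (subset counted as high-precision placements) and
optional *preferred positions*. Windows are stored as explicit integer
sets, not ranges, because several characterised constructs have
non-contiguous windows (e.g. a C-terminal ABE fusion with peak activity at
A13 and modest activity at A2–A4, A6, A8–A12 and A15–A18). The model
deliberately carries no efficiency magnitudes: measured editing
frequencies are experimental outcomes, not properties of the window
geometry, so windows are binary/tiered sets only.

Two numbering conventions are first-class, because the packaged registry
mixes Cas12f constructs with nCas9-based ones:

* `cas12f_r_zero` — TTTR PAM 5′ of the protospacer; the R base is position
  0 and the base immediately 3′ of it is position 1.
* `spcas9_pam_distal` — NGG PAM 3′ of the protospacer; positions 1..20 are
  counted from the PAM-distal end.

The default registry (JSON, packaged; user-suppliable override with the
same schema) contains 22 entries: 6 miniature ABEs, 12 miniature CBEs, two
nCas9 TadA-reprogrammed CBEs, and two composite "union" pseudo-editors
(`miniABE-any`, A2–A18; `miniCBE-any`, C3–C20) representing the pooled
targeting scope of the family for cohort scans. Every entry carries a
mandatory free-text provenance note describing the characterisation its
windows were read from, since windows entered the registry from prose
descriptions and must stay auditable. Where a construct showed a modest
secondary tier (A18–A19 for the C-terminal TadA\*(V82G) fusion;
C14–C17 for the C-terminal GGATY fusion), the secondary tier is encoded in
the activity window and the headline tier in the precision window, so
consumers can choose either reading.

## PAM scanning and coordinates

Scanning is a linear pass over both strands reporting every placement
whose PAM matches and whose full protospacer (default 20 nt, configurable
per editor) lies within the sequence. Overlapping matches are all
reported; deduplication is the caller's concern. An `N` in the sequence
matches only an `N` in the pattern — conservative behaviour for design
use. Internally all coordinates are 0-based half-open plus-strand;
reported TSVs are 1-based inclusive. Position↔coordinate conversion is
exact and round-trips for all positions; a placement records its
convention and queries under the wrong convention raise rather than
silently misnumber.

## Correctability and precision

Classification always scans the *alt-carrying* flank — the molecule
actually present in the patient genome — so a variant may create or
destroy its own PAM. A variant is correctable by an editor iff on some
strand the alt allele equals the editor's substrate base and some
placement puts it at an activity-window position such that the programmed
edit restores the reference allele. Bystanders are the other
activity-window positions carrying the substrate base under that
placement.

"Precisely correctable" is operationalised as: some qualifying placement
puts the target in the precision window AND no bystander exists anywhere
in that placement's activity window. This is the strictest reading
consistent with single-base-resolution editing; a laxer scope tolerating
bystanders outside the precision window is available
(`bystander_scope="outside_precision"`).

Flanks must be long enough to host every placement whose window could
cover the variant (protospacer length + PAM − 1 on each side; the default
flank radius of 30 nt covers TTTR + 20 nt under both orientations). A
short flank raises an explicit error, never a silent false verdict.

Cohort tables report, per editor and per plus-strand transition class
(A>G, C>T, G>A, T>C, plus `all`), the class size, correctable and precise
counts, and the derived fractions — numerators and denominators are always
emitted so every fraction is auditable, and an empty class yields NaN, not
0. The table exposes all class × editor cells rather than hard-coding
which transition class "belongs" to which chemistry, because a plus-strand
A>G variant is corrected by a CBE acting on the minus strand and both
mappings are legitimate summaries. Precise fractions are reported both
against the class and against the correctable subset.

Installation design enumerates placements putting the target in the
activity window on a chemistry-compatible strand and ranks candidates by
(precision-window placement, fewer bystanders, preferred position, smaller
position number).

## Amplicon quantification

The read model is gapless: reads are full-length copies of the amplicon
reference, and length-mismatched (indel-bearing) reads are rejected and
counted (>50 % rejection is a hard error). Indel calling, trimming,
merging and base-quality weighting are out of scope. The substitution
matrix counts A/C/G/T calls per reference position; N and out-of-alphabet
calls are excluded from the informative depth at that position.

Editing profiles map protospacer positions (0..L under the Cas12f
convention — position 0, the R itself, is editable when it is the
substrate base — and 1..L under the SpCas9 convention) to
substrate→product frequencies; positions whose reference base is not the
substrate are *absent*, which is distinct from zero and preserved through
aggregation (absent positions leave both numerator and denominator).
Frequencies are reported only where informative depth reaches a
configurable minimum (1 in library defaults and tests; the CLI default of
100 reflects amplicon-sequencing practice). Cross-site aggregation reports
mean ± SEM (SEM of a single site is NaN) with per-position n. The editing
window of an aggregated profile is called as all positions reaching a
threshold fraction (default 0.5) of the peak mean; the peak is the argmax.
Ties everywhere resolve to the smallest position/coordinate — stated once,
applied uniformly.

Product purity at a substrate position is the outcome-base mix among
*edited* reads, an edited read being any read with a non-reference call at
that position; zero edited reads yield an explicitly flagged undefined
result, never 0. Allele tables tabulate the joint states over all editable
window positions, always include the unedited reference combination, and
report the desired-allele proportion among all reads and among edited
reads. Context preference assigns each editable position's frequency to
its 3′-neighbour class (target first: CA/CT/CC/CG for a CBE) and
5′-neighbour class (target second: AC/CC/GC/TC), with neighbours read on
the placement strand, and ranks classes by mean frequency using
competition ranking so exact ties share a rank. On/off-target ratios floor
an observed zero off-target frequency at one read (1/depth) and flag the
flooring; both same-position and max-vs-max comparisons are available,
max-vs-max being the default since off-target windows need not align with
on-target ones. R-loop statistics sum per-position substrate→product
frequencies over a window and report the maximum with its position.

## Hard filtering and edit counting

The RNA-editing hard filter is the literal disjunction
`QUAL < 25 || MQ < 20.0 || QD < 2.0 || FS > 30.0 || DP < 20`: a record
fails when any clause holds, boundary values pass (strict inequalities),
and a missing annotation fails with reason `missing:<FIELD>`. Thresholds
are configurable but must be finite. Relaxing any single threshold can
never decrease the pass count (verified as a property). Without transcript
annotation the strand of an RNA edit is unknowable, so passing A>G and
T>C records are pooled as the A-to-I class and C>T/G>A as C-to-U, with
the full 12-class transition table exposed for annotation-aware
re-slicing. A position-level set-difference helper supports
"relative to parent sample" comparisons; whether to apply it is the
caller's choice, since germline subtraction conventions vary.

## Synthetic data

The generator produces every input the pipeline consumes, under one
mandatory integer seed; sub-stream generators are derived at fixed offsets
so identical configurations give byte-identical FASTA/FASTQ/VCF/TSV
outputs.

* **Cohorts** are built by inverse construction: choose a window position
  (precision window for precise intents), write a concrete PAM instance on
  the chosen strand, clear the window of substrate bystanders (precise) or
  force one (correctable-but-imprecise), and leave everything else uniform
  random. Every constructed flank is then *certified* by an internal
  brute-force enumerator, with rejection sampling until the verdict equals
  the intent — truth is computed, not assumed, and incidental PAM
  collisions in the background are left for the scanner to cope with.
  Planted counts (default 100 variants, 25 correctable, 10 precise) are
  therefore exact. A single-position window with precision equal to
  activity admits no correctable-but-imprecise variant; requesting one is
  a configuration error.
* **Reads** are drawn per co-editing model with sequencing error applied
  after editing. The independent model edits each planted position by a
  Bernoulli draw at its planted frequency; the linked model represents a
  single latent edited state per read and plants an exact (rounded) count
  of fully edited reads, so desired-allele proportions are exact at zero
  error. The outcome base is drawn from a configurable purity mix (default
  pure substrate→product). Sequencing error substitutes each base
  uniformly among the other three at a default rate of 0.001, a typical
  Illumina substitution rate; no quality-score model is simulated.
* **Called variants** follow a schedule of "pass" or a single named
  failing clause, with annotation values drawn uniformly from ranges on
  the passing or failing side of each threshold; every record is
  re-checked against the filter at generation time.

What the generator does *not* emulate — indels, PCR/optical duplicates,
quality-dependent errors, strand bias, real ClinVar class composition and
flank GC structure, linkage between nearby loci — bounds what passing
tests show: they certify the combinatorics, coordinate algebra, counting
and conservation properties of the pipeline on idealised data, not
performance on real sequencing artefacts.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale sizes chosen to exercise
every code path with comfortable statistical margins: 200 random 2-kb
contigs for scanner/oracle equivalence, 500-variant cohorts for classifier
certification, 5000 reads × 20 seeds for frequency recovery (binomial
3-SE bounds), 1000 randomized records for the filter truth table.
Frequencies are plain double-precision ratios of integer counts; no
iterative numerics are involved anywhere, so results are exactly
reproducible across platforms. Verdicts and set outputs are compared
exactly; simulated frequency recovery is judged against planted values at
3 binomial standard errors.
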