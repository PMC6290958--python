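# Methods

## Assay model

The package models a single-amplicon ultradeep sequencing assay for the
exon-12 insertion mutations that define NPM1-mutated AML.  One PCR amplicon
(~250 bp) covers the insertion hotspot; libraries are dual-indexed with 10-nt
sample barcodes on both primers and sequenced paired-end at 150 bp, so every
fragment spans the full amplicon and every read pair overlaps in the middle.
The measured quantity per sample is the variant allele frequency (VAF) of
each insertion: supporting reads over hotspot-spanning depth.  Patient-level
MRD is the log10 reduction of that VAF between the post-induction (PI) and
post-consolidation (PC) time points, dichotomized at 1 log.

## Coordinates, reference and catalog

All internal coordinates are 0-based, half-open; an insertion is a
`(position0, inserted)` pair meaning the bases sit between `position0 − 1`
and `position0`.  HGVS `c.`-numbering exists only at the parse/format
boundary via the reference's `coding_offset`.  Equivalent indel
representations are grouped by VCF-style left alignment (shift left while
the base left of the gap equals the last inserted base, rotating the
inserted string); the left-normal form is the canonical representative for
counting, catalog lookup and reporting.

The packaged reference (`data/synthetic_amplicon.fasta`) is a **synthetic
stand-in**: the assay's true primer-defined amplicon is not public.  It
reproduces the geometry that matters — 250 nt, a 30-nt hotspot window at
amplicon positions 100–130 (c.861–c.890), a cDNA anchor such that the
published `c.873_874insGCCA` falls inside the hotspot — and every module is
parameterized by `AmpliconReference` so a real amplicon substitutes cleanly.
The 12-entry catalog anchors types A/B/D to their literature-standard
inserted tetramers (TCTG/CATG/CCTG at c.863_864) and includes the published
GCCA insertion; the remaining eight entries are synthetic fixtures standing
in for the assay's uncommon subtypes.  Catalog entries are validated on load
to be left-normal fixed points, mutually distinct, and inside the hotspot.

## Read simulation

The generator is the package's definition of the study conditions, with
known truth for every sample:

* **Mutant sampling** — each of `n_fragments` input molecules carries the
  configured insertion with probability `mutant_fraction` (binomial); the
  exact mutant count is recorded as truth.
* **Error model** — independent per-base substitutions at `sub_error_rate`
  (default 10⁻³, a typical short-read platform figure) and 1-nt
  insertion/deletion errors at `indel_error_rate` (default 10⁻⁶).  Base
  qualities are the Phred equivalent of the substitution rate.  This is the
  simplest model that makes the limit of blank non-trivial while letting
  tests switch background off exactly.
* **Run structure** — reads from all samples are concatenated with their
  `i7+i5` indices in the header comment (index-read FASTQ dialects are out of
  scope).  Index hopping replaces one index (coin flip) of a `hop_rate`
  fraction of a sample's reads with another sample's index.  The
  bioinformatics control is a separate library under a reserved index pair
  in which every molecule carries a fixed 20-nt insertion.
* **Seeding** — one master seed per sample/experiment; derived streams use
  `numpy.random.SeedSequence([master, key, …])` (`derive_seed`), so cohorts
  are reproducible sample-by-sample and FASTQ output is byte-identical
  across reruns (gzip written with fixed mtime).

Features of real data deliberately not modeled: PCR duplicates/jackpotting,
quality decay by cycle, UMIs, primer artifacts, and non-uniform error
spectra.  Passing tests therefore demonstrate correctness of the pipeline's
logic and statistics under idealized noise, not performance on a real
instrument run.

## Pipeline stages

**Demultiplexing.**  A read is assigned to a sample only when both indices
match that sample's row within `max_mismatch` (default 1, standard Illumina
practice); the sheet must keep same-role indices at Hamming distance
≥ 2·max_mismatch + 1, checked up front, so assignment is unambiguous.  An
i7 matching one sample and i5 another is a conflict: counted, quarantined to
its own FASTQ for audit, and never assigned.  `assigned + unassigned +
conflict = total` holds exactly.

**Merging.**  The overlap maximizing (matches − mismatches) wins, ties going
to the longer overlap; pairs are rejected when the best overlap is shorter
than `min_overlap` (20) or its mismatch fraction exceeds 0.25.  Agreeing
overlap bases get quality min(q1 + q2, 41); disagreements take the
higher-quality base (read 1 on exact ties) with quality |q1 − q2|.  This is
a deliberately simplified, fully specified consensus rule rather than a
probabilistic posterior model; amplicon geometry guarantees overlap, so
unmergeable pairs are treated as suspect and excluded from depth.

**Alignment and calling.**  Merged reads are aligned to the amplicon itself
(global, affine gaps: match +1, mismatch −2, a gap of length L costs 6 + L)
rather than to a whole genome — for a single-locus assay the information is
identical and the direct route is orders of magnitude faster.  The alignment
engine is Biopython's `PairwiseAligner`; reported insertions are
left-normalized, so gap-placement tie-breaks cannot affect results.  Reads
with more than 20% mismatched bases, or length outside ±50% of the amplicon,
are unalignable and excluded from depth.  Three fast paths keep million-read
samples at interactive speed: an exact-reference check, a memo keyed on the
read sequence (reference and mutant haplotypes recur massively in amplicon
data), and a gap-free scorer for reference-length reads with ≤ 3 mismatches
— provably optimal under the scoring above, since any gapped alignment of
equal-length sequences costs at least two gap opens (−14) and can win only
by avoiding ≥ 5 mismatches.  Bit-identity of fast and slow paths is
property-tested, and the full aligner is tested equal to an independent
unbanded Gotoh dynamic program.

The calling rule is the assay's: a grouped, left-normalized insertion inside
the hotspot passes with ≥ `min_mutant_reads` supporting reads (default 2).
The VAF denominator is reads whose alignment spans the hotspot with ≥ 10 nt
of flanking reference on each side — a conservative, explicit choice of
denominator.  All distinct insertions are reported (clonal-switch
surveillance), sorted by VAF.  A run is only reportable if its
bioinformatics control yields a passing call of the expected 20-nt
insertion.

## Validation statistics

* **Limit of blank** — nonparametric order statistic: with n sorted blank
  background VAFs, LOB = x(⌈(1−α)·n⌉), α = 0.05 by default; 0 when all
  blanks are clean.  This is the standard clinical-assay (CLSI-style)
  nonparametric form; α = 0 degenerates to the maximum.
* **Limit of detection** — smallest dilution fraction detected in
  ≥ `required_hit_rate` (default 0.95) of replicates with all measured VAFs
  above the LOB; "not reached" is an explicit outcome carrying the full
  table.  Replicates default to 3.  No parametric (probit) fit is provided.
* **Precision controls** — high (0.2%) and low (0.02%) VAF controls in every
  run, evaluated Levey-Jennings style against the running mean/SD of prior
  runs (the first 5 runs establish the baseline).  |z| > 2 warns, |z| > 3
  fails, and two consecutive same-side warnings on one level escalate to
  failure; a missing control fails the run.  Failing values are excluded
  from subsequent limit updates; warning values are kept, because excluding
  everything beyond 2 SD truncates the spread, biases the SD estimate low
  and spirals into false rejections.  Following standard laboratory QC
  semantics, a single 2 SD warning flags a run for inspection but does not
  reject it.  At 50,000-read depth, pure counting noise leaves well over 90%
  of runs accepted.

The error-free control configuration (substitution and indel rates 0 at
50,000 fragments) isolates the binomial counting noise that dominates
precision at these depths.

## MRD classification

`log_reduction(pi, pc) = log10(pi/pc)` with explicit sentinels: clearance
(PC = 0 < PI) is +∞ and negative; a mutation appearing only at PC is −∞ and
positive; both time points zero is recorded as NaN and classified negative —
the assay's stated rule for double-negative patients.  Classification is
`positive ⇔ log_reduction < cutoff` with the shipped default cutoff of
1 log.  For cutoff re-derivation, candidate ROC thresholds are the midpoints
between consecutive distinct finite log-reductions, one threshold below the
finite minimum (separating −∞ from the finite cohort), and ±∞; Youden's
J = sensitivity + specificity − 1 is maximized with ties broken toward
higher sensitivity, then lower threshold.  Both-zero patients enter ROC
training as +∞ (indistinguishable from clearance, consistently with their
fixed negative classification).  The outcome label is a user-supplied binary
event; survival modeling is out of scope.

## Problem sizes and numerical choices

The sensitivity experiment uses four dilution levels (10⁻²…10⁻⁵) at 500,000
reads per level with substitution errors at 10⁻³ and indel errors off; at
10⁻⁵ the expected five mutant molecules give a ~96% chance of clearing the
two-read rule, so the experiment occasionally (and correctly) reports a
detection floor one level higher under an unlucky seed.  Precision controls
run at 50,000 reads; catalog-breadth samples at 10,000 reads and 5% mutant
fraction; blanks at 2,000–50,000 reads depending on the experiment.  Unit
and property tests use 10²–10⁴-read samples.  Quality scores are clamped to
Phred [2, 41]; merging ties on quality resolve to read 1; call ordering is
VAF-descending with the insertion spec as a deterministic tie-break.

## Known limitations

* The amplicon and eight catalog entries are synthetic stand-ins; absolute
  positions and flanking contexts differ from the clinical assay.
* The uniform error model understates structured errors (homopolymer slips,
  strand bias); the LOB measured here is an idealized floor.
* Only insertions are monitored — substitutions and deletions at the locus
  are out of scope, as are multi-gene panels.
* The Youden cutoff from the original clinical cohort (J = 0.42 at 1 log)
  depends on patient-level outcome data that is not redistributable; the
  package ships the procedure and the 1-log default, not the cohort.
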