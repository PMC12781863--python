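# Methods

This note documents the models, parameters and design choices behind
`splicedx`, what the synthetic-data generator does and does not emulate,
and the numerical conventions used throughout.

## Coordinates and annotation

Internal coordinates are 0-based half-open (`GenomeInterval`); HGVS-facing
and splice-junction-table coordinates are 1-based inclusive, converted only
at type boundaries.  A `TranscriptModel` keeps exons in transcription order
(descending genomic coordinates on the minus strand), so transcript→genome
projection is a single walk over exon lengths and is the exact inverse of
genome→transcript projection on exonic bases (verified exhaustively in the
tests).  Exactly one transcript per gene is *representative*: the
`MANE_Select`-tagged transcript when the GTF carries the tag, otherwise the
longest-CDS transcript with ties broken by transcript ID — a deterministic
fallback chosen so that annotation sets without curation still yield a
unique denominator for TID ratios.  Transcript and gene identifiers are
treated as opaque strings; representativeness is never inferred from an
accession prefix, because clinical reports mix RefSeq and Ensembl IDs
freely.

## HGVS-RNA parsing

The parser accepts the dialects that actually occur in diagnostic reports
rather than the full HGVS grammar: coordinate deletions/duplications with
optional length or sequence suffixes, insertions with sequence payloads or
intronic-offset payloads (bracketed or not, with or without an inner `r.`
prefix), exon-skip shorthand, and negative (5'-UTR-anchored) coordinates
with no position zero.  All Unicode hyphen/dash/minus variants are folded
to ASCII before parsing.  `length_nt` is always recomputed from the
coordinates; an explicit length that disagrees is a validation error, not a
silent preference.  For an offset-described insertion anchored at transcript
position *C*, the retained segment has length |offset₂ − offset₁| + 1 and
its genome interval is obtained by projecting *C* and walking into the
adjacent intron (acceptor side for negative offsets, donor side for
positive ones); anchors that are not exon-boundary positions are rejected.
The span length and the parsed length are computed by independent code
paths and asserted equal in the tests.

Frame classification uses any-overlap with the CDS (≥1 nt) and depends only
on `length_nt mod 3`: in-frame, frameshift, or noncoding/UTR when the
change misses the CDS or the transcript is noncoding.  Protein-level
consequence naming is out of scope.

One cataloged oddity: a reported insertion string whose offsets imply 98 nt
while the corresponding genomic change is a 26-bp deletion.  The parser
records the string literally and makes no attempt to reconcile the two
descriptions.

## Junction outlier calling

The caller consumes junction × sample matrices of uniquely-mapped
split-read counts (STAR `SJ.out.tab` or BED-like TSV dialects).  The
normalization is deliberately *local*: the denominator for a candidate
junction is the maximum count, in the same sample, over annotated junctions
sharing a donor or acceptor with it.  When the candidate spans two
canonical exon–intron boundaries this is the max of the two canonical
junction counts; when only one end is annotated (pseudoexon, cryptic site)
it is the max over junctions sharing that end.  Local normalization makes
the statistic invariant under per-sample count scaling — the point of the
construction, tested as a property — so gene expression level and library
size drop out without any global model.

Filter defaults: `min_reads = 5`, `min_norm = 0.05`, `fold_vs_second = 2`.
Tie-breaks are conservative for diagnostics: a shared exact maximum between
two samples yields no call ("maximal" is read strictly), while a
second-highest value of zero passes the fold condition vacuously (an event
absent from every other sample is the paradigm outlier).  Strand-unknown
junctions are compared against annotation on both strands.  All cohort
samples enter the comparison in filter (d).  No multiple-testing correction
is applied: the procedure is a deterministic filter, not a hypothesis test.
The implementation is checked for exact set equality against a brute-force
reimplementation on 200 random matrices.

## TID analysis

TID(sample) = TPM(isoform) / TPM(representative), undefined when the
representative is below `rep_floor = 1` TPM (mirroring the expressed-gene
TPM > 1 convention).  Splicing events are enumerated from annotation
isoform pairs rather than re-deriving them from reads: every internal exon
present in exactly one member of an (isoform, representative) pair with
shared flanks yields a skipped-exon event whose inclusion junctions are the
two flanking introns and whose skipping junction joins the flanks.  ψ uses
the junction-count form I/(I+S) with I the mean over inclusion junctions,
missing below 10 informative reads.  Differential screening is a two-sided
Fisher exact test of the case counts against pooled-control counts with
Benjamini–Hochberg correction across events, retaining |Δψ| ≥ 0.15 and
FDR ≤ 0.05 — a transparent exact test chosen over a paired-likelihood
splicing model so the screen is reproducible at desk scale.

No numeric TID outlier criterion is established in the diagnostic
literature; the rule here deliberately reuses the junction filter-(d)
geometry (cohort maximum, ≥ 2× the second-highest defined value, floor
0.05) as an explicit, configurable policy.  In *family mode* the comparison
set for a sample excludes co-affected relatives listed as such, so a
proband and an affected parent or sibling sharing the event can both be
flagged.

## Transcript realignment

The built-in aligner exists to make the stage testable end to end at desk
scale; external aligner/caller output can be substituted.  It is a
k-mer-anchored (k = 15) windowed Gotoh alignment: candidate transcripts and
diagonals are voted by seed hits, and the read is fit-aligned (read global,
free leading/trailing target bases) within a ±60 nt window using
match +1, mismatch −2, gap open −4, gap extend −1.  Traceback is
state-aware so long gaps stay contiguous.  Reads scoring below 25 % of
their maximum possible score are left unaligned; both strands are tried.

Indel calling is a pileup of gap operations, left-normalized against the
transcript sequence (the case-uniqueness test is ill-defined without a
normal form), with `min_support = 3` reads and `min_len = 3` nt — 1–2 nt
alignment noise would otherwise dominate.  Reads crossing a large indel
with a short flank admit mosaic gap decompositions (a cluster of small
gaps scoring above the single long gap); these pile up as low-support
satellite calls near the true event, so per-sample calls within 60 nt of a
stronger call on the same transcript are suppressed.  The cost is that two
genuinely distinct indels closer than 60 nt would merge — acceptable for a
targeted diagnostic caller and configurable off.

Case-unique retention keeps calls whose (transcript, position, ref, alt)
key occurs in at least one case sample and no control; case and control
batches are processed with identical parameters.  Map-back projects a
deletion through the exon structure and rebuilds the implied exon set: if
it reproduces another annotated isoform of the gene exactly (e.g. a
deletion excising precisely the cassette exon an annotated isoform lacks),
the call is classified `matches_annotated_isoform` and excluded as a
naturally occurring isoform; otherwise `novel_event`.  Insertion payloads
are searched against the flanking intron sequence so pseudoexon insertions
are localized to their intronic origin.

## Expression, AEI and signature stages

These are transparent substitutes for heavier machinery, and are labelled
as such in their output metadata.  Expression outliers use a robust z-score
on log2(TPM+1) — median/MAD (scaled by 1.4826) per gene, leave-one-in, |z| ≥ 3
on panel genes, MAD = 0 genes skipped with a note — explicitly *not* an
autoencoder-style confounder-corrected caller; downstream consumers must
not mistake it for one.  The expressed-gene filter takes mean or median
TPM > 1 and coverage > 10× (the two published conventions for cohort-wide
and panel-detection filtering).  Allelic imbalance is an exact binomial
test of the alt fraction against 0.5, evaluable from 20 reads — both the
evaluability floor and the null are policy, stated rather than implied.
Signature concordance is a Fisher exact 2×2 of case-DEG membership against
signature membership over a background universe; DEG lists themselves are
consumed as externally produced inputs.

## Cohort stratification and yield

Families carry a fixed tier (VUS / suspected-gene-variant-negative /
unsolved-no-candidate), a candidate-gene set, and per-stage findings.
Stages are credited in clinical order — conventional splicing, conventional
expression, TID, realignment, pharmacological — with the first
candidate-gene finding setting the family positive; findings outside the
candidate set are recorded as incidental and never flip status.  The
pharmacological stage is only evaluated for the two candidate-bearing tiers
(hypothesis-driven re-culture).  The orchestrator computes every configured
stage and enforces the sequential crediting during classification, which is
output-equivalent to physically skipping later stages for positives and
keeps stage outputs available for review.

Yield rates are reported at the conventional printed precision (integer
percent, one decimal for the large unsolved tier).  2/38 = 5.263 % sits
between two one-decimal conventions; the report emits both the half-up
rounding (5.3) and the floored value (5.2) in its raw metadata instead of
silently choosing one.  Positives and definitive diagnoses are tracked
separately (a family can be RNA-positive while its variant remains a VUS).

## Synthetic data: what it emulates and what it does not

Defaults encode the study conditions the stages are specified against: one
case plus 7 controls; annotated junction counts negative-binomial with mean
100 and dispersion 0.1 (the standard overdispersed count model; no noise
model is established for this setting) scaled by a lognormal (σ = 0.15)
per-sample library factor; background noise junctions at Poisson(3) per
sample with support at 1 % of depth; injected junction events at a stated
fraction of flanking coverage.  The NMD mask multiplies event support by
0.1 and simulated CHX multiplies it back by 10 — chosen so masked events
fail the read-support/normalized-value filters untreated and pass them
treated — while also multiplying the noise rate by 5, emulating the
genome-wide increase in aberrant junctions under translation inhibition
that makes unguided CHX analysis impractical.  Isoform-shift events move
TPM mass between isoforms holding the gene total constant (the
redistribution signature); knockdowns scale gene totals.  Realignment
reads are drawn from a targeted window around the event locus so that
event-spanning coverage is guaranteed at desk-scale depth (40 reads/sample,
100 nt, 1 % substitution error), emulating candidate-gene-directed
analysis rather than whole-transcriptome shotgun coverage.

Not emulated: human transcriptome scale, sequence-content biases (GC,
hexamer priming), paired-end fragment-length structure, alignment
ambiguity from gene families, or fusion transcripts.  Passing recovery
tests therefore demonstrates the *logic* of the detectors under controlled
signal and overdispersed noise, not their operating characteristics on
real libraries.

All generators are deterministic functions of an explicit mandatory seed;
identical seed and configuration reproduce byte-identical fixture files.

## Problem sizes

The test and acceptance suites run at desk scale by design: 200 random
50-junction × 8-sample matrices for oracle equivalence, 100 seeds for
junction-event recovery and CHX unmasking, 50 seeds each for TID recovery
and realignment end-to-end (two deletion scenarios, 11 samples × 40 reads),
1000-event nulls for FDR calibration and 500 draws for signature-null
uniformity.

## Known limitations

* The junction normalization denominator is per-end, not per-gene; an
  alternative reading (normalizing against the gene's strongest junction
  anywhere) would lower normalized values for events far from the gene's
  expression maximum.
* Event enumeration covers cassette exons between annotated isoform pairs;
  alternative 5'/3' splice sites, retained introns and mutually exclusive
  exons are represented in the event model but not enumerated from
  annotation.
* The realignment caller targets indels ≥ 3 nt with ≥ 3 supporting reads
  and consolidates within 60 nt; it is not a general-purpose variant
  caller and does not model base qualities.
* The expression stage corrects for no covariates; on real cohorts a
  confounder-aware caller should replace it.
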