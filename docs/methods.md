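# Methods

This note documents the models, parameter choices, numerical details and
limitations behind each stage of the pipeline, and what the synthetic
benchmark does and does not demonstrate.

## Read model and cleaning

Reads are 50 bp single-end: insert + 3' adapter + padding, truncated to
the read length, Phred+33 qualities. Cleaning is whole-read (no
base-level quality trimming): a read is rejected, in this order, when it
has more than one N base; more than one base under Phred 20; a 5'-adapter
prefix at its start (the last 8 nt of the 5' adapter — the part that
would be ligated closest to the insert); no 8 nt prefix of the 3'
adapter anywhere (leftmost match trims); an empty insert (adapter
dimer); a poly(A) insert (≥90% A — the threshold is a package choice
that avoids rejecting genuinely A-rich miRNAs); or an insert outside
16–35 nt. The 35 nt upper bound reflects the size selection implied by a
small-RNA gel cut on adapter-ligated product; the rejection-reason
vocabulary includes `too-long` for it. The order matters only for
bookkeeping — every rejected read genuinely fails the rule named by its
reason, and raw = clean + Σ rejections holds exactly per library.

Reads with identical (sequence, quality) pairs are filtered once and
their counts pooled; this makes cleaning invariant to read order and an
order of magnitude faster, and is exact because the rules depend only on
the pair.

## Annotation hierarchy and tolerant matching

Each unique tag receives exactly one category:
ncRNA > known miRNA (including edited) > repeat > exon >
novel-miRNA candidate > intron > unannotated.

*Known*: the tag must equal a precursor substring whose ends lie within
±2 nt of an annotated mature arm's ends (templated isomiR convention;
"extend or shorten by 2 bp" is read per end, not as a total-length
change). Ties break by smaller |5' offset| + |3' offset|, then
lexicographic mature id. *Edited*: the same window with exactly one
internal mismatch, reported in mature coordinates; tie-break adds the
position as a third key. Edited tags are counted under their known miRNA
for quantification and logged separately. *Homolog*: foreign mature arms
carry no precursor context, so the tag aligns end-anchored against the
bare mature with ≤2 mismatches over the overlap and ±2 nt end offsets;
overhanging tag bases are unconstrained. Identical foreign sequences
across species collapse to one entity named without the species prefix.
A 7-mer index prefilters homolog candidates; the per-candidate check is
exhaustive, so the result equals brute-force enumeration (tested).

Genome mapping is exact and full-length on both strands, implemented as
one pass per chromosome over a 16-mer seed table of all queries — the
result equals a naive scan (tested). Multi-mapping tags contribute their
count once to their single assigned category.

Tags mapping outside repeats/exons are provisional novel candidates;
after novel calling, uncalled candidates demote to intron (if an intron
locus exists) or unannotated. The paper-order hierarchy places novel
above intron deliberately: intronic hairpins (mirtron-like loci) should
reach the detector.

## Quantification

RPM uses genome-mapped clean reads per library as the denominator (the
alternative, miRNA-mapped reads, is less stable when homolog and ncRNA
content varies between libraries); the denominator is recorded with the
matrix. The overall average is the unweighted mean over the eight
libraries, which under equal replication equals the mean of stage means
— this identity is what the published worked-example table reproduces.
Retention requires overall average > 1 RPM; tiers are <100 (low),
[100, 1000) (moderate), ≥1000 (high), with both boundaries inclusive on
the upper side as stated. Percent-of-total is computed over retained
known miRNAs only (homologs and novels excluded).

Cluster detection chains same-chromosome miRNA genes (overall average
above 100 RPM) with inter-gene gaps ≤ window (default 100 kb, minimum
size 3). It is order- and translation-invariant. Heatmap ordering uses
average-linkage agglomerative clustering on correlation distance of
per-stage RPM rows; rows are pre-sorted by id so ties resolve
deterministically, and NaN distances from zero-variance rows are treated
as maximal.

## Novel-miRNA calling

The detector is a simplified consensus design, not a port of any
published tool: two independent detectors must agree, preserving the
semantics of the usual thresholds (score ≥ 5; MFE < −18 kcal/mol;
structure-randomization p < 0.05).

Folding uses a stacking-only nearest-neighbor-lite model: a stack of two
adjacent pairs contributes the mean of the two pair energies (GC −3.0,
AU −2.0, GU −1.0 kcal/mol); hairpin closure +3.0 (loop ≥3), interior
loop/bulge +2.0 (≤30 unpaired total — a model constraint, matched by the
enumeration oracle), multiloop +3.0. Isolated pairs contribute nothing,
so MFE ≤ 0 always. The solver is an exact dynamic program with
deterministic traceback, numba-compiled; for sequences ≤22 nt it equals
exhaustive enumeration of nested structures scored by the same energy
function (tested). A 20-bp GC stem with a 4 nt loop scores
−3.0 × 19 + 3.0 in closed form.

Candidates are excised per strand around read clusters (merge gap 30 nt)
with ≥5 total reads — an expression-evidence floor that keeps singleton
degradation fragments out — as two windows (block extended 70 nt
upstream / downstream, capped at 110 nt, truncated at contig ends).
Detector A scores 2.5·(fraction of reads consistent with the dominant
arm ±2 nt) + 1.5·(star-arm read support) + 1.5·(MFE < −18) +
1.5·(≥14 mature bases paired into one stem arm), passes at ≥5, and
additionally requires the dinucleotide-shuffle p (Altschul–Erickson
shuffles preserving dinucleotide counts; default 100 shuffles) below
0.05. Detector B requires MFE < −18, the mature arm on one stem arm,
5'-end spread of consistent reads ≤4 nt, and precursor length 60–110 nt.
Calls are the intersection; the intersection key is exact mature
sequence, so the same mature excised from two genomic copies collapses
to one call with both precursor records. Names are assigned by
descending total raw count.

## Differential expression

Upper-quartile factors are the 75th percentile of nonzero counts per
library, rescaled to geometric mean 1; effective size = mapped-read
denominator × factor. Counts are quantile-scaled to the geometric-mean
effective size and rounded half away from zero, making the conditional
exact test's equal-size assumption hold by construction.

The common NB dispersion maximizes the conditional log-likelihood of
replicate counts given per-group totals (free of the mean), bounded to
φ ∈ [0, 5], optimized on the log scale to 1e−6 and snapped to the
Poisson boundary when the optimum is numerically zero. The exact test
conditions on the pooled total and sums the probabilities of all splits
as likely or less likely than observed (with a 1e−12 relative guard on
the equality comparison); φ = 0 uses the binomial conditional law
directly. Fold changes use pseudo-count 0.5 on scaled counts. Calls
need |log₂FC| ≥ 1 and BH FDR ≤ 0.05 within each comparison;
log₂FC > 0 means higher in the later stage.

## Temporal profiles

Candidate profiles start at 0 with per-transition changes in
[−c, c] (c = 1, T = 4 → 27 profiles ≤ the 30-profile budget; a larger
space reduces to the budget by greedy max-min Euclidean distance seeded
from the flat profile). Trajectories are stage means of log₂(RPM+1) —
the +1 offset is the package's zero-handling choice. Assignment
maximizes Pearson r (ties to the lower profile id; flat trajectories go
to the flat profile). Expected per-profile counts average over all
T! = 24 stage-order permutations; significance is the upper-tail
binomial probability of the observed count at rate expected/n,
Bonferroni-corrected over profiles (the conservative default of the
cited algorithm family, rather than BH). Only DE miRNAs enter
profiling. Null calibration over 200 replicates of i.i.d. trajectories
keeps the family-wise error at or below 0.05 plus simulation margin
(tested).

## Targets and enrichment

The three predictors are archetypes of the usual tool trio, not ports:
(1) canonical seed classes — 8mer, 7mer-m8, 7mer-A1 from
reverse-complement matches to positions 2–8, with the 7mer-A1 nested
inside an 8mer suppressed so a site is reported once; (2) local
alignment of the reversed miRNA against a ±30 nt window around each
seed site (+5 complement, +1 G:U, −3 mismatch, −8/−2 affine gaps, seed
positions 2–8 weighted ×2; threshold 140 — a perfect 22-mer complement
scores 145); (3) intermolecular duplex energy under the same stacking
model (threshold −15 kcal/mol; equals exhaustive chain enumeration for
short sequences, tested). The gene-level intersection of the three is
the decision rule preserved exactly. Filtering keeps pairs where the
miRNA is DE in the comparison with overall average >100 RPM and the
mRNA fold change is nonzero with the opposite sign (sign-only rule; a
magnitude threshold is exposed in config but defaults off, since the
source convention states none). Enrichment is upper-tail hypergeometric
(EASE variant decrements the overlap by one) against user-supplied gene
sets, background = genes with supplied UTRs (the universe actually
scanned), BH FDR across sets.

## What the synthetic generator emulates — and what it does not

The generator plants: stage-structured abundances (lognormal bases;
balanced 4-fold step-change pairs so planted DE does not distort null
proportions; a 50-member cluster on one chromosome inside a 1 Mb window
with rising/falling programs at adjacent-stage ratio 3); templated
isomiR end shifts (5': 85% unshifted; 3': 50% unshifted, biased toward
+1); single-base edit events at rate 0.15 on five miRNAs; foreign
donors at 1–2 substitutions plus 3'-extension variants (only 2-sub and
extension donors source reads, keeping homolog truth unambiguous);
perfect-stem novel hairpins (28 bp stem, 8 nt loop, 90% mature / 10%
star reads); scattered intergenic degradation as decoy loci; and
separable contaminant classes (adapter dimers 4%, ncRNA fragments 8%,
low-quality 2%, poly(A) 1.5%, N-reads 0.5%, 5'-adapter 1%, miRNA 70%).
Contaminant ncRNA sequences are generated independently of the genome —
they are filtered before genome annotation, and the genome-mapped
fraction (~0.8 of raw reads) emerges from the class split.

Not emulated: sequencing error beyond planted substitutions,
quality-by-cycle profiles, PCR duplication, non-templated 3' additions
outside the explicit homolog variants, partial adapter degradation, and
real genomic repeat structure. Passing the benchmark therefore
demonstrates that the algorithms recover planted truths under clean
multinomial sampling; it does not certify performance on real libraries
with correlated errors and richer isomiR chemistry. Quality strings are
constant per library (Phred 35–40 pattern) with planted low-quality
reads carrying three sub-20 bases, so the quality rule fires
unambiguously.

Randomness: one master seed; per-library seeds derive deterministically
from (seed, library index); identical (config, seed) gives byte-identical
outputs.

## Problem sizes

The standard benchmark is 8 libraries × 200,000 reads, ~300 own-species
mature miRNAs (50 clustered), 38 read-sourced homolog entities, 10
novel hairpins, 25 decoy loci, on a 3.6 Mb toy genome; the test suite's
fast fixture scales this to 40 miRNAs × 5,000 reads. Oracle-equivalence
checks run at the sizes where enumeration is exact and affordable:
500 random tags for the matchers, pooled totals ≤50 for the exact test,
sequences ≤22 nt for folding, ≤10 nt per strand for duplexes.

## Known limitations

* The homolog class intentionally mixes true cross-species homologs
  with 3'-modified known miRNAs — the two are not distinguishable from
  sequence alone; both labels are reported.
* The energy model is not Turner-parameter folding; MFE values are
  comparable within this package (and calibrated so the −18 kcal/mol
  threshold separates planted hairpins from shuffled/decoy sequences),
  not against laboratory folding tools.
* The exact test scales counts to a common library size by rounding,
  which slightly discretizes p-values at very low counts.
* Enrichment results depend entirely on user-supplied gene sets; no
  ontology content ships with the package.
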