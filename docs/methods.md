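# Methods

This note documents the models, conventions and design choices behind
`altprom`, and what the synthetic validation does and does not establish.

## Quantification model

Junction identity is the exact 4-tuple (chromosome, intron start, intron
end, strand) in 0-based half-open coordinates; on-disk tables use the
1-based inclusive STAR convention and are converted at the I/O boundary.
Only uniquely mapped junction reads are counted — multimappers are kept in
the records for round-tripping but excluded from the count matrix, the
conventional choice for junction-support measures. Junctions with
undefined strand (STAR code 0) are retained at read time and simply fail
annotation lookup later, keeping I/O lossless.

Filtering happens in two stages with ≥ semantics (a junction exactly at
the threshold is kept):

1. dataset-level, genome-wide: drop mitochondrial contigs (`chrM`, `MT`),
   non-canonical intron motifs, and junctions with < 6 reads summed over
   all samples of the dataset;
2. within the gene of interest only: drop junctions with < 4 reads
   dataset-wide.

The per-sample normalization denominator is the genome-wide spliced-read
total **after stage 1 and before stage 2**. The ordering must be pinned
for the quantity to be well defined; taking the denominator before the
within-gene floor means a handful of weak in-gene junctions do not perturb
the library-size estimate. The alternative (denominator after stage 2) is
available by passing explicit totals to `normalize_jpm`.

Extended first exons (transcription reading directly into an internal
exon) are quantified by counting reads with an aligned block that fully
covers a 2-bp window immediately transcript-5' of the internal exon. Two
conventions matter here. First, "5' of the exon" is resolved in transcript
orientation: for a minus-strand gene the window is the two bases at
genomically larger coordinates abutting the exon's genomic end. Second,
"crossing" requires *one* block to cover *both* bases: a spliced read whose
intron gap spans the window is evidence of splicing into the exon, not of
reading through into it, and partial overlap of a single base is not
read-through either. Window counts are normalized with the same per-sample
denominator as junctions and enter the event matrix as additional rows;
since the annotation maps junctions (not windows), window events carry
their isoform label through a small side table (`window_events`).

Aggregation is plain summation of normalized values by event label, then
by isoform label; events labelled `none` (internal-exon junctions that do
not identify an isoform) are excluded from isoform-level aggregation.

## Differential statistics

Within each experiment, control vs disease is compared per event with a
two-sided Mann–Whitney U test. The exact permutation null is used whenever
the smaller group has ≤ 8 observations and there are no ties — which covers
the 6–9-per-group designs this package targets — otherwise the normal
approximation with tie and continuity corrections. p-values are BH-adjusted
within a *test family*, the set of rows displayed/tested together (default:
one family per aggregation level).

The combined two-experiment test fits, per event, a Gamma GLM

    y + 0.01 ~ Experiment + Disease + Experiment:Disease

on the normalized values, with treatment coding and alphabetically first
levels as references. The +0.01 shift keeps zero values inside the Gamma
support; it is applied immediately before GLM fitting only, never to the
Mann–Whitney tier. Choices that the model statement leaves open:

- **Link.** The inverse (canonical) link is the default, matching the
  conventional Gamma GLM default in the major statistical environments;
  a log link is selectable. With the full interaction the design is
  cell-saturated, so fitted means equal cell means and stay positive under
  either link. Note that under the inverse link a *positive* disease
  coefficient means a *lower* disease mean.
- **Tested effect.** The Wald test targets the Disease main effect — under
  treatment coding, the disease contrast at the reference experiment. A
  joint F-type Wald test of Disease plus all Disease interactions is
  available (`joint=True`); unlike the main-effect test it is invariant to
  which experiment serves as reference.
- **Reference distribution.** Wald p-values use Student's t with the
  model's residual degrees of freedom and the Pearson-estimated
  dispersion, the standard finite-sample convention for Gamma GLM
  summaries. At n ≈ 29 with 4 parameters this is noticeably better
  calibrated than a normal reference.

Non-convergence is reported as a flagged result with NaN p (excluded from
BH across the family), never a crash; degenerate designs (an empty
experiment × disease cell) raise instead. Effect *direction* is read from
pooled group medians (disease > control → `up`), independent of the GLM
parameterization.

## TSS geometry

A promoter is *dispersed* when its TSS spread (max − min position) reaches
the threshold (default 100 bp, the conventional dispersed-promoter scale)
**and** there are ≥ 3 distinct starts; two isolated starts do not
constitute a spread initiation region. The repeat-in-UTR question uses a
strict boundary convention: a TSS exactly at the repeat's transcript-
upstream edge does not place the repeat in the UTR. Both conventions are
deterministic tie-breaks for criteria that the literature states only
qualitatively.

## Reporter statistics

Firefly signals are normalized to co-transfected Renilla, then to the
11-repeat construct's ratio within the same promoter and independent
experiment, so analyses run on dimensionless relative activities with the
reference pinned at exactly 1. The independent experiments are the
repeated-measures subjects (the only replication unit in this design;
well-level replicates, if present, are averaged by the pivot step).

The RM-ANOVA uses textbook sums of squares; Greenhouse–Geisser ε comes
from the double-centred sample covariance of the conditions,
ε = tr(S̃)² / ((k−1) tr(S̃²)), clipped to [1/(k−1), 1] and exactly 1 for
k = 2. Dunnett's two-sided comparisons against the reference use the
RM-ANOVA error mean square on (n−1)(k−1) df; adjusted p-values come from
the equicorrelated multivariate-t distribution (ρ = 1/2, exact for the
equal per-condition n of a complete table), evaluated by deterministic
Gauss–Hermite × Gauss–Legendre quadrature (64 × 96 nodes, ≈ 1e-6 absolute
accuracy in the central range; cross-checked against Monte Carlo). With a
single comparison no adjustment is applied, so the result equals the
paired t-test.

## Synthetic data

`simulate_dataset` emulates the two-cohort corneal study design: 6 + 8 and
9 + 6 control/disease samples in two experiments. Per sample, each
annotated junction of the demo gene model draws a negative-binomial count
(Gamma–Poisson; size parameter 10 by default, a typical bulk RNA-seq
overdispersion) with mean = baseline × disease fold × library factor.
Baselines are order-of-magnitude placeholders (30–400 reads at a 1e6
library) chosen so that shared internal-exon junctions outnumber any
single first-exon junction; the default disease profile plants 0.3× on the
repeat-proximal events, 3× on the distal ones, and 1× on three unchanged
events. Library sizes are uniform on [0.8e6, 1.2e6] spliced reads; a
filler junction tops each written file to the drawn total exactly, and the
background set deliberately includes mitochondrial, non-canonical and
low-support junctions so every filter branch is exercised by the fixtures
themselves. Seeding is order-independent: each sample's stream derives
from (master seed, CRC32 of the sample id).

The demo gene model has the real locus's architecture (reverse strand,
internal exons 3–21, repeat tract between exons 3 and 4, first exons
3b/3c/3d, 4aI/4aIII/4b/4c, 8a/8bII/8cII, 10a, within the hg19 footprint)
but **synthetic coordinates** — round numbers, not curated positions. The
"10-16" event stands in for the downstream internal-exon chain as a single
junction.

What the simulator does *not* emulate: real junction coordinates and their
curation ambiguities, correlation between events sharing transcripts,
GC/length biases, batch structure beyond an experiment intercept,
multimapper ambiguity, and library sizes of real depth (tens of millions).
Passing recovery tests therefore demonstrates the pipeline's correctness
and calibration under its own generative assumptions, not performance on
real corneal data.

`simulate_reporter` mirrors the luciferase design: two promoters, six
repeat lengths (11…144), three independent experiments, relative activity
falling with repeat length to 0.30 (p4a) / 0.25 (p4abc) at 144 repeats,
with 10% CV log-normal noise on the firefly/Renilla ratio (Renilla noise
cancels by construction, so zero CV recovers the configured activities
exactly).

## Validation sizes and numerical choices

The test suite and `scripts/acceptance.py` validate at these problem
sizes, chosen to give tight Monte-Carlo error at interactive runtimes:
null calibration over 200 (tests) / 100 (script) simulated studies; effect
recovery over 50 / 40 seeds; GLM coefficient bias at 50 observations per
design cell over 500 / 300 replicates (observed relative bias ≈ 0.3%);
reporter recovery over 200 / 150 seeds; Mann–Whitney enumeration for all
66 group-size pairs with n₁+n₂ ≤ 12; BH step-up on 1,000 random vectors.
Observed calibration: family-wise BH under the global null rejects at
≪ 0.05 in both tiers (BH controls the family-wise error under a full
null), planted-direction recovery and strong-effect power are 1.0, and the
flat-event false-call rate is ≈ 0.08 against the effective per-family
threshold.

Other numerical conventions: filtering ties kept (≥); BH q-values capped
at 1; constant-response GLM short-circuits to (coef 0, p 1); F = 0 (p = 1)
for a zero between-condition sum of squares and p = 0 for a zero error
term with nonzero effect; ε set to 1 when the centred covariance vanishes.

## Known limitations

- The annotation maps one junction to one event; shared-junction events
  (one junction feeding two transcript groups) are not representable.
- The Gamma GLM treats samples as independent; no mixed effects,
  permutation alternatives or effect-size shrinkage.
- The main-effect Wald test depends on the reference experiment by
  construction; use `joint=True` for a reference-free disease test.
- BAM ingestion is out of scope: the pipeline consumes junction tables and
  block TSV/BED-style read geometry.
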