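# Methods

`cfnipt` analyses low-pass, single-end (40 bp) cfDNA sequencing of maternal
plasma — the data produced by routine non-invasive prenatal testing (NIPT).
Plasma cfDNA is a mixture of maternal and feto-placental DNA; the
feto-placental share (the fetal fraction, FF, typically 5–20%) scales every
fetal-derived coverage feature linearly.  The package exploits that linearity
five ways: it discovers fetal-specific regions, estimates FF from them,
screens aneuploidy calls for confined placental mosaicism (CPM), infers fetal
open-chromatin candidates, and scores samples for phenotype-associated
coverage shifts.  Because clinical NIPT data cannot be redistributed, a
synthetic cohort generator reproduces the statistical structure those methods
assume, and every performance claim in the test suite is made against data
from that generator.

## The synthetic genome and cohort generator

The generator draws each read's start position from the mixture
`(1-ff)·maternal + ff·fetal` of two piecewise-constant per-base weight
profiles over a 11.5 Mb toy genome: five autosome-like chromosomes (chr1 4 Mb,
chr2 2.5 Mb, chr3 2 Mb, chr4 1.5 Mb, chr5 1 Mb) plus a 0.5 Mb chrY.  Reads
are fixed-width 40 bp; defaults use 200,000 reads per sample (the clinical
assay's 4.2 million, scaled so whole-suite runtimes stay in minutes) and FF
uniform on [0.05, 0.20].

Planted structure, all chosen once as the study conditions:

* **Fetal-specific loci.** Eight autosomal loci (150–300 bp, chr2–chr4)
  plus two 200 bp chrY anchors carry sampling weight only in the fetal
  profile (4% + 1% of fetal mass); the maternal profile is zero there.
  Their coverage is therefore proportional to FF with zero intercept.  Each
  locus's 50 bp upstream flank carries the consensus `AGCGGAACGGAACG`
  (a CGGAA tandem repeat) planted at flank offsets 6–19 over random
  background; sequence is stored only in those flank blocks.
* **chrY.** Maternal weight on chrY is zero; the male fetal profile puts 5%
  of its mass there, so the chrY read share equals `0.05·ff` and inverts
  into the conventional chrY-dosage FF estimate.  Female fetal profiles have
  chrY zeroed and are renormalised.
* **NDR dips.** Ten "fetal-expressed" genes carry a 150 bp
  nucleosome-depleted window upstream of the TSS where the fetal weight is
  attenuated by the dip depth (default 0.8).  Mixture coverage there is
  `∝ 1 - 0.8·ff`: the dip deepens linearly in FF by construction.
* **Aneuploidy.** A trisomy with mosaic fraction `m` multiplies the fetal
  weight on the target chromosome by `1 + m/2` (full trisomy `m=1`; CPM
  `0<m<1` dilutes the dosage shift proportionally).  chr1 carries no other
  planted features and is the default dosage target; its ~0.4 background
  share gives 2×10⁵-read samples roughly the same dosage-counting precision
  (n·p ≈ 8×10⁴ target reads) that the clinical assay has on chr21 at
  4.2×10⁶ reads — the counting statistics, not the genome proportions, are
  what the screen depends on.
* **Phenotype panel.** Twenty genes on chr5 carry 500 bp TSS-centred
  windows whose mixture weight is multiplied by `1±0.5` in case samples
  (10 up, 10 down).  The effect size is a stated default — the magnitude of
  real disease-associated coverage shifts is not known — chosen as the
  smallest mechanism that produces clearly separable case profiles.

All randomness flows from one `numpy.random.Generator`.  A merged library of
iid samples sharing one FF can be drawn as a single multinomial
(`simulate_merged_depth`), which is distributionally identical to pooling
per-sample simulations.

What the generator does **not** emulate: GC and mappability bias, fragment
length variation (the ~166 bp nucleosome ladder), sequencing error, maternal
CNVs, or inter-individual profile variability.  Passing tests therefore show
that the algorithms recover the signals they model at realistic counting
noise — not that they are robust to every artefact of real libraries.

## Fetal-specific region discovery

Samples are sorted by FF (chrY estimate when available, else the known
synthetic FF) and split into equal-size strata (40 at full scale); each
stratum's fragments are pooled into one merged depth track.  Per base,
normalised depth (counts per million of library total) is regressed on the
group mean FF by ordinary least squares.  A base qualifies when

1. the fit is evaluable (all fitted values positive, not all-zero depth);
2. the relative fitted error is below `max_rel_error` — by default the
   *maximum* over groups of `|obs-fit|/fit` with threshold 0.015, the rule
   appropriate for clinical-scale merged libraries of hundreds of millions
   of reads.  A
   *mean*-residual mode exists because the error functional is a design
   choice; at desk-scale depth (planted-locus coverage ~50–200 per group,
   i.e. Poisson relative noise 7–14% against a background of ~40%) the
   suite uses `error_mode="mean"` with threshold 0.20, the midpoint
   separating those two regimes on a log scale, derived from the Poisson
   arithmetic rather than fitted to any test outcome;
3. raw merged depth is at least `min_reads` (2) in every group;
4. the slope is positive — constant tracks satisfy any residual test
   trivially but are not fetal-derived.

Qualifying bases merge into maximal runs.  When depth was accumulated in
coverage mode, each run's right edge is trimmed by `read_length - 1` bases:
starts in `[s, e)` cover `[s, e+L-1)`, and the trim inverts that footprint so
called boundaries live in read-start coordinates.  On noiseless expected
tracks this makes recovery base-exact wherever every base clears the
`min_reads` rule; the chrY anchors lose exactly their two boundary bases,
whose expected coverage (~1.4 reads at the lowest-FF group) genuinely falls
below 2 — the filter working as specified, not an artefact.

The 50 bp upstream flanks of called regions are stacked into a 4×50 position
weight matrix (rows A, C, G, T, columns normalised); a maximal-exact-repeat
scan of the consensus reports tandem units (≥3 bp, ≥2 copies), which on
fetal-specific flanks shows the planted CGGAA repeat.  Flanks without
reference sequence are skipped with a warning.  Only the upstream flank is
summarised by default; downstream is a config option.

## Fetal fraction estimation

*chrY dosage:* `ff = (f_Y - b_female) / (b_male - b_female)` clamped to
[0, 1], with the calibration shares measured from the generator's own
profiles (`b_female = 0`, `b_male = 0.05` by construction), not hard-coded
human values.

*Region model:* `ff = β₀ + Σ βᵢ yᵢ`, where `yᵢ` counts fragments *starting*
inside region *i* (the start rule assigns each fragment to at most one
region).  Counts are normalised to counts-per-million by default — the model
equation uses raw counts, but libraries differ in depth and raw sums would
confound library size; a `raw` mode preserves the literal equation.  Fitting
is delete-d jackknife: 1,000 iterations each exclude a random 5% of training
samples and solve OLS (minimum-norm and flagged if rank-deficient); final
coefficients are element-wise medians across iterations.  `iterations=1,
holdout=0` reduces exactly to OLS, which the tests assert to machine
precision.  Validation reports Pearson r on unclamped predictions, RMSE and
bias.

## Mosaicism screen

For an aneuploidy-positive sample, the dosage ratio of the target chromosome
to a clean euploid background region set (background autosomes excluding the
target, the planted loci and chrY) is compared with its euploid expectation:
`AneuFC = 2·(f_obs/f_exp - 1) / dosage_response`, clamped to [0, 1].  The
ratio form (rather than a share of total reads) makes the euploid expectation
FF-invariant whenever both mixture components are uniform over the
background, which removes a variance term that has nothing to do with
mosaicism.  `dosage_response` (≈0.92 for the packaged genome, measured from
its profiles like the chrY calibration) accounts for the fetal mass diverted
to chrY and the fetal-specific loci; at 1 the formula is the idealised
textbook case.

The combined Z-score standardises `D = FF_best - AneuFC` (FF_best = chrY
estimate when defined, else the region model) against a reference of
concordant positives — full trisomies, for which `D ≈ 0` regardless of FF.
CPM dilutes AneuFC to `≈ m·ff`, so `D ≈ ff(1-m)` and the sample stands out.
The cutoff defaults to 3 (configurable; the reference-based choice of cutoff
is deliberately left to the user, and a reference of ≥60 samples is used in
the packaged analyses so the estimated standard deviation is stable).  A
`joint` mode combines the chrY- and region-based discrepancies as an RMS of
their separate standardisations.  Flags are advisory annotations and never
demote a positive screening call.

## Open chromatin inference

Four merged tiers at mean FF 5/10/15/20% are normalised by total reads; a
base is a candidate when its normalised depth is *strictly* monotone across
all four tiers, with the direction recorded.  The filter is deliberately
magnitude-blind, so in expectation it also passes background drift; noise
thins it to ~8% of positions (2/24 orderings plus drift), and the run
structure does the discrimination.  Candidates (down-with-FF for open
chromatin) are extended by 12 bp flanks into 25 bp windows; windows that
overlap or abut chain into runs; runs of ≥5 windows are kept.  An optional
`restrict_to` argument intersects candidates with previously called
fetal-specific regions before chaining — in the packaged synthetic genome the
fetal-specific loci (coverage rising with FF) and NDR dips (falling) are
disjoint by construction, so the synthetic analyses run without the
intersection; on data where fetal-specific regions are broad enough to host
promoters it belongs in the pipeline.  Packaged tier analyses pool 1,000
samples per tier (2×10⁸ reads, ~1/100 of the clinical tier depth), the size
at which the planted dips are recovered reliably.

A two-library differential coverage test (the exact two-sample analogue of an
RNA-seq count test: the high-tier count against a binomial conditional on the
pooled count with success probability given by the library totals; two-sided
by doubling the smaller tail; Benjamini–Hochberg adjusted) attaches
significance to candidates; genes whose TSS lies downstream of a run on the
gene's own strand within 10 kb (a stated default — no distance is prescribed
by the underlying analyses) are collected; enrichment of the gene list
against user-supplied term sets uses the hypergeometric upper tail with the
Overlap% denominator counting input genes mapped to at least one term.  The
enrichment replaces an external annotation web service, whose p-values depend
on its private background and are not reproduced — only the Overlap%
arithmetic is exact.

## Phenotype scoring

A binary case/control contrast over TSS-centred windows (same conditional
binomial + BH machinery, α = 0.05) yields a panel of up- and down-loci.  The
signed sum `S = Σ_up cpm - Σ_down cpm` uses counts-per-million within sample;
raw counts would confound library size with phenotype.  `S` is standardised
against a reference built blindly from the whole cohort (cases included, as a
screening laboratory would; a labelled-controls mode exists, and because
standardisation is monotone the two modes give identical rankings — asserted
in the tests).  The reported score is `max(0, z + 4)`; samples above the
cohort's empirical 99% quantile (order-statistic quantile with linear
interpolation, the numpy default; the convention is configurable because
tie-handling changes the exceedance count) are called, with strict
inequality, so a degenerate all-equal cohort calls nobody.  PPV is evaluated
among called samples with known outcomes; lost-to-follow-up samples leave the
denominator.

Viewing-area profile plots rescale each track to unit mean inside the
viewport before smoothing with a centered running mean (window 50 bp,
truncated at the edges), which removes baseline differences between
libraries of different depth.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open throughout.  Division-by-zero guards:
non-evaluable regression positions are flagged rather than dropped silently;
positions with zero counts in both libraries are dropped from differential
tests with a count recorded; zero-spread references and degenerate chrY
calibrations raise.  Jackknife and cohort generation are exactly
reproducible from their seeds; pipeline reruns with the same configuration
are byte-identical and the manifest records the configuration hash.  Merged
depth tracks are int32 (counts at desk scale stay far below 2³¹) and
per-base regressions run in 250k-position chunks to bound memory.

## Problem sizes used by the packaged analyses

Region recovery: 40 groups × 5 samples × 2×10⁵ reads, three seeds.
FF model: 500 training / 200 validation samples, 1,000 jackknife iterations.
Mosaicism: 60-trisomy reference, 100 replicate pairs.  Open chromatin: four
tiers of 1,000 pooled samples.  Phenotype: 2,000 samples with 1% planted
cases.  These sizes are the package's desk-scale defaults; full-scale clinical
use means thousands of samples per stratum at 4.2 million reads each, and all
thresholds that depend on depth (notably the fitted-error rule) are exposed
as parameters for that regime.

## Known limitations

* Synthetic-only validation: no real cfDNA is shipped or fitted.
* The per-base regression assumes homoscedastic residuals on the normalised
  scale; at very low depth the relative-error rule is noise-dominated and
  must be re-tuned with depth.
* The combined Z-score's functional form (standardised best-estimate minus
  AneuFC discrepancy) is one reasonable realisation of "deviations from
  expected fetal fraction"; alternatives (joint mode) are provided but none
  is clinically validated, and flags are advisory only.
* The monotone filter is magnitude-blind by design and needs the run-length
  and (optionally) region-intersection steps to be specific.
* Enrichment p-values depend entirely on the user-supplied annotation and
  background size.
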