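# Methods

## The data model

All computation runs on a samples × analytes matrix of strictly positive
relative fluorescence units (RFU) with a per-sample annotation table
(case/control status, collection site, draw type, subject, plate, stage,
histology, assay version). Missing values are illegal: affinity-proteomic
pipelines report a value for every well, and imputation would silently
change every downstream statistic, so loading fails fast instead. All
distributional statistics (KS distances, t tests, PCA, forest features) are
computed on log2(RFU); intensities are approximately log-normal and the
additive log scale stabilises variance. Interchange is plain TSV with
values written at 6 significant digits; write∘read is the identity at that
precision.

## Preprocessing

Two multiplicative corrections:

* **Plate calibration.** Each plate carries reference calibrator wells
  (eight by default). The factor for (plate p, analyte a) is
  g_pa = ref_a / median(calibrator values of a on p), with ref the
  per-analyte median of calibrator wells pooled over plates when not
  supplied. Only *relative* plate factors are identifiable — the common
  level is absorbed into the reference — which the parameter-recovery tests
  reflect by comparing median-centred factors.
* **Median normalization.** Per-sample factor
  f_s = median_a(ref_a / x_sa) — the median of ratios rather than the ratio
  of medians, because it is invariant under per-analyte reweighting. After
  scaling, the per-sample median ratio to the reference is exactly 1.

Order is calibrate → normalize (a config switch): calibrating first keeps
plate bias out of the study-internal normalization reference. Each
transform is idempotent when re-applied with the reference it returned;
with a self-derived reference the second pass recomputes the reference, so
exact idempotence is only guaranteed for calibration (whose calibrator
medians all equal the target after one pass). Dilution-bin-specific scaling
and hybridization controls are out of scope — the pipeline treats the assay
as a single dilution group, an explicit simplification.

## Preanalytic QC

The QC stage never sees the case/control contrast it is protecting: it uses
only technical covariates (control site, draw type, plate).

* **PCA artifact screen** (first, by default). Principal components of the
  log2, analyte-standardised matrix that explain ≥ 1% of variance are
  tested for association with technical covariates by the correlation ratio
  η; components with η > 0.5 are flagged. Samples more than 3 robust MADs
  from the median score on a flagged component are flagged for removal;
  analytes in the top decile of |loading| are flagged advisorily. η is
  computed on control samples only: technical covariates can be confounded
  with disease (intra-op draws, case-enriched sites), and judging the
  association on controls makes it impossible to flag a component for the
  disease signal it carries. Running the screen first means an
  artifact-laden subcohort (e.g. degraded archived samples, which acquire a
  global offset through their normalization factors) is removed before the
  distributional filters, so it cannot inflate inter-site distances on
  otherwise clean analytes. Analyte loading flags are advisory rather than
  applied by default because a strong multi-direction artifact spreads over
  several components and their top-decile loadings collectively sweep in
  far more analytes than are actually damaged — once the driving samples
  are removed, the KS filter adjudicates the analytes on clean evidence.
  Both choices are config switches.
* **Inter-site KS filter.** For every analyte, the two-sample
  Kolmogorov–Smirnov distance D (sup-norm between empirical CDFs, computed
  exactly by ECDF evaluation at all pooled points) is taken over every pair
  of control sites with ≥ 5 samples; the analyte is excluded iff the
  maximum pairwise D is strictly greater than 0.45. Max-over-pairs is one
  of several possible aggregations across > 2 sites; it is the most
  conservative (any one deviant site suffices) and is configurable.
* **Paired-draw filter.** From subjects sampled both pre-operatively and
  intra-operatively, per-analyte paired log2 ratios are tested by Wilcoxon
  signed-rank; an analyte is excluded iff p < 0.05 *and* the absolute
  median ratio is ≥ 0.5 log2 units. The conjunction keeps consistently but
  trivially shifted analytes (which the test alone would catch at any n)
  in the panel-eligible pool, and makes the null false-exclusion rate
  strictly below α.

## Marker discovery

Welch's unequal-variance t test and the two-sample KS test per analyte on
log2 values, each Benjamini–Hochberg adjusted; candidates are analytes with
q < 0.01 under either test (configurable to one test). Candidates are then
ranked **once** by Gini importance (mean decrease in node impurity) from a
single random forest over all candidates — 1000 trees, bootstrap per tree,
√p features per split — rather than by stepwise selection; panels of size k
are nested prefixes of this one ranking, so the panel-size scan cannot
overfit by reselecting. Each k is scored by out-of-bag AUC; the scan's
chosen k is the smallest within one DeLong standard error of the maximum,
with the pipeline pinning k = 13 by default. Discovery operations accept a
blinding audit object and refuse to run on samples outside the training
split; the audit log lands in the run's provenance.

## Classifier and threshold

A random forest on the log2 panel values. Scores are vote fractions (share
of trees voting disease). The decision threshold is fixed at training time
and immutable thereafter: by default the cutoff maximizing out-of-bag
sensitivity + specificity (the Youden point, operationalising "equal
importance to sensitivity and specificity"), with ties broken toward
minimal |sens − spec| and then the lower cutoff. Out-of-bag rather than
resubstitution scores are used so the threshold is not set against
memorised training predictions. Prediction reads only the RFU matrix —
there is no code path from scoring to labels — and a missing panel analyte
is a hard error rather than an imputation.

**Version bridging.** When the assay changes format, the same panel is
retrained on bridging samples measured in the new format and concordance is
judged by the Spearman rank correlation between old-format scores (old
model on old measurements) and new-format scores (retrained model on new
measurements) over the shared samples, flagged below 0.9. The old
measurements enter explicitly because applying an old-format forest to
rescaled new-format data would conflate the reference-range shift with
genuine classifier disagreement.

## Evaluation statistics

Proportions are reported in percent with Wald intervals
p ± 1.959964·√(p(1−p)/n), clipped to [0, 100] and displayed at 1 decimal
(full precision retained internally); Wilson intervals are available as a
switch. Pooled metrics always come from summed confusion counts, never from
averaged percentages. AUC is the trapezoidal area over all distinct
cutoffs, equal to the Mann–Whitney concordance probability with half-credit
ties; its default CI is DeLong (deterministic), with a stratified
percentile bootstrap as the alternative. Alternative operating points
maximize sensitivity subject to a specificity floor, ties toward higher
specificity. Screening arithmetic is the exact Bayes identities for
PPV/NPV/population accuracy at a stated prevalence (default 0.014, the MM
rate observed when CT-screening asbestos-exposed cohorts); boundary
prevalences 0 and 1 return the documented limits.

## The synthetic cohort generator

The generator's defaults are the study conditions every end-to-end test
runs under. Per analyte a and sample s,

log2 RFU = baseline_a + site_offset(site, a)
         + case_effect_a · stage_multiplier (cases, marker analytes)
         + draw_shift (intra-op rows, artifact analytes)
         + degradation_shift (degraded samples, degradation analytes)
         + plate_bias(plate) + N(0, noise_sd²),

exponentiated to RFU. Defaults: 1045 analytes with baselines
N(10, 1.5²) log2; 13 strong markers at ±1.0 log2 (4 down-regulated, 9 up)
and 51 weak markers at ±0.5 — 64 spiked candidates in all; stage
multipliers I 0.5, II 0.75, III 1.0, IV 1.25 so signal grows with disease
burden; noise_sd 0.5; per-(site, analyte) offsets N(0, 0.1²); per-plate
scalar biases N(0, 0.2²) with 8 calibrator wells per plate (replicate noise
0.1); 30 artifact analytes shifted +1.5 log2 in intra-op draws; a
degradation artifact of −1.5 log2 on a random 20% of non-marker analytes.
The degraded subcohort is generated as an *additional* control-only
collection site sized like one clean site's control count (30 at the
default 60/60 design), mirroring an archived control set that is removed
during QC and never counted in the cohort description; blinded cohorts are
generated clean. Paired draws add a per-subject random intercept
(sd 0.3) so the pairing is informative. Cohorts of a study share all latent
parameters (baselines, marker identities and effects, site offsets) and
differ only in sampling; one master seed fans out through fixed named
substreams, so adding a component never perturbs earlier draws.

What the generator does **not** emulate: assay chemistry (binding
kinetics, dilution bins), heavy-tailed or analyte-correlated noise,
covariate-dependent missingness (there is none), pleural-effusion
subjects, or real biological covariance between markers. Passing tests
therefore demonstrate that the pipeline recovers the structure it assumes,
at the stated sizes and effect magnitudes — not that those assumptions hold
for any particular real cohort.

## Numerical and design notes

* Stratified splitting uses proportional allocation with largest-remainder
  rounding, ties broken by class name; exact string matching on ids,
  case-sensitive.
* The default study design generates training (60/60), verification
  (19/20) and validation (38/62) cohorts at exact sizes from shared latent
  parameters; a 75%/25% stratified split of a single discovery cohort is
  available separately (`join_and_split`).
* KS distances are computed by ECDF evaluation on the pooled sample — no
  asymptotic approximation enters the distance itself; test p-values for
  the univariate screen use scipy's two-sample machinery.
* Identical case/control values in the univariate screen report p = 1 and
  fold change 1 with direction NA; zero-variance Welch statistics are
  mapped to p = 1.
* Samples never out-of-bag (vanishingly rare at 1000 trees) score 0.5 in
  OOB vectors.
* Youden threshold scanning includes a sentinel cutoff just above the
  maximum score so the all-negative rule is a candidate.
* DeLong variance uses midrank placements; degenerate (perfectly
  separated) score sets yield a zero-width interval.
* Models persist via joblib (config + learner + frozen threshold +
  training-id hash); a model hash over the decision function supports the
  threshold-immutability check.

## Test problem sizes

Multi-seed simulations in the suite run at the default study conditions
where a check depends on them (marker recovery, degraded-sample flagging:
20 seeds at 1045 analytes) and at reduced sizes where it does not
(orchestration determinism: 250 analytes, 200 trees; rank-exchangeability:
50 seeds at 20 candidates, 100 trees). The full suite runs in about two
minutes; the acceptance script's end-to-end run takes under half a minute.

## Known limitations

* The KS threshold 0.45 is calibrated for ≈ 30 controls per site; at much
  smaller sites the null distribution of D crosses it and the filter
  over-excludes (the filter warns through its report, not automatically).
* PCA sample flagging at 3 MADs removes a small number of legitimate
  samples with outlying scores (~1–5% at the defaults); this matches
  archival-cohort practice but means cohort sizes after QC are not exactly
  the design sizes.
* Forest vote-fraction scores are not calibrated probabilities; no
  calibration step is provided.
* Local-FDR-based candidate selection and judgment-driven PCA exclusions
  from the original workflow are replaced by transparent thresholded rules
  (BH q < 0.01; η and MAD cutoffs), all exposed in config.
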