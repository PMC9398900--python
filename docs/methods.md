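# Methods

## The model

The package treats "biological noise" as the dispersion of a protein's
level in an assumed steady state.  Measurement uncertainty is taken to be
comparable across cohorts, so a change in cross-sample (or within-slide
replicate) SD between cohorts is read as a change in how tightly that
protein's level is controlled.  Three empirical regularities drive the
design: noise rises with age, rises further with neurocognitive disease,
and contracts when old plasma is diluted by therapeutic plasma exchange
(TPE).  A small panel of analytes that show all of these behaviors is a
"noise-reporter" panel, and the mean of their SDs — the noise score — is
modeled as linear in chronological age, giving a clock whose inversion
yields a direct measurement of biological age.

## Statistics

**Mean-based Levene test.**  Variance-shift significance is a one-way
ANOVA on absolute deviations from group means, `Z_ij = |x_ij − x̄_i|`,
referred to F(k−1, N−k).  The mean-centered form is deliberately chosen
over the median/trimmed-mean Brown–Forsythe variants (available via
`center=`): at cohort sizes of 5–30 the robust variants have very little
power.  The cost is size: the mean-based statistic is *liberal* at small
n.  On 50 null generator datasets (507 analytes, n = 8/side) we measure a
p < 0.05 fraction of ≈ 0.073, and ≈ 0.063 even on symmetric normal data —
the F reference distribution is simply not exact at n = 8, and skewed
(log-normal) abundances inflate it further.  The corresponding
acceptance-suite test asserts the nominal ±2-Monte-Carlo-SD band around
0.05 and is therefore expected to fail; it is kept as an honest record of
the test's small-sample behavior rather than loosened.  Rules that build
on the test compensate by demanding agreement across multiple transitions
and/or FDR control (below).

**Multiplicity.**  Benjamini–Hochberg step-up at q = 0.10 per transition
across the analyte family (stable sort; rejections are a prefix of the
p-sorted list and monotone in q).

**Panel rules.**  With transitions young→old (aging), old→disease, and
TPE round 0 → last round:

* A: FDR-significant SD increase with aging ∧ SD decrease with TPE;
* B: significant SD increase with aging ∧ with disease;
* C: significant SD increase with aging ∧ SD contraction ≥ 5-fold with
  TPE (the fold filter is applied to the ratio in the direction of
  change, i.e. `sd_pre/sd_post`);
* D = B ∧ C (recorded in provenance).

Panel = A ∪ B ∪ C plus externally nominated analytes (e.g. a
network-node protein chosen on ontology/interaction grounds), each member
tagged with the rules that admitted it.  Rule A uses the FDR flag and
rules B/C the raw p at α = 0.05 by default; each rule's mode is
configurable.  "Significant" SDs use the n−1 denominator throughout, and
the scan operates on the normalized natural scale (the scale on which the
array SDs are conventionally reported).  A consequence worth knowing:
for positively skewed abundances, a mean shift scales the natural-scale
SD proportionally, so strongly mean-shifted analytes are genuinely
scale-shifted as well and can enter the panel at large n.  The level
screen and the noise screen are therefore complementary, not orthogonal.

**Differential levels.**  Per-analyte two-sided two-sample Student's t
(equal variances by default, Welch behind a flag) with a strict two-sided
fold rule: selected iff `fold > 1.75 or fold < 1/1.75` *and* p < 0.05.
The boundary is exclusive (an exactly 1.75-fold analyte is not selected).
No multiplicity correction is applied at this stage; the screen is a
candidate filter.  The fold change is a ratio of cohort means on the
normalized scale with a symmetric floor (default 1e-12) so the label-swap
symmetry fold → 1/fold is exact.  Zero-variance-in-both-groups analytes
get p = 1 (equal means) or 0 (unequal) and a `degenerate` flag.

**Trajectory.**  The panel submatrix is z-scored per analyte (SD with
n−1; constant analytes map to 0), projected on the first two principal
components, and each group centroid `c` is summarized as
`(c − c_old)·(c_young − c_old)/‖c_young − c_old‖²`, i.e. progress along
the old→young axis: 0 at the old centroid and 1 at the young centroid by
construction, and invariant to rotation of the PC basis.  A panel of
rank < 2 raises an error naming the rank.

**Noise score and clock.**  Replicate mode: per panel analyte, the SD
(n−1) of the sample's replicate spots, averaged over the panel — the
default, since these arrays print replicate spots.  Panel-dispersion
mode: analytes are z-scored against the young reference cohort and the
score is the SD of the sample's z-values across the panel.  The clock is
OLS of score on age (slope in score-units/year) on a healthy reference
(young + middle + old by default, never disease or TPE samples), with
Pearson r and its two-sided p.  Biological age is classical calibration,
`(score − intercept)/slope`; negative predictions are reported with an
`extrapolated` flag rather than clamped.  The score-to-age ratio
("relative noise age") is reported as a separate field, never folded into
the fit.  Scores, clocks and reports carry mode and a panel hash;
cross-mode or cross-panel prediction raises.

**Normalization.**  `b = mean(neg controls)` is subtracted from every
spot; analyte spots are clamped at 0 (controls are kept unclamped as QC
diagnostics, which also makes renormalizing a normalized sample the
identity); everything is scaled by `ref / (mean(pos) − b)`.  The batch
reference defaults to the median of per-sample background-corrected
positive-control means; when the nominal positive-control level is known
(as for the simulator, or a spike-in of known concentration) it can be
passed explicitly, which pins the absolute score scale.  A sample whose
positive controls do not exceed background is uninterpretable and is
excluded (or raises), never silently normalized.  Normalization is
exactly (to machine precision) invariant to a global scanner gain and
idempotent.  Per-sample (per-slide) normalization is used; no
cross-slide quantile normalization is applied.

## The synthetic generator

The generator emulates the study design end to end; its defaults are the
package's reference conditions.

| parameter | default | meaning |
|---|---|---|
| `n_analytes` | 507 | array panel size |
| `n_per_cohort` | young/middle/old/disease 5, tpe 8 | subjects per cohort |
| `ages` | young 20–30, middle 46–52, old 60–79, disease 64–90, tpe 46–79 y | uniform sampling ranges |
| `level_shift_set`, `level_shift_ratio` | 72 analytes, 2.0-fold | old-vs-young mean shifts (half up, half down) |
| `noise_set` | 9 analytes | planted noise reporters |
| `sd_inflation_old` / `sd_inflation_disease` | 3.0 / 5.0 | log-SD fold at the old mid-age / in disease |
| `n_rounds`, `tpe_sd_contraction`, `tpe_recovery_fraction` | 4, 5.0, 1.0 | TPE schedule (R0..R3) |
| `replicates_per_spot`, `baseline_cv` | 2, 0.05 | duplicate printing, technical CV |
| `baseline_sigma` | 0.2 | healthy biological log-SD (~20% CV) |
| `log_level_mean`, `log_level_spread` | ln 500, 0.5 | analyte baseline log-levels |
| `gain_sd`, `control_spots` | 0.2; 6 pos @ 20000, 6 neg @ 150 | slide gain and control layout |

Levels are log-normal (positive, right-skewed), and all variance planting
acts on the log scale so SD-fold parameters are scale-free.  Healthy
noise inflation grows *linearly with age* from 1 at the young-cohort
mid-age to `sd_inflation_old` at the old mid-age — a modeling choice (the
emulated study only contrasts cohorts) that makes the implied noise–age
relation genuinely linear, i.e. gives the clock a well-defined truth.
Disease inflation is flat (an age-matched cohort with an additional
pathology effect).  Mean shifts, by contrast, are cohort-step contrasts
(young 0, middle ½, old/disease/TPE-R0 full shift).  Replicate-spot CV
tracks the same inflation by default, so within-slide replicate scatter
is a readout of biological dispersion; with
`replicate_noise_tracks_dispersion=False` replicates carry pure technical
noise and the replicate-mode clock has slope ≈ 0.

The TPE series draws the same subjects at every round.  Per round the
planted log-SD falls along a linear-in-round schedule whose total drop is
`tpe_recovery_fraction · log(tpe_sd_contraction)`; the default total
contraction of 5 from a threefold inflation deliberately *undershoots*
the young SD (post-exchange levels become the most tightly controlled),
while `tpe_sd_contraction=None` means full return to the subject's own
young-level SD, in which case the last round is statistically
indistinguishable from the young cohort.  Level shifts relax toward young
means on the same schedule.  There is no per-subject longitudinal
autocorrelation model: rounds are conditionally independent draws given
the schedule — a stated assumption, not an inference from data.

Every dataset is emitted with a `GroundTruth`: the planted sets,
per-cohort generating moments, each sample's implied replicate-mode score
(`c4(n_rep) · cv · level`, the unbiased-SD normal approximation), and the
config-implied clock line obtained by weighted OLS of the expected score
over the healthy age design.  Determinism is exact: one seed feeds three
fixed child streams (analyte parameters, cohorts, TPE series), so
cohort-only, TPE-only and combined simulations are mutually consistent
and bit-identical under a fixed config.

What the generator does **not** emulate: inter-protein correlation
(analytes are independent), batch/slide spatial artifacts beyond a global
gain and additive background, non-uniform age distributions,
subject-level longitudinal memory, and assay saturation.  Passing tests
on synthetic data therefore validate the statistical machinery and its
calibration, not the biological claims on real serum.

## Validation and calibration choices

The acceptance suite checks, under the reference conditions: exact
equivalence of the Levene implementation with an independent
ANOVA-on-deviations oracle; exact equivalence of the BH implementation
with exhaustive rank-by-rank evaluation (plus monotonicity in q); the
null size of the variance scan (the expected-fail test discussed above);
recovery of the planted 9-reporter panel at n = 30/cohort with median
false discoveries ≤ 2; coverage of the generator-implied clock slope by
the fitted 95% OLS confidence interval in ≥ 90% of seeds (a ±1-SE band
cannot reach 90% coverage even for an ideal unbiased estimator, so the
conventional confidence band is the meaningful check); machine-precision
normalization invariances; ≥ 95% mean recall of 72 planted two-fold level
shifts at n = 20/cohort with false positives bounded by α; and the
end-to-end rejuvenation direction (every TPE subject's biological age
drops R0→Rlast; the disease cohort's mean biological age exceeds its
chronological mean).  Panel-recovery and end-to-end runs plant the noise
channel only (level shifts off): because a log-normal mean shift scales
the natural-scale SD proportionally, planted level shifts are *bona
fide* scale shifts at large n and would be miscounted as "false"
discoveries of the noise screen.  Problem sizes (25–100 seeds, 8–30
subjects/cohort, 507 analytes) were chosen so each property is measured
with comfortable Monte-Carlo margin while the whole suite stays fast.

## Numerical conventions

Sample SDs use ddof = 1 everywhere.  `sd_fold` is NaN when both sides
have zero SD and +inf when only the denominator does; such analytes are
`flat` with p = 1.  Levene with zero within-group deviation spread
returns W = 0, p = 1 (no evidence) or W = ∞, p = 0 (deviation means
differ).  BH uses a stable sort, so ties keep input order.  Invariance
claims ("exact") mean to floating-point precision (asserted at
rtol ≈ 1e-10).  Clock fitting requires ≥ 3 samples and ≥ 2 distinct ages;
a slope of exactly 0 stores the fit but disables prediction with a clear
error.

## Limitations

* The mean-based Levene test's liberal small-n size means raw p-values
  from tiny cohorts should not be read as calibrated; the intersection
  rules and FDR flags are the intended inferential surface.
* Replicate-mode scores read within-slide dispersion; they equal the
  cohort-level "mean of SDs" notion only insofar as replicate scatter
  tracks biological dispersion (true in the generator by default,
  an assumption on real arrays).  Both modes are provided and recorded
  precisely because the real-data construction is ambiguous.
* Biological age by inverse calibration inherits the clock's reference
  population: scores far above the reference range extrapolate (flagged,
  not clamped), which is how >100-year disease-cohort ages arise.
* The natural-scale variance scan couples mean and SD for skewed data;
  log-scale screening would decouple them but changes the meaning of the
  SD-fold thresholds, so it is left to the caller via transformation of
  the input matrix.
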