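# proteonoise

Proteome-**noise** profiling for antibody-array serum proteomics, and a
direct, linearly calibrated noise–age clock.

Most molecular aging clocks *predict* age by training a model on large
cohorts.  This package implements a different idea: the variability (SD) of
certain circulating proteins — their *biological noise* — rises with age,
rises further with cognitive disease, and falls when old plasma is diluted
by therapeutic plasma exchange (TPE).  A small panel of such noise-reporter
proteins turns the mean of their SDs into a quantity that is naturally
linear in chronological age, so biological age can be **measured** by
inverting a fitted trendline rather than predicted by machine learning.

It is intended for groups analyzing antibody-array (or similar targeted)
abundance panels across age/disease cohorts and longitudinal interventions,
and ships a first-class synthetic-cohort generator so every stage of the
pipeline can be validated against planted ground truth.

## What it computes

Given a normalized analyte × sample matrix with cohort/round/age metadata:

1. **Control-spot normalization** — slide background (negative-control
   mean) is subtracted, then all spots are rescaled so the positive-control
   mean hits a common reference; invariant to scanner gain.
2. **Differential levels** — per-analyte two-sample Student's *t* plus a
   two-sided fold-change rule (|fold| > 1.75 by default), and a PCA
   centroid trajectory expressing each TPE round as progress along the
   old→young axis.
3. **Differential variability** — the mean-based Levene test per analyte
   and cohort transition,

   `W = ((N−k)/(k−1)) · Σᵢ nᵢ(Z̄ᵢ − Z̄)² / Σᵢⱼ(Zᵢⱼ − Z̄ᵢ)²`, `Zᵢⱼ = |xᵢⱼ − x̄ᵢ|`,

   with Benjamini–Hochberg FDR control (q = 0.10) per transition, and
   intersection rules over (young→old, old→disease, pre→post TPE,
   ≥ 5-fold SD contraction) that select the noise-reporter panel.
4. **The noise clock** — per-sample noise score (mean over the panel of
   replicate-spot SDs, or a panel-dispersion variant for replicate-free
   matrices), OLS trendline `score = slope·age + intercept` on a healthy
   reference, Pearson *r*, and biological age by classical calibration
   `(score − intercept)/slope`, including per-subject TPE shifts and
   disease-cohort excess.

## Worked example

```python
from proteonoise import *

cfg = SimulationConfig(seed=1, level_shift_set=(),
    n_per_cohort={"young": 30, "middle": 30, "old": 30, "disease": 30, "tpe": 8})
samples, truth = simulate_study(cfg)

norm = ControlNormalizer().fit(samples)
matrix = assemble_matrix(norm.transform(samples))

table = variance_scan(matrix, q=0.10)
panel = select_noise_panel(table, sd_fold_min=5.0)
print("panel:", ", ".join(panel.analytes))

scores = noise_score(matrix, panel, mode="replicate")
healthy = matrix.meta["cohort"].isin(["young", "middle", "old"])
clock = fit_clock(scores, matrix.meta["age"],
                  reference_ids=list(matrix.meta.index[healthy]))
print(f"clock: slope={clock.slope_:.3f}/yr Pearson r={clock.pearson_r_:.3f}")

shifts, summary = tpe_age_shift(matrix, panel, clock)
print(f"mean shift {summary['mean_shift']:.1f} years "
      f"(paired t p={summary['p_value']:.4f})")
```

Output:

```
panel: P001, P002, P003, P004, P005, P006, P007, P008, P009, P419
clock: slope=0.888/yr Pearson r=0.687
mean shift -43.7 years (paired t p=0.0006)
```

The generator planted nine noise reporters (P001–P009) with threefold SD
inflation in the old cohort and a fivefold contraction over four TPE
rounds; the scan recovers all nine (P419 is one false discovery at
q = 0.10).  The clock's Pearson *r* of ~0.7 on 90 healthy reference
subjects reflects the biological + replicate scatter around the linear
noise–age trend, and every TPE subject's biological age drops from round 0
to the last round — a mean rejuvenation of ~44 years on this fully applied
recovery schedule.  The disease cohort, whose planted inflation is
fivefold, comes out decades biologically older than its chronological age.

The same pipeline is scriptable from the shell (`proteonoise simulate`,
`normalize`, `select-levels`, `trajectory`, `select-noise`, `fit-clock`,
`predict`, `tpe-shift`); see `proteonoise --help`.

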