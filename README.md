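# rehoband

Frequency-resolved regional homogeneity (ReHo) state-comparison pipeline,
with synthetic BOLD phantoms for end-to-end validation.

## What this is for

Working-memory deficits in mild cognitive impairment (MCI) have mostly been
studied through task activation. A complementary question is how the brain's
*intrinsic* local synchrony reorganises between rest and a working-memory
state, and in which frequency band. `rehoband` implements that analysis for
two groups (patients vs. elderly controls) scanned in two states:

1. **Temporal preprocessing** — volume trimming, head-motion QC, nuisance
   regression (motion, global, WM, CSF), and ideal band-pass filtering into
   the named BOLD bands slow-6…slow-2 partitioning 0–0.25 Hz
   (e.g. slow-5 = 0.01–0.027 Hz).
2. **ReHo** — voxel-wise Kendall's coefficient of concordance over a voxel
   and its 26 neighbours,

   `W = 12 S / (k²(n³−n) − k ΣT)`,

   computed on unsmoothed data, z-standardized within the brain mask per
   subject, then smoothed (4 mm FWHM).
3. **Group × state interaction** — voxel-wise repeated-measures interaction
   via difference scores (task − rest) regressed on group plus covariates
   (age, sex, education, motion); the squared group-t is the interaction F.
   Multiple comparisons are handled with a seeded AlphaSim-style Monte-Carlo
   cluster-extent threshold; retained clusters get post-hoc two-sample and
   paired t-tests.
4. **Seed connectivity** — Pearson correlation maps against each significant
   cluster's mean time course, Fisher z transform, group/state t contrasts.
5. **Behaviour** — delayed-match-to-sample scoring (accuracy = hit rate −
   false-alarm rate; performance = accuracy/RT) and Pearson correlation of
   cluster-wise state changes with performance, with 1000-resample bootstrap
   percentile CIs, within each group separately.

No subject data ships with the package. A first-class phantom module
generates two-group × two-state 4D cohorts with band-limited synchrony
planted in known clusters (`√w·latent + √(1−w)·noise`), nuisance structure,
trial schedules and behaviour coupled to the planted state change — so every
claim the pipeline makes is testable against ground truth.

## Worked example

```python
import numpy as np
from rehoband import (PhantomConfig, generate_cohort, analyze_band)

cohort = generate_cohort(PhantomConfig(grid_shape=(18, 18, 12), rng_seed=7))
res = analyze_band(cohort, "slow-5", seed=7, do_fc=False)
print(res.clusters[["label", "size", "peak_stat"]])
print(res.posthoc[1][["comparison", "state", "group", "t", "direction"]])
print(res.correlations[["group", "r", "ci_low", "ci_high"]])
```

Output from this exact run:

```
   label  size  peak_stat
0      1   108  75.802164
1      2    26  18.499283
     comparison state group         t direction
0     NC vs MCI  rest        5.566785
1     NC vs MCI  task       -8.215584
2  task vs rest          NC -7.426943  decrease
3  task vs rest         MCI  5.519884  increase
  group         r    ci_low   ci_high
0    NC  0.014713 -0.578873  0.502549
1   MCI -0.277955 -0.552151  0.035472
2    NC  0.307182 -0.169764  0.723381
3   MCI  0.358241 -0.125873  0.678148
```

Reading it: the default phantom plants one slow-5-band cluster whose local
synchrony drops from rest to task in controls but rises in patients. The
pipeline recovers a 108-voxel cluster (peak F = 75.8) surviving the
Monte-Carlo extent threshold; post-hoc tests show controls above patients
at rest (t = 5.6), below them in the task state (t = −8.2), and the paired
tests give the planted crossover (decrease in NC, increase in MCI). The
second, smaller cluster is the spillover of subject-wise map
standardization around a strong effect — see `docs/methods.md`. The
brain–behaviour rows correlate each cluster's measured state change with
performance per group: in this single cohort the patient-group estimate for
the planted cluster is r = −0.28 — one n = 17 draw of a coupling planted at
−0.63, attenuated by measurement noise in the cluster change; the
replicate study run by the acceptance script recovers the population value.

The same analysis runs from the shell:

```bash
rehoband simulate --out demo --seed 7
rehoband run-all  --out demo --seed 7     # all bands, manifest.json, NIfTI/TSV outputs
```

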