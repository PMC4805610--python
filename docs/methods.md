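# Methods

`rehoband` compares local BOLD synchrony between a resting and a
working-memory state, across an impaired and a control group, separately in
narrow frequency bands. This note describes the model and the choices behind
every stage; it is written for someone who wants to know exactly what the
numbers mean and where the defaults come from.

## Regional homogeneity (ReHo)

For every in-mask voxel, ReHo is Kendall's coefficient of concordance W
between the voxel's time series and those of its 26 nearest neighbours
(faces, edges and corners of the 3×3×3 cube; 6/18 also available). With k
series of length n, time-wise rank sums R_t and S = Σ_t (R_t − R̄)²,

    W = 12 S / (k² (n³ − n) − k ΣT),   T = Σ (t³ − t) over tie groups,

so W ∈ [0, 1], W = 1 for identical rank orderings, and E[W] = 1/k under
independence. Ranks are averaged over ties and the denominator is
tie-corrected; BOLD data essentially never tie, but quantised fixtures do,
and the correction keeps W exact there. k(n−1)W follows the Friedman
statistic's approximate χ²(n−1) null, which the tests verify by simulation.

At mask borders the in-mask subset of the neighbourhood is used (k varies,
minimum 2), keeping the map full-mask rather than eroding it; isolated
voxels get W = 0 and a log message. ReHo is always computed on **unsmoothed**
data — smoothing first would manufacture synchrony. Each subject's raw map
is then z-standardized using the within-mask mean and *sample* SD (the
"entire brain" is taken to be the analysis mask), and only the standardized
map is smoothed with a Gaussian kernel (default FWHM 4 mm, σ =
FWHM/(2√(2 ln 2)) per axis, zero-padded at the volume edge with the mask
re-applied afterwards).

## Temporal preprocessing

Order: trim → nuisance regression → detrend + band-pass.

- **Trimming** removes leading volumes (equilibration): 46 from a 200-volume
  resting run and 9 from a 163-volume task run leaves 154 volumes per state,
  so both states contribute equal data.
- **Motion QC** fails a scan whose maximum absolute translation reaches
  3 mm (strict inequality: motion must stay below the bar). The scalar
  motion covariate is the mean framewise displacement — the sum of absolute
  backward differences of the six rigid-body parameters, rotations converted
  at a 50 mm head radius. The source analysis names only "head motion" as a
  covariate; mean FD is the field-standard scalarisation.
- **Nuisance regression** removes, per voxel, the least-squares fit of
  [intercept | 6 motion parameters | global mean | white matter | CSF];
  residuals are orthogonal to every retained regressor, and collinear
  columns are dropped with a warning.
- **Band-pass** is an ideal rectangular DFT filter (the convention of the
  REST/DPABI family): linear detrend, real FFT, zero every bin outside the
  band, inverse FFT. The spectrum up to 0.25 Hz (Nyquist at TR = 2 s) is
  partitioned as slow-6 (0–0.01 Hz), slow-5 (0.01–0.027), slow-4
  (0.027–0.073), slow-3 (0.073–0.198), slow-2 (0.198–0.25). A bin is kept
  iff f_low < f ≤ f_high, so a bin landing exactly on a printed edge belongs
  to the lower band and the named bands tile (0, Nyquist] — band variances
  then sum exactly to the detrended variance (Parseval), which is tested at
  1e-8 relative. Analyses default to slow-5…slow-2; slow-6 mostly carries
  scanner drift and is available on request.

Two numerical caveats worth knowing. The rectangular filter is a spectral
projection and exactly idempotent, but detrending and the projection do not
commute, so re-running the *full* operator on its own output changes it
slightly; the projection part is tested idempotent with detrending disabled.
And a sinusoid that falls between DFT bins leaks a little energy across the
band edge — a mid-bin 0.05 Hz tone emerges from its own passband with
correlation ≈ 0.988 rather than 1.0. Both are properties of the prescribed
filter, not bugs.

## Group × state interaction

The repeated-measures interaction is fitted on difference scores: per
subject d = (task z-map) − (rest z-map), regressed voxel-wise on
[intercept | group | age, sex, education, motion, (optional grey-matter
intensity)]. The squared t of the group coefficient is the interaction F
with df (1, N − q). For a balanced 2×2 design with subject-constant
covariates this is algebraically the mixed-model interaction test:
differencing eliminates the subject and state main effects (adding a
constant to every map of one state provably changes no F value), and the
between-subject regression of d on group is exactly the interaction
contrast. The tests verify equality with an independent mixed-ANOVA
implementation and with the squared two-sample t. Voxels with zero residual
variance report p = 1.

**Cluster-extent correction** is Monte-Carlo (AlphaSim-style): fill the mask
with white Gaussian noise, smooth, re-standardize within the mask, binarize
at the one-tailed z-quantile of the voxel p (0.01), label clusters
(18-connectivity by default — faces + edges, matching the toolbox family's
edge-distance rule at 3 mm voxels), and record the maximum extent; over
1000 seeded iterations, k* is the smallest extent whose exceedance
probability is ≤ α (0.05). F-test p-values are one-tailed by construction;
no two-tailed splitting is applied.

The noise smoothness fed to the Monte-Carlo is, by default, **estimated from
the group-demeaned difference maps** (per-axis Gaussian-field estimate from
gradient variance) rather than taken as the applied 4 mm kernel
(`smoothness="applied"` restores that). The reason is empirical: ReHo maps
are intrinsically far smoother than the applied kernel, because adjacent
voxels share 18–26 of their 27 neighbourhood series. On phantoms, the
applied-FWHM threshold (k* ≈ 8 at these sizes) let several null clusters
through per analysis, while the estimated-smoothness threshold (k* ≈ 20)
keeps the family-wise rate near α. The gradient-variance estimator is
mildly biased low (~10% on known fields), which leaves the correction
slightly anti-conservative; this is noted, not hidden.

One spillover is inherent to subject-wise standardization and worth knowing
when reading phantom results: a strong planted cluster shifts a map's
whole-brain mean differently per (group, state) cell, so out-of-cluster
z-values acquire a small opposite-signed interaction everywhere. On real
data the same mechanism operates whenever a large genuine effect exists.
The recovery study therefore reports an "off-target cluster rate" alongside
recovery; it reflects this spillover, not a failure of the null correction
(which is calibrated on effect-free phantoms).

Retained clusters are reported with size, peak F and peak grid coordinate
(ties broken by the first voxel in lexicographic order), then characterised
by post-hoc t-tests on cluster-mean z-ReHo: pooled two-sample t between
groups per state, paired t between states per group, with the direction of
each cell's change.

## Seed connectivity

Each significant cluster seeds a connectivity analysis **on the same
band-filtered series in which it was found** (the band semantics stay
coherent). The seed time course is the unweighted voxel mean; each voxel's
Pearson r with it is Fisher-transformed (z = atanh r, |r| clipped at
1 − 1e-7 so self-correlations stay finite; zero-variance voxels get r = 0
and are counted). Group contrasts are voxel-wise pooled two-sample t-tests
between groups within a state; state contrasts are paired t-tests within a
group. Thresholded summaries keep positive differences only (negative values
remain in the raw t maps); thresholding reuses the cluster machinery at a
configurable voxel p (default 0.05) and the band's extent threshold.

## Behaviour

The working-memory task is a blocked delayed-match-to-sample: 4 blocks × 8
trials, each trial showing 2 targets followed by 12–13 test objects, every
target and distractor appearing 2–4 times in pseudo-random order. Scoring:
accuracy = hit rate − false-alarm rate (hits are "match" responses to
targets; misses count as non-hits), RT is the mean over all responded test
stimuli, and performance = accuracy / RT (per ms; the reciprocal of the
inverse efficiency score — realistic values sit near 1.5×10⁻³).

Brain–behaviour coupling is the Pearson correlation between a cluster's
state-related change (mean z-ReHo, task − rest) and performance, computed
**within each group separately** (never pooled), with a two-tailed t
approximation (df n−2) and a seeded case-resampling percentile bootstrap
(default B = 1000, 95% bounds). Percentile rather than BCa: only the count
and level are prescribed, and percentile adds no assumptions. At n = 17 the
percentile CI's true coverage is a little below nominal (the simulation
study measures ~92–95%); that is a property of the method at this sample
size.

## The phantom generator

The generator produces the study conditions every stage expects: 16 control
and 17 impaired subjects, two states each, 154 volumes at TR = 2 s, 3 mm
voxels, default grid 24×24×16. Local synchrony is planted in a connected
cluster as

    voxel = √w · latent + √(1−w) · noise,   w ∈ [0, 1] per (group, state),

where the latent is white noise passed through the *same* ideal band-pass
used in preprocessing (so its spectrum is exactly band-limited — no second
filter definition) and the noise is independent white noise per voxel. After
band-filtering, in-band neighbour correlation exceeds w because only the
band's share of the noise variance survives; w is therefore a synchrony
*weight*, not the achieved correlation, and achieved in-cluster W is
monotone in w (tested). The default planted effect is one slow-5 cluster
(≥ ~100 voxels) with the canonical crossover: w falls 0.35 → 0.05 from rest
to task in controls and rises 0.05 → 0.35 in patients. Per subject, w is
jittered (SD 0.04, clipped to [0, 1]; clipping bites occasionally at the low
end) so subjects differ in their true state change.

The crossover magnitude was calibrated deliberately. Because one latent
realisation drives a whole cluster per scan, cluster-mean W fluctuates as a
unit and the between-subject variance of the difference scores is large; a
planted effect must therefore be strong to be detected reliably at n =
16/17, just as the interaction effects the design is modelled on were strong
(peak F values well above 10). The default weights are set so the corrected
analysis detects the planted cluster in well over 80% of replicate cohorts —
detectability of the default effect is a design requirement of the phantom,
since every downstream recovery study conditions on it.

On top sit a constant baseline (1000), a weak shared global fluctuation
(weight 0.2, removed again by nuisance regression), motion random walks
(0.02 mm/step — well under the QC bar), and white-matter/CSF regressor
series. Covariates are drawn per group from normal/Bernoulli distributions
matched to a typical elderly MCI-vs-control cohort (ages ≈ 68.6 ± 5.8 vs
70.5 ± 4.5, education 11.8 ± 3.2 vs 9.8 ± 4.6, roughly balanced sex).

Behaviour: performance = group baseline (1.51×10⁻³ controls, 1.16×10⁻³
patients) + coupling · (planted state change) + N(0, 6×10⁻⁵). RT is drawn
per subject from the group profile (610 ± 56 ms vs 693 ± 86 ms) and
accuracy = performance × RT, clipped to [0, 1] — so performance =
accuracy/RT holds exactly wherever clipping is inactive. The residual SD
6×10⁻⁵ was chosen so the implied accuracy spread matches a healthy elderly
cohort (~0.05) and clipping stays rare. The default coupling is calibrated
in closed form so the population correlation between change and performance
is −0.63 within a group. Response logs are simulated per scheduled stimulus
with hit/false-alarm probabilities consistent with the subject's accuracy
(plus a 2% miss rate), so scoring the logs recovers the generative scores to
within binomial noise on ~390 stimuli.

What the phantoms deliberately omit: anatomy, spatial misregistration,
slice-timing, scanner drift/spikes, physiological noise spectra, and any
spatial autocorrelation outside planted clusters. Passing tests therefore
establish the *statistical machinery* — calibration, detection, recovery —
not performance on real scanner data.

## Problem sizes used in the studies

The replicate studies keep the cohort (16/17), volumes (154), TR, effect
sizes and the ~144-voxel planted cluster at their defaults but run on a
compact 18×18×12 grid; null calibrations use 12×12×8; the Monte-Carlo null
facts use a 10⁴-voxel mask with 1000 iterations; behaviour recovery uses
200 replicates of n = 17 with B = 1000. These sizes were chosen to keep a
full reproduction run at desk scale while leaving every rate's Monte-Carlo
error well inside the asserted tolerances.

## Reproducibility

One global seed fans out through `numpy` SeedSequence spawning to every
stochastic stage (generation, Monte-Carlo, bootstrap). Gzipped NIfTI is
written with a fixed header mtime and empty name field, so repeated runs of
the same config and seed are byte-identical, manifest checksums included.

## Known limitations

- The difference-score interaction is exact for the balanced 2×2 design with
  subject-constant covariates; it is not a general mixed-model engine, and
  numerical parity with any particular GUI toolbox is not claimed.
- The smoothness estimator's low bias leaves the extent correction slightly
  anti-conservative; permutation or random-field alternatives are out of
  scope by design.
- Voxel coordinates are grid indices with a synthetic diagonal affine; no
  anatomical template space is implied.
- The bootstrap CI under-covers slightly at n = 17 (see above).
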