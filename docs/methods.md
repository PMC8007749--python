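# Methods

`dbsconn` reproduces, as reusable and tested code, the analysis pipeline of
a nine-participant randomised, double-blind, sham-controlled,
staggered-onset trial of deep brain stimulation (DBS) of the bed nucleus of
the stria terminalis (BNST) region for treatment-resistant
obsessive-compulsive disorder: the clinical outcome statistics, a
simplified stimulation-field model, and the three structural-connectivity
methods that relate the stimulation field to symptom improvement.  Because
the trial's imaging data and the HCP-985 normative connectome are not
redistributable, every analysis is exercised against a synthetic phantom
study with planted ground truth; the only real data shipped is the nine
participants' published endpoint table.

## Clinical outcome statistics

*Percentage reduction* is `100 * (baseline - endpoint) / baseline`;
negative values mean worsening.  *Responders* are participants with a
reduction at or above threshold (35% for YBOCS, 50% for MADRS); the
boundary is inclusive ("attained a reduction of 35%").  Cohort summaries
report both the sample (n-1) and population (n) standard deviations,
because published cohort tables mix the conventions: the endpoint table's
percentage reductions match the sample convention (49.6 ± 23.7) while the
baseline YBOCS dispersion matches the population convention (32.7 ± 2.6).

The *blinded-phase comparison* is a pooled-variance Student two-sample
t-test on change scores (baseline minus end-of-blinded score, so positive
is improvement); Welch's variant is available behind a flag because the
source analysis does not report degrees of freedom.

The *longitudinal mixed model* is

    score_ij ~ TimeSinceDBS_ij + Age_i + Gender_i + Baseline_i
               + (1 | participant) + (1 | timepoint)

fitted by maximum likelihood with `statsmodels` `MixedLM` (an all-ones
grouping with two variance components implements the crossed random
intercepts).  The timepoint term is implemented as written — a random
intercept per distinct assessment day — even though a random-slope reading
is also defensible; a per-participant random-slope variance component is
available behind `random_slope=True`.  The coefficient of interest is
TimeSinceDBS in points per day (negative = improvement).  Hypothesis
testing uses a 1-df likelihood-ratio test against the model without the
time term.  Time is internally rescaled to units of 100 days for optimiser
conditioning and reported back in days.  Gender enters as a two-level
factor, reference level female (alphabetical); the factor is dropped if a
cohort happens to contain a single gender.  On non-convergence the model
falls back to a single random intercept per participant and flags it.

An important calibration fact, discovered while validating the model: if
every participant shares the same assessment days, the per-timepoint random
intercept can absorb any common time trend and the likelihood-ratio test
becomes severely conservative.  With per-participant assessment-date
scatter (as in any real trial, and as produced by the generator) the
timepoint levels are mostly unique and the test is well calibrated (null
rejection rate ≈ 5%).

The *CBT effect* is a paired t-test of the last open-phase (pre-CBT
plateau) score against the last post-CBT score; participants whose post-CBT
values are LOCF carry-forwards are excluded.  *LOCF* (last observation
carried forward) is an explicit preprocessing step with an audit column.
The *normality check* is scipy's Shapiro–Wilk.

## Stimulation-field model

The quadripolar lead (1.5 mm contacts, 0.5 mm gaps, contacts 0–3 left /
8–11 right, ventral to dorsal) gives contact centre k at
`tip + (0.75 + 2k) mm` along the shaft.  The electric field is a capped
inverse-square point source per active contact,

    E(x) = sum_k  k_e * V / max(r_c, |x - c_k|)^2    [V/mm],

with core radius r_c = 1 mm and medium constant k_e = 1 V·mm.  This
deliberately replaces the finite-element volume-conductor model used in
the source analysis: it is closed-form, testable, and produces activation
radii of 4–5 mm at protocol amplitudes (3.5–5.6 V), which is the regime the
downstream connectivity analyses care about; absolute VAT volumes are not
comparable to finite-element ones, only the relational analyses are.  The
VAT is the super-threshold set with a chronaxie-style pulse-width scaling
`E_t(pw) = E_t90 * sqrt(90/pw)`, `E_t90 = 0.2 V/mm`.  Default constants
were chosen once for that 4–5 mm regime.  Only case-positive monopolar
stimulation is modelled (every chronic setting in the trial is "C+").
Voxel binning is half-open (a boundary point belongs to the higher-index
voxel); hemispheres are always modelled separately and fields are never
summed across hemispheres.

## Fibre connectomics

All streamline geometry is resampled at 0.5 mm arc-length steps, shared by
every operation.  *Recruitment*: a fibre's weight is its maximum E-field
value over in-VAT sample points, normalised by the largest such value over
all fibres for that field (the exact field-to-weight map of the original
toolchain is unpublished; this max-normalised variant is a declared
stand-in).  *Connectivity profiles* add each recruited fibre's weight once
per distinct voxel its path visits, so profiles are additive over disjoint
fibre subsets.  *R-maps* are voxel-wise Spearman correlations
(average-rank ties) of profile value with improvement across participants;
voxels with fewer than 3 participants showing nonzero connectivity are
invalid, preventing degenerate constant-vs-constant correlations.
*Spatial similarity* is the Pearson correlation between a profile and the
R-map over valid voxels, Fisher z-transformed with |r| capped at 1 − 1e−7.
*Leave-one-out prediction* builds the R-map from all-but-one participant
and predicts the left-out participant by spatial similarity; both Pearson
(default headline) and Spearman correlations of predicted against
empirical improvement are reported, with a label-permutation test
(add-one-corrected p).  *Fibre t-scores* contrast improvement between
participants whose binary VAT encompasses a fibre (≥ 1 resampled point
inside) and those whose VAT misses it, pooled-variance two-sided t, with a
minimum group size of 2 on each side; unscorable fibres are reported as
skipped, never zero.  Selection takes the top 5% *of positively scoring
fibres* by t (rank-based, no p threshold).  *ROI association* z-scores
per-label profile mass and enters it, interacted with time, into the
longitudinal model; rank-deficient columns are dropped by name, and
univariate per-ROI fits are emitted alongside the multivariate ones.  The
*tract-recruitment scorer* sums a named tract's recruitment weights per
participant and correlates the score with improvement (Pearson).

## The synthetic study

The generator manufactures all four inputs with known ground truth, at the
trial's stated conditions: baseline YBOCS 32.7 ± 2.6, blinded on-vs-sham
difference 4.9 points, open-phase maximum reduction 16.6 points, additive
CBT effect 4.8 ± 3.9 points, MADRS baseline 25 ± 6 with blinded/open
effects 3.4/10.8, n = 10 participants, outcome noise sd 2 points.

**Phantom connectome** (64 mm cube, 1 mm voxels, ~1.9k fibres): straight
bundles jittered per-waypoint perpendicular to the local tangent
(half-normal offset magnitude) and spline-smoothed at 0.5 mm, so bundles
are coherent tubes.  The layout is designed around the right stimulation
target:

* one **response bundle** (40 fibres, dispersion 1 mm) at 5.5 mm from the
  active contact — the edge of a protocol-amplitude VAT — so electrode
  placement determines how much of it each participant's VAT encompasses;
* six long **hub bundles** at 3.2 mm, recruited by every plausible VAT with
  near-constant weight: they anchor the weight normalisation and lay a
  stable profile "carpet" against which response-bundle mass can be read
  out by the scale-invariant spatial-similarity predictor;
* sixteen short **decoy bundles** (50 fibres each) ringing the contact at
  4.5–5.5 mm whose connection flips between participants: a dense
  outcome-null fibre field that the discriminative statistics must reject;
* one **far bundle** that is never recruited.

Each bundle endpoint gets a 4 mm spherical parcellation label.

**Electrodes** are placed at the nominal per-hemisphere target plus
isotropic Gaussian jitter (default sd 1 mm; out-of-bounds draws are
resampled, at most 100 times).  Chronic settings mirror the trial's
titration protocol: amplitude on a 0.1 V grid, normal around the 4.5 V
target (sd 0.45, clipped to 3.5–5.6 V), pulse width 90 µs with an
occasional 120 µs, 130 Hz, a second active contact in about half of
participants, settings symmetric across hemispheres.  A continuous
amplitude distribution matters: discrete amplitude levels cluster
recruitment into groups and destroy rank-identifiability at n = 10.

**Ground-truth recruitment** is the fraction of response-bundle fibres
encompassed by the participant's right-hemisphere VAT.  Trajectories
follow a piecewise-linear accrual in time-on-stimulation: the blinded
effect over the first 90 days, the remainder to the open-phase maximum
over the next 160 days, then plateau — so both arms plateau before the CBT
course; the sham arm starts accruing only at the open phase (day 120).
The CBT effect ramps in over 60 days from day 400 and is not scaled by
recruitment (a therapy effect, not a field effect).  Scores are clamped to
instrument ranges (YBOCS 0–40, MADRS 0–60).  Assessment dates scatter ±5
days per participant (the blinded-phase endpoint only backwards, so it
always precedes unblinding); only the pre-surgical baseline is a fixed
calendar anchor.  This scheduling scatter is what keeps the longitudinal
model's per-timepoint random intercept from absorbing common time trends
(see above).  All noise draws are recorded in the ground truth, and a
fixed seed reproduces every file bit-for-bit.

What the phantom does *not* emulate: brain anatomy, diffusion signal or
tractography error, registration/brainshift, tissue heterogeneity, rater
behaviour (scores are continuous, not integer), dropout processes (a
withdrawal must be specified explicitly).  Passing recovery tests
therefore show that the *statistical machinery* recovers a planted
geometric effect under trial-scale noise — not that the method would
behave identically on real imaging data.

## Validation experiments and their scale

The shipped experiments (also run by `scripts/acceptance.py`) use sizes
chosen to finish in minutes on one CPU:

* endpoint-table statistics: deterministic, n = 9;
* VAT vs closed-form sphere on a 40 mm cube;
* planted-effect recovery: 20 default cohorts; per cohort, Dice overlap of
  the selected top-5% fibre set with the planted bundle, and the LOOCV
  predicted-vs-empirical r with a 100-permutation null.  At n = 10 a
  single cohort's LOOCV r is a noisy quantity, so significance is judged
  at the ensemble level: the median observed r across cohorts against the
  95th percentile of the permutation distribution of that median
  (permutations aligned across cohorts).  Typical values: median Dice
  ≈ 0.6, median r ≈ 0.5 against a null threshold ≈ 0.2;
* null calibration: 100 cohorts with nothing planted; the mixed-model LRT
  p, a fibre-level t-test p and the LOOCV permutation p are checked for
  uniformity (Kolmogorov–Smirnov);
* mixed-model slope recovery: 100 cohorts with a planted −0.03 points/day
  linear trend at noise sd 2; bias of the mean estimate is ≈ 1%.

## Known limitations

* The inverse-square field is isotropic and homogeneous; absolute VAT
  volumes are simplistic by design.
* The Fisher-z spatial similarity is scale-invariant, so it reads
  recruitment only through *relative* mass contrast between
  outcome-relevant and background connectivity; cohorts whose profiles
  differ only in overall magnitude are invisible to it.
* With shared assessment dates the literal `(1|timepoint)` term makes the
  time-effect LRT conservative (see above); the generator avoids this, but
  users fitting data with a rigid shared schedule should prefer the
  random-slope variant or interpret the LRT as conservative.
* Mixed-model Wald tests on between-participant covariates (including ROI
  interactions) become anticonservative when true slope heterogeneity is
  present but unmodelled; the random-slope flag addresses this.
* At n ≈ 10 the leave-one-out correlation has a heavy-tailed permutation
  null (95th percentile ≈ 0.6) and a small-sample fold artifact; a single
  cohort's r should never be interpreted without its own permutation null.
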