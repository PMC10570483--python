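# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `msdyn`. It is the place where design decisions that were
genuinely open are explained in full.

## Background and scope

Resting-state EEG alternates between brief (~80–120 ms) periods during
which the scalp potential topography stays quasi-stable — microstates —
classically summarized by four template maps labeled A–D. The package
implements the standard analysis chain used to ask whether the temporal
dynamics of these maps differ between clinical groups (here: patients who
do or do not develop chronic pain after breast-cancer surgery, with pain
rated on the 11-point NRS and NRS 4–10 defining the high-pain group):

1. signal conditioning of 30-channel recordings;
2. polarity-invariant two-level modified k-means segmentation;
3. backfitting of group templates and temporal metrics
   (duration, occurrence, coverage, transition percentages);
4. normality-routed group comparisons with BH-FDR correction, mixed
   ANOVA, covariate-adjusted GLM, effect sizes, and metric–NRS
   correlations.

Because the clinical recordings themselves are not distributable, the
package ships a first-class synthetic cohort generator with planted
ground truth, so every stage is verifiable end to end.

## Segmentation model

**GFP and peak maps.** The global field power is the per-sample spatial
standard deviation (population SD across channels) of the common-average-
referenced data. Topographies are extracted at strict local maxima of the
GFP; peaks whose GFP exceeds `mean + 2·SD` of all peak GFP values (sample
SD) are excluded as likely artifacts. The bare `2·SD` threshold is
available via `peak_exclusion="2sd"` — the outlier rule is stated in the
field ambiguously ("two times the standard deviation"), and
`mean + 2·SD` is the standard outlier convention, so it is the default.
Peaks inside bad-segment masks are discarded.

**Modified k-means.** Topographic clustering must treat a map and its
sign-flipped copy as identical, because the polarity of a scalp
oscillation alternates within a stable topography. Each restart seeds
k = 4 centers by drawing maps without replacement, assigns every map to
the center of maximal |Pearson correlation| across channels, and updates
each center as the sign-aligned arithmetic mean of its members
(re-centered, re-normalized). Iteration stops when the assignment is
stable or the GEV gain falls below 1e-6 (hard cap 1000 iterations). One
hundred random restarts are run and the solution with the highest global
explained variance wins; the restart count follows the published
"100 iterations" protocol, read as restarts with the per-restart cap
exposed separately (`kmeans_max_iter`). Empty clusters are re-seeded from
the currently worst-fitted map. A first-principal-eigenvector center
update (`center_update="eigen"`), which maximizes the polarity-invariant
fit exactly, is available; on separated clusters the two updates agree to
numerical precision (tested).

**Fit diagnostics.** GEV = Σₜ (GFPₜ · corr(vₜ, a_{L(t)}))² / Σₜ GFPₜ².
The cross-validation criterion uses the residual topographic variance
σ̂² = Σₜ (vₜᵀvₜ − (a_{L(t)}ᵀvₜ)²) / (T·(C−1)) penalized by
((C−1)/(C−K−1))², with C channels and K templates; it is exactly zero on
noise-free data and grows monotonically with sensor noise (tested).

**Two levels and canonical labels.** Individual template sets (4 maps per
subject) are pooled and re-clustered; the group templates are labeled A–D
by the one-to-one assignment to canonical reference maps that maximizes
total polarity-invariant similarity (Hungarian assignment over the 4!
permutations via `linear_sum_assignment`); a mean matched similarity
below 0.5 triggers a non-canonical-solution warning.

**Backfitting and metrics.** Every unmasked sample is labeled with the
template of maximal |spatial correlation|; ties go to the lowest class
index and zero-variance samples inherit the nearest preceding valid
label. No temporal smoothing is applied by default (none is part of the
protocol being reproduced); `min_duration_ms` optionally absorbs runs
shorter than a threshold into their predecessor. Runs are maximal
constant-label stretches within unmasked spans; no run or transition is
ever counted across a mask boundary. Duration is the mean run length in
ms, occurrence the number of runs per unmasked second, coverage the
percentage of unmasked samples, and the 12 transition statistics are
joint percentages of all observed label changes (they sum to 100; this
matches how the reference results tabulate them, whose high-pain column
sums to ≈100). Boundary runs (touching the recording edge or a mask) are
included by default — the truncation bias is negligible at minutes-long
recordings — and can be excluded via `include_boundary_runs=False`,
which affects duration/occurrence only.

## Preprocessing

Filters are zero-phase 4th-order Butterworth applied forward-backward.
The high-pass (0.1 Hz) needs care: at corners this far below Nyquist the
filter's quadruple pole sits so close to the unit circle that the default
padding-based `filtfilt` start-up injects a slow transient that can
exceed the signal (a t³·e^(−t/τ) mode). The package therefore (i)
subtracts the exact channel mean first — an IIR high-pass only removes DC
asymptotically, with a settling time rivaling the recording length — and
(ii) applies the high-pass section-by-section with Gustafsson's
minimum-transient initial conditions. The 80 Hz low-pass and the 48–52 Hz
band-stop are well conditioned and use ordinary `sosfiltfilt`. Verified
behavior: DC in → ≈0 out; 10 Hz preserved within 5%; 150 Hz attenuated
>40 dB at 1 kHz sampling; a pure 50 Hz tone leaves <3% residual.

Resampling is polyphase (`resample_poly`, downsampling only), with
annotations rescaled. Re-referencing subtracts the averaged mastoids and
drops M1/M2 from the scalp set; before all topographic analysis the data
are additionally common-average referenced (standard in the microstate
literature; spatial correlation mean-centers maps anyway, so this is
inert for labeling but fixes the GFP definition). Bad channels are
replaced by the inverse-distance-weighted mean of the 4 nearest good
channels in the 2-D montage (spherical splines would be the
higher-fidelity alternative but are unnecessary for the synthetic
montage); more than three bad channels excludes the subject, which the
pipeline logs and tolerates. Bad segments are merged into a mask and
never spliced out, so sample indices stay aligned with ground truth.
ICA-based artifact removal is out of scope: the synthetic inputs contain
no ocular or muscle artifacts, and contaminated stretches enter as
annotations.

## Synthetic cohort generator

The generator emulates 5-minute eyes-closed, 30-channel, 500 Hz
resting-state recordings of a 21 high-pain / 45 low-pain cohort. It is
the study-condition definition, not a tuning knob; all defaults below are
fixed.

**Montage and canonical maps.** A 30-channel 10–20 layout (32-channel cap
minus the mastoid references) with schematic head-circle coordinates.
The four canonical maps are built from the electrode geometry: A and B
are the two mirrored diagonal gradients, C an anterior–posterior gradient
with a radial (posterior-emphasizing) component, D a fronto-central
Gaussian extremum; all zero-mean, unit-norm, pairwise |correlation|
≤ 0.59.

**State dynamics.** Labels follow a semi-Markov process: stable-period
durations are gamma distributed with shape 4 and subject-specific mean
(cohort mean 100 ms, between-subject SD 10 ms) — squarely inside the
80–120 ms range the literature reports — and successor states follow a
zero-diagonal row-stochastic matrix, uniform (1/3) at baseline.

**Planted group effect.** Each subject carries a log-bias b on all
transition entries into class C (entries scaled by e^b, rows
renormalized); with the uniform base matrix the embedded-chain stationary
share of C has the closed form π_C = e^b/(2e^b + 2). Low-pain subjects
draw b ~ N(0, 0.33); high-pain subjects draw b ~ N(β, 0.33). β is solved
deterministically (Gauss–Hermite quadrature over the subject-level
distributions plus Brent's method) so that the standardized group
difference in MS-C occurrence (π_C/mean-duration) equals the configured
effect size, default d = 0.88 — the published effect for MS-C occurrence.
The bias SD 0.33 reproduces the published within-group occurrence CV
(~19%). Planting the effect on the transition matrix (rather than adding
shifts to metrics post hoc) makes occurrence, coverage, and
transition-percentage effects co-occur, as they do in the reference
results. A 200-replicate Monte Carlo recovers mean realized d = 0.885.

**Rendering.** signal(t) = s_r · env(t) · m_{L(t)} where env is a floor
(0.3) plus rectified 10 Hz carrier (alpha, plausible for eyes-closed
rest) — strictly positive, so every sample carries its topography and
noiseless backfitting is exact — and s_r is a random ±1 polarity per
stable run. The polarity factor matters: without it the always-positive
envelope gives the signal a fixed nonzero temporal mean (a mixture-of-
templates "DC topography") that any AC-coupled filter subtracts, tilting
every map; real scalp oscillations alternate sign, which is precisely why
the analysis disregards polarity. White sensor noise is scaled so the
realized RMS(signal)/RMS(noise) equals the configured amplitude SNR
exactly (default 5). Amplitudes are arbitrary units: only topography
shape matters to the analysis, and no amplitude scale is being
reproduced.

**Pain ratings and covariates.** NRS values are drawn per group from
decreasing integer distributions (4–10 for high-pain, 0–3 for low-pain)
and assigned to subjects by rank of their true C coverage plus rank-
breaking noise of 1.5× the within-group coverage SD; that link strength
was chosen by a design-time Monte Carlo to put the cohort-level Spearman
correlation between C coverage and NRS at ≈0.6 (replicate mean 0.614,
SD 0.08), the magnitude reported for the real cohort. The exact
correlation is not guaranteed per cohort. Age, BMI, education, BDI-II,
ASA, surgery type, ALND and chemotherapy flags are drawn independently
to match the published group margins; they are *not* confounded with the
EEG by construction (confounded designs are built explicitly in the GLM
tests).

**What the generator does not emulate.** No ocular/muscle/electrode
artifacts, no volume-conduction forward model, no 1/f background or
spatially correlated noise, no eyes-open condition, and no genuine
covariate–EEG confounding. Passing tests therefore demonstrate that the
algorithms are correct and calibrated under the stated generative
assumptions — not that real recordings of this population would yield
the published group differences.

## Statistics

Each continuous comparison is routed by per-group Shapiro–Wilk tests at
α = .05 (per-group is the stricter convention; the protocol does not
specify) to a pooled-variance Student t-test or, on any rejection, a
Mann–Whitney U test with the tie-corrected normal approximation. Welch's
t is available by configuration. Cohen's d (pooled SD, high-pain minus
low-pain) is always reported. Categorical tables use Pearson chi-square
without continuity correction — this choice reproduces the published
demographic p values (.041 for surgery type, .011 for ALND) from their
printed counts, which the Yates-corrected statistic does not.

BH-FDR families follow the number of corrected p values reported per
table: the four classes of each temporal parameter form one family, the
twelve transition statistics another. The mixed ANOVA (group between ×
class within) comes from `pingouin`; note that coverage is compositional
(each subject's four values sum to 100), so its between-subject variance
is structurally zero and the between-group main effect for coverage is
undefined (0/0) — the interaction, which carries the scientific content,
is unaffected. The covariate-adjusted sensitivity analysis is a Gaussian
identity-link linear model of each primary metric on the group indicator
plus age, surgery type, BDI-II, and ALND; constant covariates are
dropped (they carry no information and would only make the design
singular), and non-estimable fits on very small cohorts are skipped with
a log message. Analytic power for the pooled t-test uses the noncentral
t distribution (d = 0.88 at n = 21/45 gives 0.907).

## Problem sizes used in the test suite

All simulations are seeded and bit-reproducible (identical seed + config
⇒ byte-identical outputs, tested). The suite runs the study-scale designs
at reduced recording lengths, chosen so every check retains its power
while the whole suite stays interactive: unit fixtures use 6 subjects ×
20 s; the SNR-5 recovery check uses 20 subjects × 60 s with the full 100
k-means restarts; the type-I-error calibration runs 200 null cohorts of
10+10 subjects × 30 s with 20 restarts (the synthetic peak maps are well
separated, and restarts beyond ~10 never change the solution there); the
effect-size/power/correlation recovery uses 200 replicate 21/45 cohorts
at generative-truth level. Renewal-sampling attenuation of the planted
effect at 30–60 s recordings is under 4% and does not bias any of the
stated tolerances.

## Known limitations

* EDF files can be read (through `mne`, optional) but not written; the
  round-trip on-disk format is the delimited channel matrix with JSON
  sidecar.
* The GLM sensitivity analysis needs enough residual degrees of freedom;
  on cohorts of fewer than ~10 subjects it is skipped.
* Bad-channel interpolation uses planar inverse-distance weighting, not
  spherical splines.
* k is fixed at 4; no meta-criterion for the number of classes, no
  microstate syntax/entropy analyses, no source localization.
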