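# Methods

This note documents the models, generators, numerical choices and known
limitations of `pescale`. All empirical statements below are computed by the
test suite or by `scripts/acceptance.py`.

## Experimental design generator

The paradigm is a probabilistic cue–image design. A `StimulusSet` is 8
stimuli (4 animate, 4 inanimate), each paired with a unique consonant cue;
vowels are reserved for no-go trials and are never associated with a
stimulus. The per-run transition matrix puts 7 trials in each cue's paired
(expected) cell and 1 in each of the 56 unexpected cells, so a main run has
112 go trials (56 expected + 56 unexpected) plus 16 no-go trials = 128.
Cue reliability is exactly 7/14 = 0.5, and each image appears 14 times per
run, ruling out stimulus-frequency confounds by construction. Behavioral
blocks triple the expected repetitions (21 per pair) and double the no-go
count (256 trials). The localizer presents each intact image in 4 and each
phase-scrambled image in 2 miniblocks (48 blocks of 12 s, 15 cycles of
800 ms each, one brightness-target cycle drawn uniformly from cycles 4–13).

Intertrial intervals follow an offset exponential truncated to a range
(main task: mean 5 s, range 3–12 s; behavioral blocks: mean 2.5 s, range
1.5–7.5 s). Truncation is implemented by re-sampling out-of-range draws
rather than clipping — clipping would put probability atoms on the
boundaries and bias the mean — and the exponential scale is solved
numerically (Brent's method) so the *truncated* mean hits the target:
E[Y | Y ≤ U] = s − U/(e^{U/s} − 1) for Y ~ Exp(s). Trial order is drawn by
shuffling with local repair of adjacent same-(cue, image) repetitions;
whole-sequence rejection is hopeless for behavioral blocks, where each
expected pair appears 21 times in 256 trials and the no-adjacent-repeat
probability under a uniform shuffle is of order e^{−13}. No-go trials pair
a uniformly drawn vowel with a uniformly drawn image (the design source
gives no balancing rule; uniform sampling is the neutral choice). Onsets are
continuous seconds (image onsets; the 500 ms cue precedes each image and is
not modeled); the GLM convolves on a 16× oversampled grid, so onsets need
not sit on the repetition-time grid.

## Feature models and surprise

A feature model assigns each stimulus a feature vector; its RDM holds
pairwise correlation distances 1 − r ∈ [0, 2]. RDMs of several model
instances are averaged element-wise to suppress instance-specific structure.
Trial-wise surprise on an unexpected trial is the RDM entry between the
cue-predicted and the seen image, z-scored across the subject's unexpected
trials using the population standard deviation (denominator n) — the
standard convention for parametric modulators, and the one under which two
raw values {0.4, 0.8} map to z = {−1, +1}. A feature model whose surprise is
constant across trials cannot be z-scored and is rejected upstream.

Stimulus-set optimization mirrors the original selection procedure: among
random admissible 4-animate + 4-inanimate subsets of a larger pool, choose
the one maximizing

var(low-layer RDM triangle) + var(high-layer RDM triangle) − |r(low, high)|.

The scalarization (unit weights, additive) and the candidate count are this
package's choices; the selection's purpose — detectable within-layer RDM
structure with minimal across-layer correlation — only requires a
reproducible argmax, not a particular optimizer. Pearson correlation is used
for the cross-layer term because the variance terms are already
moment-based. Pool screening removes category outliers by agglomerative
clustering of high-layer features (average linkage, correlation distance,
cut at k = number of categories); a stimulus is flagged when it is the sole
exemplar of its category outside that category's modal cluster. Linkage and
cut height are unstated in the source and therefore configurable; the
default rule is deliberately conservative (a category with two exemplars in
a foreign cluster is not "an outlier", it is a mislabeled category).

## Synthetic data with planted ground truth

`synth_feature_hierarchy` draws two independent latent stimulus factor
matrices ("low" and "high", 6 factors each) and builds layer *l* features as
(1 − w_l)·(low @ P) + w_l·(high @ P′) + noise, with a monotone mixing
schedule w rising from 0 (layer 1) to 1 (layer 8) and per-instance random
projections (default 50 features). This reproduces the two properties the
pipeline relies on: adjacent-layer RDMs correlate more than distant ones,
and instance-averaged RDMs approach the latent geometry. The untrained-
network control is an independently seeded hierarchy. Synthetic word
embeddings carry a shared animacy-aligned component (weight 0.2, 50
dimensions) under dominant word-specific structure, so the semantic RDM
correlates moderately — not degenerately — with the animacy split, as real
distributional embeddings do; this keeps the word and animacy parametric
modulators distinguishable in the GLM, mirroring the reported collinearity
diagnostics (all VIF < 5).

`synth_bold` builds voxel time series as HRF-convolved 500 ms boxcars with
per-trial amplitude baseline + Σ_m slope_m · z_m(trial), plus optional
low-frequency drift (random cosines entirely below the 1/128 Hz cutoff, so
the high-pass filter removes them — property-tested) and Gaussian noise
(optional AR(1)). The default grid is 20×20×10 voxels at a nominal 2 mm —
large enough for 6 mm searchlights, small enough for seconds-scale tests —
with the x axis split into four planted populations: `high_scaling` (layer-8
slope), `low_scaling` (layer-2 slope), `null` (stimulus-responsive, no
scaling) and `non_selective`. Ground truth is recorded on the run, so every
downstream estimate is checkable by parameter recovery: the GLM recovers
planted slopes exactly (relative error < 1e−6) at zero noise.

The localizer generator plants per-stimulus additive patterns in selective
voxels; scrambled miniblocks evoke a reduced baseline and no pattern, so the
intact-minus-scrambled contrast isolates object-selective populations and
8-way identity decoding rises to 1 as noise → 0 and falls to 1/8 as noise
dominates. Behavioral responses are Gaussian RTs per condition (defaults
501 / 509 / 524 ms for expected / unexpected-same / unexpected-different,
within-subject SD 90 ms, truncated at zero by resampling) with Bernoulli
errors (2% / 3% / 6%, keeping overall accuracy above 95%) and a 3% no-go
false-alarm rate; the RT means are the reported group means of the paradigm
and the dispersion/error levels are realistic choices for a speeded
two-alternative task.

For group-level power and type-I simulations, `synth_trial_betas` generates
per-trial response amplitudes directly (baseline + slope·z + noise) — the
quantity the single-trial estimation stage recovers — so a 200-replicate,
33-subject simulation runs in seconds. The BOLD-level path (synth → GLM/LSS)
is verified separately, noise-free and at pipeline scale; re-fitting volumes
inside every replicate would test the same estimator identities repeatedly.
In these simulations each subject contributes 8 runs × 56 = 448 unexpected
trials and the noise SD is set to σ = slope·√(1/r² − 1) with r = 0.1, i.e.,
per-subject beta–surprise correlations around 0.1 — a realistically weak
single-trial effect for this kind of ROI analysis.

## First-level GLM

Condition regressors (expected, unexpected, no-go) are 500 ms boxcars
convolved with a canonical double-gamma HRF (response peak 6 s, undershoot
16 s, ratio 6, peak-normalized; all parameters configurable — exact
double-gamma conventions differ between packages) on a 16× oversampled grid
and sampled at the TR. Each parametric modulator is the unexpected-trial
boxcar weighted by that trial's z value, convolved identically. Modulators
are z-scored but *not* serially orthogonalized against the condition
regressors: shared variance is discarded rather than attributed, which is
the interpretation the analysis depends on. Z-scoring is per run (the
natural unit here, where each run realizes the full transition matrix).
First-order temporal derivatives (of conditions and modulators) and nuisance
series (6 motion parameters, framewise displacement, CSF, WM — synthesized
as slow AR(1) processes when no real confounds are supplied) complete the
design. High-pass filtering projects out a discrete-cosine basis with
periods above 128 s (mean removed and recorded); filtering then fitting is
numerically identical to appending the basis as nuisance (tested). Spatial
smoothing is Gaussian (σ = fwhm/2.3548 per axis) with mask-aware
renormalization so flat signal stays flat at mask edges.

Estimation is ordinary least squares per voxel, with an optional AR(1)
Cochrane–Orcutt pass in place of full local autocorrelation prewhitening;
at the group level, inference across subjects is robust to run-level
whitening at this scale, and OLS keeps every estimator identity exactly
testable. Runs combine by inverse-variance fixed effects
(v = 1/Σ 1/v_i). Contrast t statistics map to z scores by matching tail
probabilities at the fit's degrees of freedom. VIFs are computed per
regressor as 1/(1 − R²) after mean-centering, with perfect collinearity
reported as infinity. Group tests are one-sample t (Cohen's d_z) or Wilcoxon
signed-rank (matched-pairs rank-biserial r); two-sided p values throughout.
Cluster-level familywise error uses sign-flip permutation of subject maps
(26-connectivity, default formation threshold |z| ≥ 3.29, max-cluster-extent
null) instead of Gaussian-random-field theory: it is assumption-free and its
calibration is verifiable by simulation, which the test suite does.
Benjamini–Hochberg is used wherever results tables are FDR-corrected, and
nonsignificant one-sample results get a default-prior (JZS, Cauchy scale
0.707) Bayes factor.

## Single-trial estimation (LSS)

Each go trial gets its own GLM: a regressor for the trial of interest, one
regressor per image identity collecting that image's remaining trials
("split by image identity", regardless of expectation status), a no-go
regressor, and nuisance. Temporal derivatives are omitted from the LSS
iterations by default (configurable); the source lists them only for the
main GLM. On designs spaced beyond the HRF support, LSS equals the
least-squares-all oracle to machine precision, and the mean LSS beta per
image approaches that image's condition beta; both are asserted in tests.
No-go trials are never trials of interest.

## Searchlight RSA

Searchlights are all in-mask voxels within a Euclidean radius (default 6 mm;
123 voxels at 2 mm isotropic deep in the mask), clipped to the mask. Neural
RDMs are cosine distances between per-voxel z-scored stimulus patterns
(z-scoring absorbs voxel-wise affine scaling). Model comparison uses
Kendall's tau-a on the lower triangles — the RSA-field convention when
candidate models may predict tied dissimilarities (the animacy RDM is
binary); tau-b is available by flag. Fisher z = atanh(tau) feeds one-sample
t tests across subjects; |tau| = 1 is clamped at 1 − 1e−12 before the
transform. Best-layer maps take, per searchlight, the layer with the largest
group-mean Fisher z, break ties toward the earlier layer, and unlabel
centers whose winning layer fails the group threshold (display default
z ≥ 3.1).

## Surprise-scaling analysis

ROIs are anatomical masks, Gaussian-dilated (3 mm), with overlapping voxels
assigned to the smaller mask, then reduced to the k most informative voxels
(default k = 200; k sweeps 100–500 supported) by localizer decoding
accuracy — never by main-task data, which would bias selection. Alternative
rules: `stimulus_driven` (localizer z ≥ 3.1) and `bottom_k_decoding`
(uninformative-voxel control ROIs). Scaling regression fits, per subject,
OLS of the ROI-mean (or per-voxel) unexpected-trial betas on z-scored
surprise, reporting the group one-sample t on slopes and the mean
per-subject Pearson r; a joint multi-modulator variant regresses on all
models simultaneously so shared variance is discarded (partial slopes). The
prediction-error best-layer map runs one single-layer regression per layer
per voxel and labels each voxel with the layer of largest R² — deliberately
*not* a joint 8-layer model, because neighboring layers' surprise vectors
correlate strongly and a joint fit would be uninterpretable under that
collinearity — thresholded liberally (z ≥ 1.96) at the group level with
optional extra 3 mm smoothing. The source describes 5 mm followed by 3 mm
smoothing as "8 mm total"; Gaussian widths compose in quadrature (√34 ≈
5.8 mm), so the sequential operation is implemented as stated and the
nominal label left to the caller.

## Decoding

Linear SVMs (C = 1, one-vs-one) decode the 8 image identities. Searchlight
decoding of localizer single-trial patterns under stratified 4-fold
cross-validation produces the informativeness map for ROI selection. For the
probability analysis, the decoder is trained on the prediction-free
localizer patterns with pairwise-coupled Platt calibration, evaluated on
main-task unexpected-trial patterns, and the true-class probability is
regressed per subject on z-scored high-level surprise; a decoder emitting
uniform probabilities yields exactly 1/8 = 0.125 per trial and slope 0. The
calibration method matters for the slopes and is therefore fixed and
recorded. Expected-vs-unexpected identity decoding averages single-trial
estimates per (object, expectation condition, run) before testing.

## Behavioral statistics

Go trials with RT < 100 ms or > 1,500 ms are excluded (boundary values
retained: the exclusion rules are written as strict inequalities); only
correct responses enter the RT analysis. Unexpected trials split by animacy
agreement with the cue-predicted image into same/different button press.
One-way repeated-measures ANOVAs (3 levels) apply the Greenhouse–Geisser
correction whenever ε < 1 (uniformly — no Huynh–Feldt switch above
ε = 0.75, since the trigger rule is unstated), reporting partial η².
Post-hoc paired t tests are Holm–Bonferroni corrected with Cohen's d_z.
Within-subject CIs use Cousineau normalization (subtract subject mean, add
grand mean) with the Morey bias correction C/(C − 1); condition means are
unchanged by the normalization and pure subject offsets produce zero-width
intervals (both tested). Subject exclusion applies a directional 2-SD rule
per quality metric (higher-is-worse for FD, FD%, DVARS, RT;
lower-is-worse for tSNR, accuracy).

## Pipeline, formats, reproducibility

Events are BIDS-style TSV (onset/duration in seconds); volumes are NIfTI
with the TR in the header; RDMs are labeled square TSV; configs are YAML
with explicit per-stage seeds (design, features, bold, behavior, analysis) —
no hidden defaults. `run_pipeline` simulates N subjects end-to-end (default
demo scale: 12×10×8 voxel grid, 1 run, one ROI per planted population) and
writes a manifest of SHA-256 content hashes; identical configs produce
byte-identical outputs (tested). Voxel indices are 0-based internally; the
affine carries the nominal voxel size.

## Problem sizes used in tests

Unit and acceptance tests run on reduced volumes (hundreds to a few thousand
voxels), 1 to 8 runs and 2 to 33 synthetic subjects; statistical
calibration checks use 200–500 replicates at the beta level and 60–100
replicates for permutation-based cluster inference. These sizes are chosen
so the full suite exercises every estimator at meaningful SNR in about a
minute on one CPU.

## What the synthetic generator does and does not emulate

It emulates: the transition structure and trial counts; partially correlated
layer RDM hierarchies; linear surprise scaling of unexpected-trial
amplitudes in designated populations; stimulus-selective localizer patterns
with an intact > scrambled contrast; low-frequency drift below the high-pass
cutoff; white or AR(1) noise; condition-ordered RTs and error rates. It does
not emulate: biophysical BOLD nonlinearities, motion and susceptibility
artifacts, spatially correlated physiological noise, hemodynamic
variability across voxels, or real network activations — so passing tests
demonstrate that the *analysis chain* is correct and calibrated under the
stated generative model, not that the scientific result holds in new human
data. Group statistics measured on human recordings are not reproduction
targets at desk scale; what is reproduced is the arithmetic of the design,
the collinearity diagnostics (all VIF < 5), the estimator identities, the
error-rate calibration, and the qualitative
feedforward-vs-prediction-error layer dissociation.

## Known limitations

- OLS (optionally AR(1)) in place of full prewhitening slightly mis-weights
  run-level variances under strong autocorrelation; group inference is the
  acceptance surface and is unaffected at the scales tested.
- Sign-flip permutation assumes symmetric subject-level error distributions
  under the null.
- The LSS ≈ LSA identity holds exactly only for designs spaced beyond the
  HRF support; at realistic trial densities LSS is a biased but
  variance-favorable estimator, as in practice.
- The stimulus-subset search is random sampling, not exhaustive; with unit
  score weights the cross-layer correlation term dominates only when layer
  RDM variances are of comparable magnitude.
- Bayes factors use the default JZS prior; other priors change BF₁₀
  materially near t = 0.
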