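# Methods

This note records the models, parameter choices and numerical conventions
behind `dvpclust`, and what the synthetic experiments do and do not show.

## Synthetic pulse model

Each beat is a sum of Gaussian components on the unit pulse duration: a
systolic wave, a reflected wave, a diastolic wave, and a negative Gaussian
"notch well" centred between the reflected and diastolic components.  The
four canonical morphology classes differ in diastolic amplitude
(0.48 / 0.32 / 0.20 / 0) and notch depth (0.18 / 0.10 / 0.06 / 0), with
centres and widths drifting later/wider from class 1 to 4; class 4 is a
pure single Gaussian (no reflected or diastolic component).  Parameters
were hand-tuned so the rendered classes show the canonical gradient — a
clearly marked notch plus diastolic peak in class 1, a single broad wave in
class 4 — and so that the four classes are separable in DDTW space: with
zero noise, every rendered pulse across the age range and the raw-length
range is nearest (by DDTW) to its own class template.  That separability is
a design requirement: it makes the clustering-recovery experiments
well-posed.

**Age coupling.** A subject's vascular age scales the reflected/diastolic
amplitudes and the notch depth down linearly (to 0.85 of nominal at age 83)
and widens the systolic wave (by up to 10%), reproducing the known
attenuation of the diastolic wave with age.  Class membership is drawn from
the configured mixture tilted logistically in standardized age (slopes
−1.2 … +1.2 across classes at the default coupling strength), so older
subjects favour classes 3–4; the tilt is mean-corrected so the class
*marginal* stays close to the configured mixture.  The strength of both
couplings is a free modelling choice (no quantitative class-prevalence-by-
age data exist); both are exposed in the configuration.

**Noise.** Additive Gaussian noise is band-limited: white noise filtered
with a Gaussian kernel (σ = 3 samples) and rescaled to the configured
marginal standard deviation (default 0.02 in template amplitude units).
Pulse-oximeter front ends remove broadband sensor noise before beats are
segmented, so the perturbations a recorded beat actually carries — baseline
movement, beat-to-beat morphological variability — are smooth on the
sample grid.  White per-sample noise would instead dominate the
derivative-domain (DDTW) geometry, which no filtered physiological signal
does.  Raw beat lengths are drawn uniformly from 60–140 samples purely to
exercise the resampling path; only the normalized 100-sample form matters
downstream.

**Covariates.** Age, weight, height, BMI and BPM are drawn from truncated
normals whose *truncated* mean and standard deviation match the target
cohort summary statistics (the underlying location/scale are solved
numerically; naive truncation would bias, e.g., the age mean upward by more
than one year).  PWV is affine in age (slope 0.15 m/s per year, residual
SD 1.96) clipped to its physiological range, with the intercept corrected
for the expected clipping bias; PAS and PAD are affine in age (slopes 0.5
and 0.3 mmHg/year).  Transit time is path_length / PWV (path length 1 m,
in ms) with 5% multiplicative noise — stiffer arteries, shorter transit
time.  BMI is drawn independently of weight and height, matching the
reported marginals rather than enforcing the algebraic identity.

What the generator does **not** emulate: continuous multi-beat recordings,
beat segmentation, motion artefacts, arrhythmic or pathological beat
morphologies, within-subject beat-to-beat covariate variation, or any
dependence structure among covariates beyond the age couplings.  Passing
recovery tests on this data shows the pipeline is correct and sensitive at
realistic separations; it does not show that real DVP datasets contain
four clusters.

## Preprocessing

Beats are resampled to 100 points by linear interpolation over the pulse
duration, then min-max scaled to [0, 1] (resample → scale; the reverse
order would differ only through interpolation extremes).  Z-normalization
uses the population (ddof = 0) standard deviation.  Splitting is at the
pulse level — 30% test, then 30% of the remainder as validation — matching
the protocol it reproduces; pulse-level splitting lets one subject
contribute to several partitions and is therefore leakage-prone, which is
accepted deliberately for protocol fidelity.

## Handcrafted features

Fiducial detection: systolic peak = global maximum; onset = pre-systolic
minimum; maximum downslope = most negative first derivative after the
systolic peak; dicrotic notch = first local minimum of the pulse after the
maximum downslope, falling back to the most negative local minimum of the
first derivative (a decelerating-then-steepening shoulder) when no true
minimum develops; diastolic peak = first local maximum after the notch.
Absence is encoded, never raised: DDR reports the sentinel 1.1 when no
diastolic point exists (the notch of a class-1 pulse can be the global
minimum of the normalized beat, making DDR exactly 0 — a valid value).

Numerical conventions: peak counting uses prominence 0.02 in normalized
amplitude; rise time is floored at one sample before the log; kurtosis is
Pearson (excess + 3, strictly positive) before the log; the downslope
derivative variance is floored at 1e−8; skewness/kurtosis are computed over
the 100 amplitudes as a sample (time-weighted alternatives were rejected
for simplicity).  The reflected-wave flag (AI_bin) is 1 when the first
derivative has a prominent local maximum between the systolic peak and the
notch — the signature of a secondary systolic wave.  Standardization (zero
mean, unit variance per feature) is always fitted on the training partition
and applied everywhere; a zero-variance training column is an error naming
the column.

## DDTW

The derivative estimator is
d[i] = ((x[i] − x[i−1]) + (x[i+1] − x[i−1])/2)/2 with endpoint replication
— the standard form for derivative-domain warping; it is pluggable.  Pulses
are z-normalized *before* differentiation.  The dynamic program uses cell
cost |s_i − t_j|, the three-move recurrence, no step weights and no path
normalization (the raw cumulative cost is returned; some DTW variants
normalize by path length — this one deliberately does not).  The
Sakoe–Chiba band is |i − j| ≤ w in samples on the derivative grid, default
w = 20; a band narrower than the length difference is an error.  DTW is not
a metric (no triangle inequality is asserted anywhere).  Pairwise matrices
are filled in row-major upper-triangle order; the inner dynamic program is
JIT-compiled.

## K-medoids

PAM: greedy BUILD initialization followed by full SWAP scans, taking the
best improving medoid/non-medoid exchange until none exists; the objective
(sum of dissimilarities to the own medoid) is asserted non-increasing at
every swap.  Ties break toward the lowest index, and medoids are reported
in ascending dataset order, so results are deterministic given the input
order and invariant (as partitions) under input permutation.  Template
mode performs a single nearest-template assignment pass — with fixed
medoids there is nothing further to update — with an optional refine flag
that re-medoids the template-seeded clusters within the dataset.  Inertia
is reported as the *mean* squared distance to the own medoid by default so
that values are comparable across representations with different distance
scales; the raw sum is available.  Feature-space clustering uses Euclidean
distances (not squared), consistent with treating the inputs as
dissimilarities.

## Model selection

Silhouette excludes the sample itself from its own-cluster mean; members of
singleton clusters score 0.  Prediction strength counts ordered pairs
(i ≠ i′), consistent with the n(n−1) normalizer; test clusters with at most
one member contribute 1 (the 1/(n(n−1)) factor is undefined there).
ps(1) = 1 identically.  The prediction-strength split is a seeded half/half
partition of the input.  The scan covers k = 1..15 by default; silhouette
is undefined at k = 1 (and degenerate at k = n) and recorded as NaN there.
The joint rule — silhouette argmax among prediction-strength-feasible k
(threshold 0.7, configurable; curves without ps are unconstrained), ties
toward the inertia elbow (maximum perpendicular distance to the endpoint
chord on the normalized curve) — returns a *recommendation*; the curves are
the primary output, because the final choice of k always retains a
subjective component.  Prediction strength for the DDTW representation is
implemented but off by default in the pipeline (it doubles the number of
PAM fits; on precomputed matrices it is available behind the
`compute_ps` opt-in).

## Clinical relevance

Quantile functions are evaluated at midpoint probabilities
(q − 0.5)/Q, Q = 100, by linear interpolation of the order statistics.  The
default pair distance is the mean absolute quantile gap — the 1-Wasserstein
distance between the empirical distributions — with an RMS variant behind a
flag; both coincide on point-mass examples, and both are exactly
shift-sensitive (shifting one sample by c changes the distance by |c|),
which is the point: a cluster of uniformly older subjects must register as
different.  Covariates are min-max normalized over the full dataset before
distance computation (making d comparable across covariates); raw-scale
mode is available and is positively homogeneous.  The weighted average
d = 1/(k(k−1)) Σᵢ wᵢ Σ_{j≠i} wⱼ dist(i, j) with wₙ = Nₙ/N down-weights tiny
clusters; weights always sum to 1, and d is invariant to cluster
relabeling.  With linear-interpolated quantiles, duplicating every sample
changes d only at O(1/n) (the weights are exactly invariant).  Hypothesis
testing: Kruskal–Wallis per covariate across clusters of size ≥ 2; only
where it rejects at α = 0.05 are pairwise Welch t-tests run, with Holm
adjustment (no adjustment procedure was prescribed; Holm controls FWER
without independence assumptions).

## Autoencoder

Geometry (encoder): 100 → conv(32)/pool ×3 → 13×32 → flatten(416) →
dense(8).  Decoder: dense(416) → reshape(13, 32) → stride-2 transposed
convolution (realized as zero-interleaving + same convolution) to 26 →
crop to 25 → upsample/conv to 50 → upsample/conv to 100 → flatten(3200) →
dense(100) with a sigmoid, so reconstructions live in (0, 1) like the
input.  Activations: ReLU inside convolutional layers; the latent dense
layer is linear (a ReLU bottleneck would silence latent dimensions at no
benefit); the reconstruction layer sigmoid.  Kernel size 3, stride 1, same
padding, pool/upsample factor 2 — unstated in the source architecture and
fixed here as the smallest standard choice.

Training: Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e−3, batch size 32,
L2 penalty λ = 1e−4 on weights (not biases), at most 200 epochs with
early stopping on validation MSE (patience 10) and best-weights restore;
initialization is Glorot-uniform from the configured seed, so training is
bit-deterministic.  A hyperparameter search was deliberately not included —
the fixed defaults above are configuration, not method.  The latent size 8
is the published bottleneck.  The whole stack is plain NumPy with explicit
backward passes, verified against finite differences in the test suite;
at 100-sample inputs a full training run on ~1,000 pulses takes well under
a minute on one CPU.

## Problem sizes used in the shipped experiments

The recovery experiments run on 400-pulse cohorts (one pulse per subject,
uniform class mixture), the autoencoder quality check on 1,000 clean
pulses, and covariate moment recovery on 10,000 draws.  These sizes give
overwhelming statistical power for every planted effect (e.g., the
quantile-distance permutation check wins 100/100 replicates) while keeping
a full test-plus-reproduction cycle within a couple of minutes; the
pipeline itself has no size-dependent logic and scales to cohorts of
~10,000 beats, where the pairwise DDTW matrix (≈50M banded alignments)
becomes the dominant cost.

## Known limitations

* The four-class generator is a stylized model: real DVP shape variation is
  continuous and multi-factorial, and the clean class structure planted
  here is the *best case* for cluster recovery.
* Pulse-level splitting leaks subject identity across partitions (kept for
  protocol fidelity).
* DDTW costs are raw cumulative costs; comparing inertia values across
  representations relies on the mean convention, not on any common scale.
* The sentinel DDR = 1.1 mixes a ratio scale with a flag value; downstream
  standardization treats it as just another number, as intended by the
  feature's definition.
* BMI is generated marginally and is inconsistent with weight/height at
  the subject level.
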