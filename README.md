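# dvpclust

Unsupervised clustering of photoplethysmogram (PPG) pulse-wave shapes, with
tools to test whether the resulting clusters are clinically meaningful.

## The problem

The digital volume pulse (DVP) — one cardiac cycle of a PPG recording —
changes shape with age, blood pressure and arterial stiffness.  Pulse
shapes are traditionally sorted into four classes by the prominence of the
dicrotic notch, from a clearly marked notch with a distinct diastolic wave
(class 1) to a single broad wave with no visible notch (class 4).  Real
recordings are harder: many pulses sit between classes, and there is no a
priori reason the number of natural shape classes is four.  `dvpclust`
treats this as a cluster-analysis problem: embed single beats in a shape
space, cluster them without labels, select the number of clusters from the
data, and score each clustering by how well it separates clinical
covariates.

## What it implements

**Representations.** Each beat, normalized to 100 samples in [0, 1], is
represented three ways:

1. *Handcrafted morphology features* — 14 fiducial-point and statistical
   features (notch/diastolic amplitude ratio DDR, downslope areas and
   derivative moments, second-derivative landmark amplitudes/indices,
   skewness, log-kurtosis, rise time, peak count, a reflected-wave flag);
2. *Derivative dynamic time warping (DDTW)* — pairwise alignment costs
   between z-normalized, derivative-transformed beats under a Sakoe–Chiba
   band (|i − j| ≤ w, default w = 20), so beats are compared by the timing
   of their morphological events rather than raw amplitudes;
3. *Convolutional-autoencoder latents* — an 8-dimensional code from a 1-D
   CNN autoencoder (three conv/pool encoder stages, mirrored decoder)
   trained to reconstruct beats under MSE + L2 loss.

**Clustering.** K-medoids (PAM, BUILD + SWAP) on the feature space or the
precomputed dissimilarity matrix, in three modes: `template` (medoids fixed
at the four canonical notch-class template beats), `baseline` (free, k = 4)
and `optimal` (free, k chosen by model selection).

**Model selection.** For k = 1..15: mean silhouette
s = (b − a)/max(a, b), inertia (mean squared distance to the own medoid),
and the prediction strength ps(k) = min over test clusters of the fraction
of ordered sample pairs co-assigned by a train-fitted model.  The
recommended k maximizes silhouette among k whose prediction strength clears
a threshold (default 0.7), breaking ties toward the inertia elbow.

**Clinical relevance.** Kruskal–Wallis screening plus Holm-adjusted Welch
post-hoc tests per covariate, and a weighted quantile-distance statistic

    d = 1/(k(k−1)) · Σᵢ wᵢ Σ_{j≠i} wⱼ · dist(i, j),   wₙ = Nₙ/N,

where dist(i, j) is the mean absolute gap between the clusters' empirical
quantile functions of the covariate (the 1-Wasserstein distance, sensitive
to location shifts by design).  Larger d = the clustering separates that
covariate better.

**Synthetic cohorts.** Clinical DVP datasets are rarely public, so the
package ships a generator that plants the four morphology classes (sums of
systolic/reflected/diastolic Gaussian waves with a notch well), couples
class prevalence and waveform shape to a subject's vascular age, and draws
covariates (age, weight, height, PWV, PAS, PAD, BMI, BPM, transit time)
matching the summary statistics of a ~300-subject pulse-wave cohort.  Every
pipeline stage is tested against this generator's ground truth.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score

from dvpclust.synth_data import balanced_config, generate_dataset
from dvpclust.preprocess import normalize_pulses
from dvpclust.ddtw import pairwise_ddtw
from dvpclust.clustering import kmedoids_fit
from dvpclust.model_selection import scan_k
from dvpclust.clinical_relevance import csm_table

cfg = balanced_config(n_pulses=400, seed=1)        # 4 planted morphology classes
pulses, clinical, true_class = generate_dataset(cfg)
X = normalize_pulses(pulses)                       # (400, 100), each in [0, 1]

D = pairwise_ddtw(X, w=20)                         # derivative-DTW dissimilarities
curves = scan_k(D, k_range=range(1, 16), metric="precomputed", seed=1)
print("recommended number of clusters:", curves.chosen_k)

result = kmedoids_fit(D, curves.chosen_k, metric="precomputed")
print("adjusted Rand index vs planted classes:",
      round(adjusted_rand_score(true_class, result.labels), 3))

d = csm_table(result.labels, clinical).set_index("variable")["d"]
print(d.round(3).to_string())
```

Output:

```
recommended number of clusters: 4
adjusted Rand index vs planted classes: 1.0
variable
age       0.012
weight    0.003
height    0.001
PWV       0.009
PAS       0.004
PAD       0.004
BMI       0.002
BPM       0.002
TT        0.010
```

The silhouette/inertia scan recovers the four planted shape classes, the
DDTW + K-medoids partition matches the planted labels exactly, and the
quantile-distance table shows the pattern expected for shape-driven
clusters: age, transit time and PWV (the covariates the generator couples
to waveform shape) separate far better than BMI, BPM, height or weight
(drawn independently of shape).

A command-line interface mirrors the library
(`dvpclust synth | preprocess | features | ddtw | ae-train | ae-encode |
cluster | select-k | clinical | run-all`); `run-all` executes the full
3 × 3 grid of representations × {template, baseline, optimal} modes and
writes per-run directories with labels, counts, selection curves and
clinical reports.

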