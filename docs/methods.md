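# Methods

## Model

`octad` treats retinal OCT anomaly detection as one-class density
estimation over local-region embeddings.  A backbone CNN maps a
prepared scan to feature grids; cells of the stride-8 lattice carry
D-dimensional embeddings that summarize a receptive field of roughly
20–40 px.  Healthy training scans populate a nominal bank of such
embeddings, and a test region is scored by its mean Euclidean distance
to the k = 5 nearest bank members.  The image-level score is the
maximum over the region grid: a scan is anomalous as soon as one
region is, which preserves sensitivity to small lesions at the cost of
making the score an extreme-value statistic (its null distribution is
the max of ~784 noisy minima, so the normal-score floor rises as
bank coverage thins — visible when the coreset fraction is small).

Four scoring backends share this interface:

* **global kNN** — search the whole bank regardless of position
  (default; correct when scans are unaligned, as real B-scans are);
* **aligned kNN** — search only same-position members; assumes
  registration across scans and degrades when that fails;
* **Gaussian field** — per-position mean and ridge-regularized
  covariance (ε = 0.01, sample covariance with the n−1 denominator);
  scoring by Mahalanobis distance;
* **gallery retrieval** — retrieve the K = 5 nearest healthy scans by
  global-average-pooled image embedding, then score regions against
  the pooled cells of just those scans.

An image-level backend (kNN on pooled embeddings alone) is included as
the baseline that the local approach is expected to beat.

## Backbone

The bundled `toy_cnn` is a seeded NumPy CNN: a stride-2 average-pool
stem, then four stages of 3×3 convolution → leaky ReLU (slope 0.1) →
2×2 average pool, with 8/16/32/64 channels, He-normal initialization
drawn from a fixed-stream generator so weights are a pure function of
the seed.  On a 224 input the stages produce 56/28/14/7 grids —
the stride schedule of a standard residual network — so the default
stage pair (2, 3) yields a 28×28 region grid (D = 48 after
concatenation).  The width was chosen because narrower random feature
banks (D ≈ 24) proved seed-unstable as kNN representations: individual
seeds could lack directions sensitive to low-contrast lesions.  The
channel count is a property of the backbone spec and can be changed;
everything downstream adapts to D automatically.

Both forward and backward passes are implemented directly (im2col
convolutions and their adjoints), so the adaptation stage needs no
deep-learning framework; gradients are verified against central finite
differences in the test suite.  Pretrained residual-network backbones
are declared in the spec enum but require weight assets that are not
bundled; requesting them raises a resource error pointing at
`toy_cnn`.

## Feature adaptation

Adaptation fine-tunes the backbone on healthy scans with the center
loss ‖f(x) − c‖², c frozen at the mean pre-adaptation image embedding
(a moving center would admit the trivial solution of moving c instead
of f).  Catastrophic forgetting is limited by an
elastic-weight-consolidation penalty λ Σ Fᵢ(θᵢ − θᵢ⁰)² whose diagonal
Fisher estimate is the mean squared center-loss gradient over held-in
normal scans at the initial weights — the pretraining task of the
original one-class adaptation recipe is not available here, and the
center-loss Fisher protects exactly the directions the loss is
sensitive to at the start.

Optimization numerics were a genuine design point.  Fixed-step
gradient descent on this loss is unusable: the curvature spans orders
of magnitude across the conv stack, so small steps change nothing
measurable while larger ones diverge (at a step of 1e-2 the loss rose
~80× over 20 epochs).  The implementation therefore uses Adam-style
per-parameter step sizes αᵢ for the center-loss gradient, and applies
the quadratic EWC term *implicitly* as a proximal step,

    θ ← θ⁰ + (θ − α ⊙ m̂ − θ⁰) / (1 + 2 α λ F),

which is exact for the quadratic, reduces to the plain adaptive step
at λ = 0, and pins θ = θ⁰ exactly as λ → ∞ (an explicit penalty step
oscillates and diverges there for any fixed step size).  Defaults:
40 epochs, step 1e-4, λ = 1e4, batch 8.  The per-epoch history records
the mean center loss over each full pass (pre-update values within the
pass).

## Synthetic data

The generator emulates what matters to this pipeline about real
B-scans, not OCT physics.  Healthy scans are stacks of horizontal
bands whose boundaries carry a random vertical offset (±8% of image
height), tilt (±0.12), sinusoidal curvature (6 px amplitude), and a
smoothed random walk — so scans are unaligned and uncentered.
Alternating band reflectivities (0.30/0.55 plus a small per-layer
increment) sit between a dark vitreous (0.12) and a choroid (0.20).
Noise is multiplicative gamma speckle with shape 4 (σ/μ = 0.5), the
standard OCT noise family.  Optional solid white/black margins (8–24 px,
random sides) exercise margin removal; background levels were chosen
so that under speckle no interior row crosses the quarter-line
white/black fraction that triggers stripping, keeping recovered crop
boxes exactly equal to the injected margin widths.

Anomalies are injected into an otherwise identical "normal twin":
geometry, speckle field, and margins come from independent
deterministic substreams, so the anomalous scan equals its twin
outside the lesion.  The phenotypes follow their clinical OCT
appearance:

* **drusen** — dome-shaped elevation of the deep (RPE) boundary,
  draped progressively into the overlying layers, with
  medium-reflectivity (0.48) sub-RPE deposit material and
  back-shadowing (×0.65) beneath;
* **dme_fluid** — retinal swelling around a cluster of 2–5
  hyporeflective cystoid cavities (tissue ×0.2) separated by septa;
* **cnv** — jagged, steep scrambling of several deep boundaries under
  a Gaussian envelope plus a bright irregular blob (+0.35) and
  back-shadowing.

Lesion linear extents default to 8–40 px, spanning sub-cell to
multi-cell scales relative to the 8-px grid.  The ground-truth mask is
the set of pixels whose noiseless value changed by more than 0.02;
sub-tolerance residue (overlapping edits that nearly cancel) is
snapped back to the twin's value so mask locality is exact.  The
deposit material, swelling, and shadowing are not decoration: a purely
geometric boundary shift is locally indistinguishable under
position-agnostic search, because a healthy bank built from unaligned
scans already contains band patterns at every vertical offset — only
appearance cues that never occur in healthy tissue (deposit
reflectivity, steep jagged edges, honeycomb fluid texture, shadows)
make the benchmark solvable, as it must be for the pipeline's
contracts to be testable.

What passing tests on this generator do **not** show: robustness to
real speckle statistics and scanner artifacts, to anatomical variation
(fovea, vessels, pathology mimics), to varying image quality, or to
pretrained-feature semantics — the bundled backbone sees random
projections, not learned texture.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| k (kNN) | 5 | density-estimation neighborhood |
| white/black thresholds | 0.96 / 0.04 | margin binarization on [0,1] intensities |
| line fraction | 0.25 | "more than a quarter" margin rule |
| coreset fraction | 0.10 | clinical-scale profile: a 100-scan bank (~78k regions) keeps ~7.8k vectors; 0.01 suits banks thousands of scans deep |
| coreset projection | 24 dims | selection-time speed knob; query distances always full-D |
| Gaussian ridge ε | 0.01 | positive-definiteness of per-position covariances |
| heat-map σ | 4 px | rendering only, never before image scoring |
| adaptation | 40 epochs, step 1e-4, λ=1e4 | see above |
| seeds | (0, 1, 2) | all stochastic stages repeated thrice; metrics reported mean±sd |

## Numerical choices and degenerate inputs

kNN ties break by stable bank index; batched scoring uses
scikit-learn's brute-force neighbors, whose quadratic-expansion
distances carry ~1e-7 absolute noise (self-matches score ≈1e-7, not
exactly 0).  Greedy coreset seeds at the first index of a seeded
permutation and never re-selects an index, so selection is a true
subset even with duplicate vectors.  Mahalanobis scoring uses batched
Cholesky factorizations.  Margin stripping re-binarizes each pass,
strips rows before columns, and caps alternation at 4 passes; an image
consumed entirely by margins raises a degenerate-input error, as does
a post-crop size under 32 px.  Empty banks, single-grid Gaussian fits,
k larger than the (aligned slice of the) bank, and single-class
evaluation sets all raise typed errors rather than returning NaNs.

## Benchmark problem sizes

The packaged benchmark uses 100 healthy training scans and
50 + 3×25 test scans at 224×224, three pipeline seeds; the
experiment-matrix comparisons (image-level vs local, aligned vs
global, adapted vs raw) run on a 40-train / 44-test configuration with
coreset fraction 0.25 and a 10-epoch, step-1e-3 adaptation schedule.
These sizes keep a full run in minutes on one CPU core while leaving
each contract's effect measurable.

## Known limitations

* The bundled backbone's random features carry no learned semantics;
  absolute AUCs on real OCT data would hinge on a pretrained backbone
  plugged into the same interfaces.
* Aligned search and the Gaussian field assume inter-scan registration
  that neither the generator nor real B-scans satisfy; they are
  included as comparison arms, not recommendations.
* The max-statistic image score has no calibration; thresholds are
  chosen on labeled data by F1 maximization.
* kNN distance is not a probability; scores are comparable within one
  fitted model only.
* The coreset inflates all kNN distances by construction (scores
  against a subset dominate scores against the full bank); fractions
  well below 10% on small banks measurably hurt low-contrast classes.
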