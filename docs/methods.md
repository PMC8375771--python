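# Methods

`advrep` simulates and analyses a complete experiment on the representation
of adversarial images: a hierarchical image classifier is trained on
parametric object classes, adversarial stimuli are generated against it,
responses of a synthetic visual cortex are simulated with controllable
ground truth, and the representational analyses — RDM similarity with
resampling inference, consistency-based vertex selection, sparse forward
encoding — are run end to end. This note documents the models, the choices
behind their defaults, and what the synthetic conditions can and cannot
show.

## The surrogate classifier

The classifier mirrors the stage taxonomy of a classic deep convolutional
network: five convolutional stages with ReLU gating (2×2 max pooling after
stages 1, 2 and 5), two fully-connected ReLU stages, and a softmax output
stage — eight stages in all, so downstream "5 ROIs × 8 layers" bookkeeping
is preserved. It is implemented directly in NumPy with exact
backpropagation, because the analyses require gradients of class
probabilities with respect to pixels and per-stage activation vectors, not
large-scale accuracy. Channel widths are scaled far down (8–32 channels,
64-unit fully-connected stages) and the default input is 32×32×3 in
[0, 255]; local response normalization is omitted (it would change the
surrogate only quantitatively). Dropout is not used; activations are
extracted in inference mode.

Training uses minibatch Adam (learning rate 2e-3, batch 32, default 50
epochs) with a stratified 25% holdout; the trainer refuses to return a
model below 95% held-out accuracy. Adam was chosen over plain SGD with
momentum after the latter proved seed-fragile on this architecture (roughly
half of random initializations diverged at any fixed learning rate); Adam
reaches 100% held-out accuracy across all seeds tested at both 16×16 and
32×32 scales. Training is deterministic given the seed.

A real pretrained AlexNet can stand in for the surrogate through the
`FeatureExtractor` adapter (lazy import of torch/torchvision, 227×227
inputs). Nothing in the pipeline or tests requires it.

## Synthetic stimuli

Image classes are parametric 2D patterns rather than natural photographs:
each class fixes an oriented grating (class-specific orientation and
spatial frequency), a Gaussian blob at a class-specific position, and an
RGB tint; exemplars within a class vary by nuisance jitter (grating phase,
±2° orientation, amplitude, blob displacement, additive pixel noise).
Several redundant cues per class keep the classes separable even at 40
classes, where orientations are only 4.5° apart. The analyses downstream
are agnostic to image content; what matters is that the classifier is
confident and differentiable.

## Adversarial generation

Two generators attack any model exposing probabilities and input
gradients:

* **Adversarial noise (AN)** — gradient ascent on the regularized
  objective P_c(I) − λ‖I − I_mean‖², starting at the mean image, pixels
  clipped to [0, 255] after every step, stopping when the target-class
  probability reaches 0.99 (or on pixel convergence / iteration budget;
  non-convergence is always flagged, never silent).

  Two numerical choices matter. First, the default ascent direction is the
  gradient of log P_c rather than P_c. The two are the same direction
  (∇P_c = P_c · ∇log P_c), but on the softmax plateau where the ascent
  starts (P_c ≈ 10⁻⁴) the raw probability gradient is scaled by P_c and
  the iteration stalls within machine tolerance of the start; the
  log-gradient form makes progress from the first step. The stopping rule
  is still on P_c itself. `gradient_of="prob"` restores the literal form.
  Second, the defaults λ = 1e-8 and step = 500 are calibrated to the
  surrogate's gradient scale (|∇log P_c| ≈ 1e-5 per pixel): with λ ≥ 1e-6
  the penalty gradient dominates and the ascent equilibrates below the
  0.99 threshold, and a unit step would need on the order of 10⁶
  iterations. Stability of the anchored variants requires 2·λ·step < 1.

* **Adversarial interference (AI)** — the accept/reject hill-climb: fresh
  uniform noise in [−5, +5] on every pixel, kept only if the wrong-class
  probability strictly increases, until it exceeds 0.5. A gradient variant
  (same ascent as AN, anchored to the regular image, threshold 0.99) is
  also provided.

  The wrong class for each image is pre-selected by **confusability
  probing**: a few dozen noisy copies of the image are classified and the
  most probable non-true class is taken. A blind random assignment can
  hand the greedy climb an unreachable target — measured on a 20-class
  surrogate, 2 of 20 images stalled below p = 0.12 after 30 000 iterations
  under random wrong classes, while all 20 converged (median 141
  iterations) under the probe. Pre-selecting a confusable wrong label
  (dog → bird, not dog → fire-truck) is also how such stimuli are chosen
  in practice. A seeded random derangement remains available
  (`wrong_class_policy="derangement"`).

## The experiment design and the cortical sheet

The trial structure reproduces the reference event-related design: two
sessions of five runs; each run presents every session image twice plus
nine blank trials in seeded-random order (129 trials per run at the 60
images/session default), and the condition table assigns one predictor per
(image, repetition) pair plus a single blank predictor (241 at defaults).
How blanks interleave with stimulus trials is not constrained beyond
uniform randomness. No hemodynamics, HRF convolution or GLM fitting are
simulated — the response module emits "beta" amplitudes directly.

The cortical sheet is a flattened two-hemisphere surface with five visual
ROIs (V1–V4, LO) laid out as spatially disjoint jittered unit-spacing
grids (default 150 vertices per ROI per hemisphere, 1500 in all). Because
the sheet is already flat, the searchlight's geodesic distance is exactly
the 2D Euclidean distance; the default disk radius of 3 sheet units plays
the role of the 3 mm searchlight disk.

## Simulated vertex responses and their ground truth

Each vertex's noise-free regular-image (RE) response pattern is a
3-sparse (default) linear combination of its assigned classifier stage's
unit activations over the RE images, z-scored across images. ROIs map onto
stages along the ventral hierarchy: V1→L1, V2→L2, V3→L3, V4→L4, LO→L5.
Responses to the adversarial images are then generated **at the response
level**, not by feeding adversarial images through a simulated brain: the
AI pattern is the variance-matched mixture ρ_AI·RE + √(1−ρ_AI²)·noise
(independent noise per vertex), and likewise the AN pattern with ρ_AN.
Gaussian repetition noise (sd 0.5 in units of the unit-variance patterns)
is added per presentation; two presentations by default. The defaults
ρ_AI = 0.8, ρ_AN = 0.0 encode the qualitative empirical finding the
pipeline is built to detect — adversarial-interference responses share the
regular images' representational geometry, adversarial-noise responses do
not — with enough repetition noise that split-half consistency is a
non-trivial selection signal.

Every generator is a pure function of its arguments including the seed,
and the recorded ground truth (per-vertex support, weights, source stage,
mixing weights, noise scale, seed) regenerates the betas bit-exactly.

What this generator deliberately does not emulate: spatial autocorrelation
of responses across the sheet (vertices are conditionally independent
given their stage features), hemodynamic or physiological noise structure,
attentional or arousal drift between sessions, and any nonlinearity
between features and response. Passing tests therefore show that the
analysis chain recovers the representational structure that was put in;
they do not certify the analyses against realistic fMRI noise.

## Representational similarity analysis

RDMs use correlation distance (1 − Pearson) between item patterns by
default — the field-standard choice; Euclidean distance is available. A
zero-variance pattern makes correlation distance undefined and raises an
error naming the item. RDMs are compared by Spearman rank correlation of
their strictly-upper triangles with average ranks for ties.

Inference follows the prescribed resampling scheme. The RE-AI minus RE-AN
difference is assessed by subsampling 80% of the units without replacement
1000 times; the one-sided p is the add-one estimator
(1 + #{diff ≤ 0})/(n+1), and the 95% CI is the plain percentile interval
(no bias correction). Absolute similarities are tested against a
label-permutation null, the permutation nested inside the unit subsample.
Trends over the 8 stages use the Mann-Kendall test with tie-corrected
variance and ±1 continuity correction (implemented here; no pre-installed
package provides it, and it is oracle-tested against exhaustive pairwise
enumeration).

A calibration caveat, measured and documented rather than hidden: the
directional subsample bootstrap is mildly anticonservative. An 80%
subsample shares most of its units with the full sample, so the baseline
distribution's spread understates true sampling variability (for a
mean-like statistic the deviation sd is ≈ √((1−f)/f) = 0.5 of the
full-sample sd). Under the generator's null (ρ_AI = ρ_AN) the empirical
size at α = 0.05 is ≈ 0.12 — about 2.4× nominal — across the scales
tested. The label-permutation test, which is exactly valid, calibrates at
its nominal size and is the one to trust for absolute claims; the
bootstrap difference test is reported as prescribed by the procedure it
reimplements.

## Vertex selection

For each vertex, the RE-image RDM is computed twice within its searchlight
disk — once per presentation — and the two RDMs are compared by Spearman
correlation. Disks with fewer than 3 vertices yield missing values (an
RDM comparison on fewer points is not meaningful). The top 100 vertices
per hemisphere per ROI are retained (200 per ROI; the doubled 400-variant
is supported), ties broken by ascending vertex id for determinism,
missing-consistency vertices excluded before ranking. Selection reads only
the RE responses.

## Sparse forward encoding

One model per (vertex, stage): y = Xw with X the m×(n+1) matrix of the
stage's activations over the m training images (columns z-scored on the
training set, scaling stored for test-time reuse; intercept column of ones
appended, exempt from scaling). The solver is regularized orthogonal
matching pursuit (ROMP), implemented here (no pre-installed package
provides it): per iteration, correlate the residual with all columns, take
the s largest magnitudes, regularize to the maximal-energy subset whose
magnitudes lie within a factor of two, add it to the support, refit by
least squares; halt at support size 2s (intercept excluded) or residual
≤ 1e-6·‖y‖. The sparsity budget defaults to s = m/4 (10 at the default 40
training images). Rank-deficient refits fall back to the minimum-norm
solution with a warning. Greedy recovery is instance-dependent: on random
noiseless 3-sparse problems (unit-norm Gaussian columns) exact recovery
runs ≈ 84% at m = 20, n = 40 and ≈ 90% at m = 40, n = 48 — the oracle
tests use instances inside the recovery regime and the test suite asserts
the existence of the exact solution separately from the greedy's success
rate.

Generalization: per vertex, Pearson correlation between predicted and
measured responses **across the adversarial images** (the per-vertex
orientation; per-image-across-vertices is available). Cell accuracy is the
plain (not Fisher-transformed) mean over the cell's vertices, with a
bootstrap CI from resampling 80% of vertices 1000 times and a permutation
p from shuffling the measured images' labels (the same permutation across
vertices within a replicate). The AI-vs-AN comparison resamples vertices
and records the difference of cell means.

At the output stage the adversarial-interference images genuinely change
the representation (they are built to flip the classifier's label), so
RE-trained models lose predictive power there — the expected signature of
the hierarchy, mirrored in the layer profile, not an artifact.

## Problem sizes in the tests and the acceptance script

The test suite trains its surrogates at 12 classes / 16×16 and runs the
full qualitative-reproduction pipeline at 20 classes / 32×32 with 500
vertices (50 per ROI per hemisphere, 25 selected per hemisphere) and
500-replicate resampling; the calibration battery uses 200 simulated
datasets of one 100-vertex ROI with 40 items and 200-replicate bootstraps.
The acceptance script trains the full 40-class default set at 32×32 and
attacks 8 classes/images. These sizes keep every stage non-degenerate
(≥ 10 units in the smallest stage, 40-item RDMs where the reference
geometry is 40×40) while the whole chain remains desk-scale.

## Known limitations

* The response simulator's independence assumptions (above) make the
  synthetic cortex easier than a real one; effect sizes are set by ρ, not
  estimated from data.
* The subsample bootstrap difference test is anticonservative (~2.4×
  nominal size); use the permutation test for absolute claims.
* ROMP is greedy: exact sparse recovery is typical but not guaranteed, and
  the support bound 2s means reported supports can be larger than the
  generating sparsity.
* The surrogate's adversarial images are adversarial for the surrogate
  only; nothing is claimed about transfer to other architectures.
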