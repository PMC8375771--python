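# advrep

Representational analysis of adversarial images across a hierarchical
classifier and a synthetic visual cortex.

Deep image classifiers can be fooled in two complementary ways: images that
look like noise to a human but are classified into an object category with
near certainty (adversarial **noise**, AN), and ordinary images perturbed
so slightly that a human sees no change while the classifier's label flips
(adversarial **interference**, AI). Whether a measurement system —
artificial or biological — *represents* these images the way it represents
regular (RE) images is a question about representational geometry, and
answering it takes a pipeline: generate the adversarial stimuli, measure
responses, compare representational dissimilarity matrices (RDMs) with
resampling inference, select reliable measurement units, and test whether
forward encoding models trained on regular images generalize to the
adversarial ones.

`advrep` implements that pipeline end to end for researchers in visual
computational neuroscience, with every input synthesized from seeds: an
8-stage differentiable classifier (5 conv + 2 fully-connected + softmax,
pure NumPy with exact backprop), both adversarial generators, an
event-related experiment design, a flattened two-hemisphere cortical sheet
with five ROIs (V1–V4, LO), and vertex responses with controllable,
recorded ground truth. Because the generator's coupling parameters are
explicit (ρ_AI, ρ_AN), every analysis is a parameter-recovery exercise:
tests can verify that the chain finds exactly the structure that was put
in, at the rates it claims.

## The statistics at the core

* **RDM similarity** — for each unit population (a classifier stage's
  artificial neurons, or the vertices of one ROI), RDMs of the RE, AN and
  AI image sets use correlation distance (1 − Pearson); geometries are
  compared by Spearman's R over the strictly-upper triangles:
  R_RE-AN = corr(RDM_RE, RDM_AN) and R_RE-AI = corr(RDM_RE, RDM_AI).
* **Inference** — the RE-AI − RE-AN difference by subsampling 80% of the
  units without replacement 1000 times (one-sided bootstrap p); absolute
  similarities against label-permutation nulls nested in the unit
  subsample; trends over the 8 stages by the Mann-Kendall test.
* **Vertex selection** — per-vertex split-half consistency: Spearman
  correlation between the two presentations' RE RDMs within a 3-unit
  searchlight disk on the flattened sheet; top 100 vertices per hemisphere
  per ROI retained (200 per ROI), using RE responses only.
* **Forward encoding** — per (vertex, stage): y = Xw with X the
  m × (n+1) stage-activation matrix (intercept column appended), solved by
  regularized orthogonal matching pursuit (ROMP) under the sparsity
  program min ‖w‖₀ s.t. y = Xw; generalization is the Pearson correlation
  between predicted and measured responses across the adversarial images,
  with vertex-bootstrap CIs and label-permutation p-values per
  (ROI, stage) cell — 5 ROIs × 8 stages = 40 model groups.

## Worked example

The full default experiment — 40 classes, one RE image each with one AN
and one AI counterpart (120 stimuli), a 1500-vertex sheet, 1000-replicate
resampling — runs in about 5 minutes on one CPU:

```python
from advrep.pipeline import run_pipeline
report = run_pipeline(dict(seed=0), out_dir="out")
```

or equivalently `advrep run --out out --seed 0`. Highlights of the report
this prints (seed 0):

```
stimuli   : 120 total (40 RE + 40 AN + 40 AI); 129 trials/run; 241 conditions
surrogate : held-out accuracy 1.000
AN images : 40/40 converged, min target-class probability 0.9900
AI images : 40/40 converged, min wrong-class probability 0.5010
ROI RSA   :        RE-AN    RE-AI   bootstrap p (diff)
    V1    :       -0.037    0.745   0.001
    V2    :        0.064    0.898   0.001
    V3    :        0.080    0.924   0.001
    V4    :        0.018    0.925   0.001
    LO    :        0.045    0.944   0.001
searchlight: mean RE-AN 0.008, mean RE-AI 0.624 over 1500 vertices
encoding  : AI permutation p < 0.05 in 40/40 ROI x stage cells,
            AN in 2/40 (mean accuracy 0.596 vs 0.002)
```

Read it as a parameter recovery: the generator coupled the AI responses to
the RE geometry (ρ_AI = 0.8) and decoupled the AN responses (ρ_AN = 0),
and every analysis — ROI-level RDM similarity, the searchlight map, and
encoding-model generalization — recovers precisely that asymmetry, while
the AN permutation tests reject at roughly their nominal 5% rate. The
`out/` directory holds the JSON report, CSV tables (searchlight map,
selected vertices, encoding accuracies, layer profile), the stimulus PNGs,
the HDF5 response container and summary figures. Identical config and
seeds reproduce the report byte for byte.

## Layout

| module | contents |
| --- | --- |
| `advrep.synth` | images, experiment design, cortical sheet, vertex responses with ground truth |
| `advrep.model` | the 8-stage NumPy classifier: training, activations, input gradients |
| `advrep.adversarial` | AN gradient ascent; AI accept/reject hill-climb and gradient variant |
| `advrep.rsa` | RDMs, Spearman similarity, bootstrap/permutation inference, Mann-Kendall, searchlight |
| `advrep.selection` | split-half consistency maps, top-N vertex retention |
| `advrep.encoding` | feature matrices, ROMP, encoding-model training and generalization |
| `advrep.pipeline` / `advrep.cli` | orchestration, config validation, reports; `advrep` console entry point |

`docs/methods.md` documents the models, defaults, numerical choices and
known limitations — including the measured anticonservativeness of the
subsample bootstrap difference test.
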