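# spixcrf

Superpixel conditional-random-field segmentation of brain-tumor MR slices,
with the pairwise graph *learned from the image* by ℓ1-penalized Ising
pseudo-likelihood.

## The problem

Delineating glioma (tumor core plus surrounding edema) on a 2-D MR slice is
a binary labeling problem: every pixel is tumor or normal tissue. Working at
pixel level is expensive and noisy, so the slice is first over-segmented
into a few hundred *superpixels* — compact, intensity-homogeneous regions
that preserve tissue boundaries — and each superpixel becomes one node
`y_i ∈ {−1, +1}` of an undirected graphical model.

Most region-based MRF/CRF segmenters assume the neighborhood graph is known
(usually plain region adjacency). Here the graph is estimated: node labels
are modeled by an Ising distribution

    P(y) ∝ exp( Σ_i θ_i y_i + Σ_(i,j) θ_ij y_i y_j ),

and the couplings θ_ij are fitted by minimizing the symmetric negative
pseudo-likelihood  Σ_m Σ_i −log p(y_i⁽ᵐ⁾ | y_rest⁽ᵐ⁾, θ)  plus an ℓ1
penalty λ‖θ_edge‖₁, solved with a monotone accelerated proximal-gradient
method (soft-threshold prox, backtracking line search). Couplings driven
exactly to zero delete their edges, so the penalty level selects a sparse
graph per slice.

A conditional random field is then built on the learned graph:

    P(y | x) ∝ exp( Σ_i (ω_nodeᵀ f_i(x)) y_i + Σ_(i,j) (ω_edgeᵀ g_ij(x)) y_i y_j ),

with node features `f_i = [1, φ_i]` built from four handcrafted families per
superpixel (71 columns total):

* 14 first-order intensity statistics (mean, spread, shape, entropy);
* 44 RLCP texture features — 11 gray-level run-length statistics (SRE, LRE,
  GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE) of the LBP-coded
  region along 0°, 45°, 90°, 135°;
* 1 mean level-set curvature of the smoothed intensity surface;
* 12 fractal features — (area, mean intensity, box-counting dimension) of
  four multi-Otsu binary channels;

and edge features `g_ij = [1, |Δ mean intensity|, centroid distance]`.
Weights are tied across nodes and across edges, so a model trained on one
cohort applies to new slices. Training minimizes the penalized
pseudo-likelihood with ℓ1 on the node feature weights (feature selection)
and squared-ℓ2 on the edge weights; inference is iterated conditional modes
(ICM) from independent-unary initialization, with exhaustive enumeration as
an oracle for small graphs. Predictions are scored with correlation (φ),
Dice, Hausdorff distance, sensitivity and specificity.

Since no clinical data ships with the package, a phantom generator renders
FLAIR-like slices — bright disk core + edema ring inside an elliptical
brain, with Gaussian noise and a smooth multiplicative bias field — together
with noise-free truth masks, so the whole pipeline is trainable and
testable offline.

## Worked example

```python
import spixcrf as sx
from spixcrf.pipeline import train_model, segment_image
from spixcrf.metrics import evaluate_cohort

template = sx.PhantomSpec()                      # 128x128, noise sd 0.05
train = sx.generate_cohort(template, 5, seed=11)
test  = sx.generate_cohort(template, 5, seed=22)

cfg = sx.RunConfig(seed=7)
model, count = train_model([(s.image, s.mask_whole) for s in train], cfg)
print("selected features:", len(model.selected_features()), "of 71")

pairs = []
for k, s in enumerate(test):
    res = segment_image(s.image, model, cfg, seed=100 + k)
    pairs.append((res.mask, s.mask_whole))
print(evaluate_cohort(pairs).round(3))
```

Output:

```
selected features: 12 of 71
        correlation   dice  hausdorff  sensitivity  specificity
sample
0             0.997  0.997      1.000        0.994        1.000
1             0.975  0.976      5.385        0.998        0.997
2             0.994  0.994      1.414        0.996        1.000
3             0.999  0.999      1.000        1.000        1.000
4             0.996  0.996      1.000        1.000        1.000
mean          0.992  0.993      1.960        0.998        0.999
```

The ℓ1 stage kept 12 of the 71 node features (intensity statistics dominate,
as expected for an intensity-separable phantom); the segmentation overlaps
the truth almost perfectly, with sub-2-pixel mean Hausdorff distance.

A command-line interface mirrors the stages: `spixcrf simulate`,
`superpixels`, `features`, `learn-structure`, `train`, `segment`,
`evaluate`, `pipeline` (see `spixcrf --help`).

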