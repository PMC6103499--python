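# Methods

## Model

The segmentation target is a binary labeling `y ∈ {−1,+1}^p` of the `p`
superpixels of a 2-D grayscale MR slice. Two probabilistic models are used
in sequence.

**Structure learning.** Node labels are modeled by a pairwise Ising field
`P(y) ∝ exp(Σ θ_i y_i + Σ_(i,j)∈E θ_ij y_i y_j)` over a *candidate* edge set
E (the ≤2-hop region adjacency graph). Its full conditional for one node is
logistic in the local field `a_i = θ_i + Σ_j θ_ij y_j`:
`p(y_i = +1 | rest) = e^{2a_i}/(e^{2a_i}+1)`. Given i.i.d. label samples,
the parameters minimize the symmetric negative pseudo-likelihood plus
`λ‖θ_edge‖₁` (node biases unpenalized). One coupling is shared per
unordered pair and receives gradient from both endpoint conditionals, so no
AND/OR symmetrization is needed. Couplings soft-thresholded to exactly zero
remove their edges; `|θ_ij| > 10⁻⁶` defines the learned graph. The
partition function is never computed: pseudo-likelihood for fitting, exact
enumeration only as a ≤4-node test oracle.

For a single unlabeled image the i.i.d. samples are produced by *pixel
draws*: per draw, one uniform-random pixel per superpixel, binarized at the
image's global Otsu threshold, mapped {0,1}→{−1,+1}. Rows are i.i.d. given
the image, preserving the sample interface of the estimator while remaining
computable without masks. A Gibbs sampler over the fitted field provides
model-generated samples for validation (e.g. edge recovery from a known
20-node cycle).

**CRF.** On the learned graph, labels conditioned on the image follow
`P(y|x) ∝ exp(Σ ψ_i + Σ ψ_ij)` with `ψ_i = (ω_nodeᵀ f_i(x)) y_i` and
`ψ_ij = (ω_edgeᵀ g_ij(x)) y_i y_j`. Weights are tied across nodes and
across edges — the only parameterization that transfers between images with
different superpixel counts. Training again maximizes penalized
pseudo-likelihood (each conditional is a logistic regression in the local
field), with `λ1‖τ_node‖₁` selecting node features and `λ2‖ω_edge‖₂²`
shrinking the full edge vector. The edge ℓ2 deliberately covers the
constant-column coupling too: left free, a uniform attractive coupling
absorbs the neighbor-label correlation during pseudo-likelihood training
and the unaries under-train. The node bias stays unpenalized.

MAP inference is iterated conditional modes: initialize each node at the
argmax of its unary logistic, sweep nodes in fixed index order flipping each
to its conditional mode, stop when a sweep changes nothing (cap 100
sweeps). Deterministic by construction; exhaustive enumeration (≤15 nodes)
serves as the optimality oracle. ICM matches the enumerated optimum in
roughly 19 of 20 random instances when couplings are an order of magnitude
weaker than unaries — the regime fitted models actually occupy (measured
edge weights ~0.03–0.13 against node weights ~0.5); with couplings as
strong as unaries, agreement drops to ~75%, a known ICM limitation.

## Superpixels and features

Slices are over-segmented by adaptive-compactness SLIC (SLIC0): k-means-like
clustering in (intensity, x, y), with each cluster's compactness rescaled
after the first iteration by the ratio of its maximal color to maximal
spatial distance. Compactness is quoted in conventional 0–255 gray-level
units (default 40, internally divided by 255 because the backend normalizes
intensities), 10 iterations. Fragments under 25% of the average target size
are merged into the touching neighbor with the closest mean intensity —
boundary-preserving, unlike longest-boundary merging. Region ids are
compacted to 0..p−1 and 4-connectivity is enforced.

Node features (71 columns, fixed order):

* **First-order (14):** mean, sd, variance, mean/median absolute deviation,
  coefficient of variation, skewness, excess kurtosis, max, mode, third
  central moment, range, IQR, entropy. Population moment conventions
  (variance of {1,2,3,4} is 1.25); a constant region defines cv, skewness,
  kurtosis and entropy as 0. Entropy uses a 32-bin histogram over the
  region's min–max with 0·log 0 ≡ 0.
* **RLCP texture (44):** classic LBP (P=8, R=1, square ring, neighbor ≥
  center, border replication; non-rotation-invariant codes), codes
  quantized to 16 levels, then 11 run-length statistics along each of
  0°/45°/90°/135°. Runs never cross the region mask; the matrix is built on
  the contiguous bounding box so mask gaps break runs. Pixel-count
  conservation `Σ l·M(g,l) = |region|` holds per direction by construction
  and is property-tested.
* **Curvature (1):** mean over the region of the level-set curvature
  `κ = (f_xx f_y² − 2 f_xy f_x f_y + f_yy f_x²)/(f_x²+f_y²)^{3/2}` after
  Gaussian smoothing (sd 1 px); pixels with squared gradient below 10⁻⁸ get
  κ = 0. An `as_printed` variant without the mixed-derivative term is kept
  behind a config flag for fidelity to an alternative published form; the
  standard form is the default because it reproduces the analytic 1/r of
  circular level sets (within 2% at r = 8–32 px).
* **Fractal (12):** 4-threshold multi-Otsu (32-bin histogram search — the
  256-bin default is combinatorially slow for 5 classes and shifts
  thresholds negligibly) gives four binary channels `intensity ≥ t_k`; each
  contributes area fraction, mean intensity under the channel, and
  box-counting dimension. Regions with fewer than 5 distinct values fall
  back to midpoints between the sorted distinct values, padded with the
  maximum. Box counting uses dyadic sizes {1,2,4,8,16} clipped to the larger
  bounding-box side (so 1-px lines keep multiple scales), grid anchored at
  the bounding-box corner, dimension = −slope of the log–log least-squares
  fit; degenerate patterns return 0.

Edge features: `[1, |Δ mean intensity|, centroid distance (px)]`.
Node features are z-scored with center/scale fitted on training nodes only
and reapplied at test time; zero-spread columns get unit scale.

## Optimizer

Both fits share a monotone accelerated proximal-gradient solver (Nesterov
momentum, backtracking line search halving the step until the quadratic
bound holds and regrowing it 1.2× per iteration, monotonicity safeguard
that rejects objective-increasing candidates). Stopping: relative objective
change < tol on an accepted step (structure 10⁻⁷, CRF 10⁻⁹) or the
iteration cap (structure 500, CRF 50). Non-convergence returns the best
iterate with a warning; in the per-image structure pass this warning is
expected and suppressed, because single-class nodes push their unpenalized
biases toward ±∞ indefinitely while the edge support stabilizes early.

## Defaults

| parameter | default | notes |
|---|---|---|
| n_superpixels | 200 | top of the 40:20:200 sweep grid, which training-set Dice selects when sweeping is enabled |
| compactness / SLIC iters | 40 / 10 | conventional values for this slice resolution |
| candidate graph | 2-hop RAG | superset of adjacency for the ℓ1 stage to prune |
| n_draws_struct | 200 | pixel draws per image for structure learning |
| lambda_struct | 20 | sum-scale objective over 200 draws; sparsifies the 2-hop candidate set to a handful of edges |
| λ1, λ2 | 2, 1 | ℓ1 keeps ~10–20 of 71 features on phantom cohorts; ℓ2 keeps couplings an order below unaries |
| CRF max iterations | 50 | optimizer budget |
| zero_tol | 10⁻⁶ | edge-deletion threshold on fitted couplings |
| inference | ICM | `exact` available ≤15 nodes |

## The phantom

`PhantomSpec` renders a 128×128 slice: elliptical brain (semi-axes 52×44 px,
level 0.35) on background 0.05, tumor = disk core (radius 12 px, level 0.90)
plus annular edema (width 6 px, level 0.65) — the hyperintense-tumor
appearance of FLAIR/T2. Degradations: additive Gaussian noise (sd 0.05) and
a multiplicative bias field (low-order 2-D polynomials scaled to ±10%)
emulating coil inhomogeneity. Cohorts jitter tumor center (±10 px), core
radius (9–15 px) and edema width (4–8 px); truth masks are noise-free and
satisfy core ∪ edema = whole, core ∩ edema = ∅.

What the phantom does **not** emulate: anatomy (gyri, ventricles, skull),
Rician noise statistics, partial-volume effects, infiltrative or necrotic
tumor texture, multi-modal channels. Tumor/normal separation is primarily
an intensity contrast, so passing the end-to-end bar shows the pipeline is
correctly wired and statistically sound — not that it reaches clinical
accuracy on real data, where texture and fractal channels would carry more
of the load.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
train-20/test-20 cohorts of 128×128 phantoms at 200 superpixels (the full
end-to-end pass takes ~1–2 minutes on one CPU), 20-node cycle recovery from
2000 Gibbs draws, ≤12-node enumeration oracles, 100-instance ICM
comparisons.

## Known limitations

* ICM is a coordinate-ascent local search; with strong frustrated couplings
  it finds local optima (see agreement figures above). Graph cuts or loopy
  BP are out of scope.
* The dense 1-hop RAG ablation (`graph_mode="rag"`) underperforms the
  learned sparse graph at small training sizes: pseudo-likelihood training
  with many edges lets neighbor labels explain away the unaries. This
  contrast is the point of learning the structure.
* At very coarse superpixelation (~100 regions on 128² px) SLIC can miss a
  short boundary arc (measured recall 0.92 at 100 vs 1.0 at ≥120 on
  noiseless phantoms); segmentation quality is ultimately bounded by
  superpixel boundary adherence.
* The pixel-draw sample source treats pixels within a superpixel as
  exchangeable; heavy intra-region gradients (strong bias fields) weaken
  that approximation.
* Binary whole-tumor labeling only; core/edema subcompartments exist in the
  phantom truth but multi-class CRFs are out of scope.
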