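# Methods

## The model

`landreg` detects spatial landmarks on tissue sections without any
annotation and uses them — through an analytically solved thin-plate
spline (TPS) — to register sections to each other, to reconstruct
serial-section stacks in 3-D, and to align different modalities
rasterized from the same tissue.

A convolutional hourglass network maps an image to K heatmaps at input
resolution, each normalized to a probability map by a spatial softmax.
The landmark of map k is its argmax; during training a differentiable
surrogate is used (see *Soft argmax* below).  The only geometric
machinery is the TPS

    f(x, y) = a1 + ax·x + ay·y + Σᵢ wᵢ U(‖(xᵢ, yᵢ) − (x, y)‖),
    U(r) = r² log₂ r,  U(0) = 0,

fitted per output axis with the side conditions Σwᵢ = Σwᵢxᵢ = Σwᵢyᵢ = 0
through the augmented linear system [[K + λI, P], [Pᵀ, 0]].  Because
the spline is solved in closed form it cannot memorize image-specific
identities, which is what forces the detector to place corresponding
landmarks consistently across sections: a registration loss can only
be reduced by landmarks that actually correspond.

Three training regimes share this mechanism:

* **Pairwise.**  Two augmented variants of one section give X_target
  and X_source; the warp of X_source onto X_target is scored with an
  MS-SSIM dissimilarity (base loss).  A second section Y registered to
  X_target adds a consistency loss (patch-wise around the landmarks
  with window 3 for homogeneous data, whole-image for data with batch
  effects).  Total: L_base + 0.1·L_consistency.
* **Z-stack (anchor points).**  Each section X_i is registered to a
  random reference both rigidly (Kabsch–Umeyama) and by TPS; a noisy
  neighbor X_j (drawn within ±3 sections) is registered by TPS.  The
  loss (1−dA)·D(X_j^TPS, X_i^TPS) + dA·D(X_j^TPS, X_i^rigid) is gated
  by the relative foreground-area change dA of the TPS registration,
  so area-distorting splines are penalized and the landmarks behave as
  planar anchor points along the stack.
* **Multimodal.**  One detector per modality; per-modality base and
  whole-image consistency (intra) losses, plus an inter-modality term:
  a section of modality B is registered into a modality-A frame and
  the RMSE between first-layer activations of detector A on both
  images ties the modalities into a joint latent space.  Total:
  L_base + 10·L_intra + 0.1·L_inter.

## Losses

All dissimilarities are `1 − MS-SSIM`.  The papers' loss notation is a
similarity, but a similarity cannot be minimized, so the standard
`1 − MS-SSIM` form is used; this affects nothing but the sign
convention of reported histories.  MS-SSIM follows Wang et al.:
Gaussian-window (σ 1.5) statistics with *valid* convolution,
contrast-structure at every scale, luminance only at the coarsest
scale, scales linked by 2× average-pool downsampling, combined as a
weighted geometric product with the standard five-scale weights
(0.0448, 0.2856, 0.3001, 0.2363, 0.1333), truncated and renormalized
when the image supports fewer scales.  The default window is 5 for
whole images and 3 for landmark patches (16 px patches, clipped at
borders).  With `n_scales=1` and an 11-tap window the implementation
is numerically identical to scikit-image's Gaussian-weighted SSIM with
population covariance, which the tests use as an independent
cross-check.

## Differentiation

No tensor framework is assumed: `landreg._autodiff` is a compact
reverse-mode automatic-differentiation core on numpy arrays providing
exactly the operator set the training graph needs — elementwise
arithmetic, matmul, conv2d, average pooling, nearest upsampling,
softmax, a differentiable linear solve (for the TPS system), and
bilinear grid sampling (for the warp).  Gradients therefore flow from
the MS-SSIM loss through the warp coordinates, the TPS coefficients,
the soft-argmax, and the heatmap network in one graph.  Every operator
is verified against central finite differences in the test suite.
Two pieces are deliberately outside the tape: the rigid
Kabsch–Umeyama fit (an SVD whose gradient adds little signal next to
the TPS path) and the area change dA (a pixel count, not smooth); a
`stop_grad_tps` flag additionally allows detaching the TPS solve.

## Soft argmax

The heatmap head already produces probability maps.  The training
surrogate is the expected coordinate under the temperature-sharpened
distribution p ∝ h^(1/τ) (τ default 0.1), which for a softmax head is
identical to a softmax over the logits divided by τ.  An *additive*
softmax on probability values (softmax(h/τ)) is near-uniform for any
map whose values are O(1/HW) — the landmarks then collapse to the grid
centroid and gradients vanish, which we observed directly.  The
sharpened form has the right limits: a one-hot map returns its pixel,
a uniform map returns the centroid, and τ → 0 recovers the hard
argmax.  Inference defaults to the same sharpened soft argmax: it
returns sub-pixel coordinates and degrades gracefully on diffuse maps,
where a hard argmax jumps between ties; for sharply peaked maps the
two coincide.  Hard mode (ties broken at the smallest row-major index)
is available through the detector configuration.

## Geometry conventions

Pixel coordinates are 0-based (x, y) = (column, row) with centers at
integers.  TPS fitting normalizes coordinates to [−1, 1] per axis
(scale invariance of the linear system); the normalization box is
stored in the model.  Image warping is backward: the model is fitted
target → source and output pixels pull source intensities bilinearly,
with out-of-bounds taps contributing zero (black background).  Partial
boundary overlap therefore fades smoothly to zero rather than cutting
off at the last pixel center — the convention a zeros-padded sampler
uses, and the differentiable one.  λ defaults to 1e−6 during training
(conditioning under near-duplicate landmarks after drop-out) and 0 in
the analytic tests.

dA is `min(1, |A_after − A_before| / A_before)` with foreground =
any channel ≥ 0.1.  The relative-with-clipping form keeps dA in [0, 1]
so it is usable directly as a convex mixing weight.

Background "cropping" is union masking: pixels whose channels all fall
strictly below 0.1 in either image of a pair are zeroed in both.
Masking rather than geometric cropping keeps the two loss inputs
equal-shaped.

## Training defaults

Defaults mirror full-scale runs: learning rate 1e−4 with a ×0.95 step
every 10 epochs, batch 48 (pairwise/multimodal) or the whole stack
(z-stack), 300 iterations per epoch with replacement, up to 80 epochs,
stop when the best loss improves by less than 1e−4 over 10 consecutive
epochs, landmark drop-out probability 0.1 with at least 4 survivors
(TPS degenerates below 3 points; 4 gives slack against collinearity).
The optimizer is Adam with default moments.  Augmentation is rotation
(uniform ±15°, with an isotropic shrink keeping the foreground inside
the frame) followed by elastic deformation from a coarse grid of
Normal(0, σ²) knot displacements (σ 3 for homogeneous benchmarks, 5.5
for tissue); flips are excluded because landmark identity is not
mirror-symmetric.  The rng stream order (rotation, then elastic) is
fixed.

The CPU-scale configuration used by the tests and the acceptance
script is the package's own desk-scale study: 64 px sections, the
`reduced` two-level hourglass (≈38k parameters; the `reference`
preset at ≈5.6M parameters mirrors the full-scale network), 8
landmarks, batches of 4–12, 2–4 iterations per epoch and 8–12 epochs,
learning rate 1e−3 (appropriate to the small network; the 1e−4
default belongs to the large-scale schedule).  These sizes make each
training smoke run finish in about a minute while still showing the
qualitative behavior of interest: decreasing registration loss,
improving affine equivariance of the landmarks, decreasing TRE and dA
along a stack, and a matched-vs-shuffled gap in the multimodal latent
loss.

## Synthetic data

The generator renders from an analytic latent: a smooth foreground
whose boundary radius is a low-order Fourier series, internal Gaussian
structures whose centers are the ground-truth landmarks, and three
channels mixing these features.  Inter-section and inter-modality
geometry is an affine composed with a smooth elastic field defined on
coarse knots, applied *forward* to points and inverted per pixel by
fixed-point iteration when rendering — image and point ground truth
are therefore consistent to well below 0.1 px.  Batch effects are
monotone gamma + gain maps that keep zero background at zero, so the
0.1 background threshold stays meaningful.  Stacks put all geometric
drift into the per-section deformations (plus per-section jitter) and
drift blob intensities separately, so the exact pair correspondence
maps compose along the chain.  Spot tables use a hexagonal lattice
restricted to the foreground with Poisson counts of smooth per-gene
rate fields.

What the generator does **not** emulate: histological texture and
stain variation, section tears and folds, non-monotone intensity
artifacts, partial tissue loss between sections, and modality-specific
noise structure (e.g. count sparsity of real Visium at full gene
depth).  Passing the synthetic suites therefore demonstrates the
correctness of the machinery and the qualitative learning behavior,
not performance on real histology.

## Omics pipeline

Spots with fewer than 200 detected genes are removed, then genes
present in fewer than 3 spots; because each pass can expose new
violations the two passes iterate to a fixed point (the result is
idempotent).  Counts are scaled per spot to the median spot total and
log1p-transformed; zeros stay zero.  Gene selection clusters each
sample (Leiden on a PCA neighborhood graph, resolution 1.0, seeded),
ranks genes per cluster by the magnitude of the Welch t statistic
(cluster vs rest, computed in-module so the ranking is testable),
unions the per-cluster top-n sets, and intersects across samples; a
single-community sample falls back to a variance ranking.
Rasterization min-max scales each channel *before* Delaunay-linear
interpolation onto a square grid aligned to the spot bounding box with
a 2% margin (isotropic spacing); pixels outside the convex hull and
zero-range channels are 0.  Channel reduction for display runs PCA
over foreground pixels, fixes each component's sign so its loading
vector sums positive, and min-max scales to [0, 1].

## Evaluation

Consistency error compares affine(detect(x)) with detect(affine(x))
per landmark.  Forward/backward errors fit ordinary least squares
(with intercept) between detected and annotated point sets on a seeded
50/50 image split and report the held-out mean Euclidean error divided
by a normalizer (default 1; pass the image diagonal or an
inter-landmark scale for comparable numbers); a rank-deficient design
falls back to ridge (1e−6) with a warning.  TRE is the mean Euclidean
error of held-out target points of one consecutive pair.  ATRE
propagates every section's target points through the composed chain of
fitted transforms into the final section's frame and sums the
per-section mean errors (the reference contributes zero) — the paper
family defines the accumulated variant only verbally, so this sum
convention is declared here and checked against brute-force
propagation.  k-NN region accuracy uses k = 5 with ties broken toward
the smallest label index.

## Known limitations

* The numpy autodiff core is single-threaded per op and holds the
  whole graph; it is sized for 64–128 px images and the reduced
  detector, not for GPU-scale training.
* Gradients do not flow through the rigid fit or dA (see above); on
  stacks this makes the rigid term a fixed anchor rather than a
  learned one within each step.
* The detector assumes consistently oriented inputs; mirrored sections
  are out of scope by design.
* Heatmap-based landmarks are limited to one coordinate per map; K
  must be chosen generously enough (≥ 4 after drop-out) for the TPS to
  stay well-posed.
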