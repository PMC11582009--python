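# Methods

This note records the modelling assumptions, numerical choices and open
design decisions behind the package, in the order the pipeline runs.

## SWC model

A morphology is an ordered table of nodes (id, structure type, x/y/z in µm,
radius, parent).  Validation enforces unique ids, existing parents and an
acyclic parent relation; multiple roots are accepted as a forest with a
warning, because repository reconstructions vary in quality.  Structure type
codes are carried but not used by projection: all node types are rendered
identically, and the soma is drawn as a point like any node (no
radius-scaled disc).  No repair or resampling of arbors is attempted.

## Canonical alignment and projection

PCA alignment maps the largest-variance axis to x, second to y, third to z,
centroid to the origin.  Eigenvector sign is inherently ambiguous, so each
axis is oriented to make the coordinate skewness along it nonnegative; for
near-symmetric clouds (|skewness| < 1e−9) the largest-magnitude loading is
forced positive instead.  This gives a deterministic frame, which is what
makes "similar neurons produce similar views" testable.  Degenerate
(colinear/coplanar) clouds are handled by the orthonormal basis the
symmetric eigendecomposition returns for zero eigenvalues.

Rotations are right-handed, active, column-vector; the composite view
rotation is R_z(θ)·R_y(θ) with the y-rotation applied first.  The projection
plane is x–y.  θ steps through k·ϕ for k = 0…⌊360/ϕ⌋−1, so non-divisor ϕ
values are legal.

Rasterization min–max scales the projected cloud isotropically to fit a
square image (default margin 5% per side), plots every node and draws every
child–parent segment with Bresenham's algorithm (line thickness 1 px by
default; SWC radii are ignored since binary images carry no thickness
semantics).  A single point renders as one centred pixel.  Images are
strictly {0, 1}.

## View descriptors

The backbone is a contract (ingest 1- or 3-channel images, emit a
nonnegative C×H×W map), not a fixed network.  The default is a seeded
two-convolution network (3×3, stride 2, ReLU; C = 16) so everything runs on
one CPU in seconds.  The 50-layer residual network used at full scale in the
literature requires an external framework and is deliberately not bundled;
`build_backbone("resnet50")` raises a clear error and any user module with
the same contract can be plugged in.

GeM pooling is computed as m·(mean((x/m)^p))^{1/p} with m the per-channel
max — algebraically identical to the power mean for any positive constant,
and immune to overflow at p as large as 1e6 (which the limit tests use).
Features are clamped at 1e−6 before the fractional power; p is a single
shared learnable scalar initialised to 3 (per-channel optional, both
exposed because the original setting is unstated) and clamped at 1e−2
during optimisation.  A batch-normalization layer unifies descriptor scales
across views; in eval mode it is a frozen affine map, making inference
deterministic.

## Measurement gate (GVMM)

Raw post-activation feature maps are unbounded, while the salience
threshold T₁ sweeps 0.1–0.9 in the literature, which presupposes a [0, 1]
range; maps are therefore min–max normalised per view before masking
(per-channel normalisation is available behind a flag).  The mask keeps
entries ≥ T₁ (boundary kept) over all of C×H×W and is treated as a constant
during backpropagation (straight-through on the kept entries); min/max are
likewise treated as constants, which leaves gradients exact up to the
normalisation scale.

The scoring head follows the textual description: 1×1 conv C→C/2, flatten,
batch normalization, FC to one output.  The published parameter increase for
this module (~0.002 M) is irreconcilable with that wiring at C = 2048
(≈2 M); a `head="pooled"` variant (spatial mean then FC C→1, exactly
C+1 ≈ 0.002 M parameters) is provided, defaulting to the textual wiring.
The score is d = σ(log(|s| + ε)) with ε = 1e−12 — small enough that
d(s=1) = 0.5 to better than 1e−9 while still defining d at s = 0.  Scores
are not renormalised across views before fusion.

## Enhancement gate (GVEM)

L₁–L₃ are linear C→C maps (1×1 convolutions over descriptor channels) with
the same batch normalization as the encoder.  Similarities use unscaled dot
products (no √C scaling) under a row softmax, so A is row-stochastic by
construction.  The gating formula as printed in the source combines the two
masked branches in a way that leaks exp(0) = 1 from each mask's complement;
the implementation uses the two-branch elementwise reading
b_ij = exp(−a_ij) on M₁, exp(a_ij) on M₂ — which matches the stated intent
(suppress redundant pairs, amplify dissimilar ones) — followed by a row
softmax.  The literal algebraic reading is kept behind `literal_eq6=True`.
Boundary entries a_ij = T₂ fall in M₁.

## Fusion head

X_t = D·X′ is a weighted *sum* over views (1×N by N×C), not a
concatenation: D is a vector of scalars and the classifier input dimension
is fixed.  "Residual batch normalization" is implemented minimally as
BN(D·X′ + mean_n(x_n)) with both the residual and the BN toggleable.  The
classifier is FC→200, ReLU, FC→200, then a linear softmax layer over K
classes (whether the original puts a nonlinearity between the two 200-unit
layers is unstated; one ReLU is used).  Manual view-weight vectors bypass
the measurement gate for ablations.  With both gates off the model is the
baseline: D = 1, A′ = I, X′ = X.

## Training and evaluation

All trainable components run on the package's numpy reverse-mode autograd
(validated against central finite differences in the test suite).  Loss is
cross-entropy, optimiser Adam (lr 0.001, batch 16); training aborts on a
non-finite loss.  Cross-validation is stratified k-fold (k = 10) — the
source says only "randomly divided", but stratification prevents empty-class
folds at desk scale.  Metrics are computed from the confusion matrix by the
package itself (accuracy = trace/total; macro-F1 = unweighted mean of
per-class F1, the averaging scheme being unstated in the source);
scikit-learn serves as an independent oracle in tests only.  Epoch count is
a config default of 50 for synthetic runs.  All randomness flows from one
integer seed; two runs with the same config and seed are bit-identical on
CPU.

## Synthetic data

The generator emulates labeled SWC trees whose classes differ in branching
statistics: fixed-length jittered elongation steps, direction blended with
a class trunk bias plus isotropic noise, bifurcation with class probability
up to a maximum branch order, split angle 40° mean.  Class presets were
chosen once to be morphologically plausible at desk scale (tens to ~1300
nodes per tree) and are deliberately separable by branch count alone
("separable-3") or deliberately overlapping ("confusable-2").  What a green
end-to-end test establishes is that the pipeline learns branching-statistic
differences from binary projections; it does not establish performance on
real repository data, where reconstruction quality, incomplete arbors and
subtler class differences dominate.

## Known limitations

- No pretrained backbone ships with the package, so absolute accuracies on
  real datasets are not comparable to GPU-scale published numbers.
- The numpy engine is single-threaded and desk-scale; image sizes beyond
  ~128 px with the tiny backbone get slow.
- The GVMM mask is non-differentiable (straight-through); a learned
  threshold is explicitly out of scope.
- View caching keys on the node table hash and projection settings only.
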