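# Methods

This note documents the models, numerical choices and limitations of
`snakereg`, a weakly supervised deformable 3-D registration package.

## Problem and conventions

Deformable registration seeks a displacement field u that aligns a moving
image I_m with a fixed image I_f by minimizing

    E(u) = D(I_f, I_m ∘ (id + u)) + λ R(u),

where D is an image dissimilarity and R a smoothness penalty.  Throughout
the package grids are voxel-indexed and 0-based with axis order (d, h, w);
fields are stored channel-first `(3, D, H, W)` with components
(du_d, du_h, du_w) **in voxel units**, and warping follows
`warped(p) = moving(p + u(p))` with trilinear (images) or nearest (labels)
interpolation and border-clamped sampling.  Voxel units (rather than
normalized grid units or millimetres) make the synthetic oracles exact and
keep the Jacobian analysis free of spacing factors; header affines are
round-tripped but never used for resampling.

Folding is quantified by the Jacobian determinant of p ↦ p + u(p), computed
with central differences in the interior and one-sided differences at the
boundary; the reported statistic is the fraction (printed as a percentage)
of voxels with det ≤ 0.  For any affine displacement u = (A − I)p the
discrete determinant equals det(A) exactly at interior voxels, which the
tests exploit.

## Automatic differentiation

No deep-learning framework is used: the package carries a compact
reverse-mode autodiff engine (`snakereg.autodiff`) over float32 numpy
arrays.  Heavy volumetric primitives — 3-D convolution (im2col + BLAS),
trilinear grid sampling, cubic box sums and Gaussian window filters — are
single tape nodes with hand-written adjoints; box and Gaussian filters are
symmetric under zero padding and therefore self-adjoint.  Every adjoint is
checked against central finite differences in the test suite.  Containers
(`Volume3D`, `DisplacementField`) hold float64 for exact geometry oracles;
network and loss computation is float32.

## Dynamic snake convolution (DSConv3D)

The 3×3×3 kernel is linearized along each grid axis into a
`points_per_kernel`-tap (default 9) polyline.  At step c from the center
the two lateral coordinates carry the running sum of the first c learned
per-step offsets of that side; the center tap is fixed.  Offsets are
predicted from the operator's own input by a zero-initialized 3×3×3
convolution and squashed by `max_step · tanh` (default bound: 1 voxel per
step), so training starts from straight, axis-aligned kernels and offsets
can never exceed the bound.  Fractional positions are read by trilinear
interpolation with border clamping.  With 9 taps and unit bound the three
axis-variants together reach exactly a 9×9×9 cube (verified analytically
and by exhaustive enumeration).  Each axis-variant applies its own
tap-weight matrix (independent channel mixing); the three responses are
fused by averaging by default, with summation and concat-plus-pointwise
fusion as options.  A loop-based reference implementation ships in the
package and anchors the operator tests.

Design points the operator's published description leaves open, resolved
here: the cumulative sums run outward from the fixed center one side at a
time (the printed index form mixes conventions and is not reproducible
literally); the offset predictor sees the operator's input features; and
per-axis channel mixing is independent.

## Shifted-window transformer backbone

Tokens live channels-last on coarse grids.  Patch embedding flattens
non-overlapping 2-channel 4×4×4 patches (128 values) to C channels
(default C = 48).  Blocks are pre-norm residual: window attention, then a
GELU MLP.  Window attention uses relative-position bias; odd grids are
right-padded, padded keys are masked out, and the partition/reverse pair is
an exact bijection for every shift (property-tested).  Shifted blocks use
window//2 cyclic shifts with the standard region masks so wrapped content
never mixes.  Patch merging concatenates 2×2×2 token neighbourhoods in
(d, h, w) scan order and projects 8C → 2C; expansion projects C → 4C and
redistributes into a 2×2×2 neighbourhood at C/2, cropping any padding.
Defaults: depths (2, 2, 4, 2), heads (4, 4, 8, 8), window 2×4×4, MLP ratio
4 — all configurable; the published architecture does not fix them.

## Network assembly

Encoder: patch embed → four swin stages with merges between.  Decoder:
expands with (a) plain token skips at the deeper stages and (b) a
multi-fusion dense skip at the /4 stage, where VGG-style branches
(two conv-norm-ReLU layers per halving, then 2× average pooling) pull the
full- and half-resolution stem features down to token scale, concatenate
with the decoder and encoder features and fuse through two Conv3D blocks.
A convolutional stem on the stacked pair provides those skip features
(16 channels at full resolution; C/2 at half resolution after pooling).
The stem sees both images — the published description mentions only the
moving image, but the decoder cannot localize correspondence without the
fixed image; this is a deliberate deviation recorded here.

The head restores the /4-scale C-channel map to full resolution in two
upsample-conv stages: a Conv3D block (3³ kernel, stride 1, padding 1, norm,
ReLU), then a block whose convolution is the DSConv3D operator, each
followed by concurrent spatial & channel squeeze-and-excitation (channel
gate: global-average-pool → bottleneck MLP → sigmoid; spatial gate: 1×1×1
convolution → sigmoid; fused by elementwise max).  A final 3³ convolution
with 3 output channels emits the field.  This layer is zero-initialized so
an untrained network is exactly the identity transform — the stable
starting point for both training and refinement.  Because batch size is 1,
"batch" normalization is implemented as per-channel spatial normalization
(exactly what batch statistics degenerate to at batch size 1), with a
group-norm option.

`flow_gain` applies a fixed multiplier to the zero-initialized field head.
Adam moves each weight by at most ~lr per step regardless of gradient
scale, so at short training budgets the emitted field grows only
~lr · steps · fan-in; the gain is the standard per-layer compensation that
lets desk-scale runs traverse a useful field range without touching the
published learning rate.  Default 1.0.

## Losses

* **Local NCC** (similarity in [0, 1]): per-voxel windowed squared
  correlation, window n³ with n = 9 by default (the publication leaves n
  unstated; 9³ is the community default for brain MRI).  Window statistics
  use fixed-count box sums with zero padding; both images are pre-centered
  by their global means so float32 cancellation stays below 1e-6.  The
  variance-product guard is a *clamp* `max(var_f · var_w, ε)`, ε = 1e-5:
  away from the guard the measure is the exact correlation ratio, so
  identical images sit at a true zero-gradient optimum (an additive ε would
  leave a rounding-scale gradient that Adam amplifies to full-size steps).
* **Smoothness**: mean squared forward-difference gradient of the field,
  summed over components and axes.  A uniform translation scores 0; a unit
  slope of one component along one axis scores exactly 1.
* **Refinement energy**: (1 − NCC) + w_reg · smoothness (w_reg = 1 by
  default), written as a minimizable dissimilarity; an optional
  (1 − SSIM) term can be added (`ssim_weight`, default 0 — where SSIM
  enters the published pipeline is ambiguous, so the hook exists but is off).
* **Supervised loss**: mean (φ − φ_opt)² over all voxel-components plus
  λ · smoothness(φ) with λ = 0.02; the pseudo target is a constant.  All
  sums are normalized to means so losses are resolution independent; λ is
  kept at its published value.
* **SSIM**: Gaussian-windowed (σ = 1.5) with the standard stabilization
  constants; differentiable end to end.
* **Dice**: per foreground label 2|A∩B|/(|A|+|B|); labels absent from both
  maps are excluded; the mean is over present labels.

## Instance optimization and weak supervision

`instance_optimize` treats the field as the sole parameter and runs n Adam
steps (defaults n = 10, lr 0.1, betas (0.9, 0.999)) on the refinement
energy, returning the refined field; the initial field is copied, never
mutated, and refinement aborts on non-finite energy.  When the gradient
falls to pure float32 rounding noise (max |g| < 1e-6) the loop stops —
otherwise Adam's normalized steps would random-walk a converged field.

A training step predicts φ, detaches it, refines the copy into φ_opt, and
updates the network (Adam, lr 1e-4) on the supervised loss.  Detaching
guarantees no gradient flows from the pseudo label into the network.  A
confidence gate accepts φ_opt only if it does not worsen the energy
(threshold configurable, default 0); rejected labels fall back to
self-supervision (the loss degenerates to λ · smoothness).  With n = 0 the
loop supervises φ with itself — a tested identity.  The refinement runs
per training step; the alternative per-epoch reading of the published
schedule is configurable by calling the refiner outside the loop.

Augmentation is exact and label-safe: random axis permutations (90°
rotations, cubic grids) and flips applied jointly to images and labels.
Validation selects the best checkpoint by mean Dice on held-out cases.

## Synthetic data

Phantoms: 4 strictly nested random ellipsoidal shells (cortex / white
matter / ventricle-like), labels 1–4 over background 0, per-structure mean
intensities in (0, 1], Gaussian noise (sd 0.05) and slight smoothing
(sd 0.5).  Fields: per-component Gaussian-smoothed white noise (smoothing
sd 4 voxels) rescaled to a maximum magnitude of 2 voxels, verified
fold-free by an exhaustive determinant scan with automatic 20% amplitude
back-off.  A case pairs a phantom (moving) with its warp under a known
field (fixed), so ground truth exists exactly: warping the moving labels
with the true field reproduces the fixed labels voxel-for-voxel in nearest
mode (Dice 1, 0% folding) — the generator's own acceptance test.  What the
phantoms do not emulate: MRI physics (bias fields, modality contrast),
skull or background anatomy, inter-subject topology differences; passing tests
show algorithmic correctness and desk-scale learnability, not clinical
performance.

## Problem sizes

All defaults are desk-scale by design: unit tests run at 4³–16³; operator
oracles at 6³; field-recovery experiments at 32³ (200 refinement
iterations); the scaled-down training study uses twenty 24³ cases for 30
epochs with a reduced network (C = 12, depths (1, 1), window 2³, 3-tap
snake kernels, 6-channel stem/head) — the full-width architecture is
identical in structure and is exercised at 16³–32³ in shape and gradient
tests.

## Known limitations

* The engine is single-threaded numpy; wall-clock scale is desk-level.
  Full-resolution (160×192×224) training is out of scope.
* Displacement fields are predicted directly (no diffeomorphic
  integration); invertibility is monitored, not enforced.
* NCC border windows see zero padding (fixed-count convention); values at
  the border are consistent but not identical to truncated-window
  statistics.
* SSIM boundary handling is zero-padded Gaussian filtering; interior
  values match scikit-image, borders differ by design.
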