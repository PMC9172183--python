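# Methods

`lungwater` quantifies lung water density (LWD) from proton-density-weighted
thoracic MR volumes. At a flip angle of ~1° the reconstructed magnitude
signal is, to good approximation, proportional to mobile water content times
a smooth receive-coil sensitivity. The pipeline turns that proportionality
into an absolute percentage in three steps: segment the lungs, remove the
coil sensitivity by a regularized fit to the body signal, and scale the lung
signal by a hepatic reference assumed to contain 70% water.

## Signal model and coordinate conventions

All volumes live on a fixed anatomical frame: axis 0 runs
anterior→posterior (coronal slice index), axis 1 superior→inferior, axis 2
subject-right→subject-left; voxels are indexed from 0 with physical
positions at voxel centers, converted to mm via the spacing (default 3.5 mm
isotropic). The assumed signal model is

    S(x) = C(x) · WD(x)/100 · S0 + ε,

with `C` a smooth positive coil-sensitivity field, `WD` true water density
in percent, and `ε` additive zero-mean Gaussian noise clipped at zero (a
magnitude-image surrogate; at the simulated SNRs the difference from a
Rician model is negligible for the mean-based read-outs used here, and the
Gaussian keeps analytic oracles simple).

## Lung segmentation

Two interchangeable front ends produce disjoint right/left lung masks.

**Classical (weight-free default).** Body = voxels above the volume mean,
largest connected component; lungs = low-intensity cavities enclosed by the
body, after discarding anything connected to the superior volume face
(airway/trachea); two largest components kept, morphologically closed
(1-voxel ball), laterality assigned by centroid column. This heuristic
requires bright body / dark lungs, which holds for proton-density thoracic
images. Known limitation: because the body threshold is the global mean,
lung voxels whose signal approaches it are clipped from the cavity — on
phantoms this begins to bias the posterior segment once posterior LWD
approaches ~35%. The quantification chain is therefore also exercised with
ground-truth masks, and the intended production segmenter is the network.

**Residual U-Net.** A 2D residual U-Net: input stem, three downsampling
layers, one bridge layer and four upsampling layers, where each layer's
block is two cycles of (batch normalization, 3×3 convolution, leaky ReLU)
inside a residual skip. The fourth upsampling layer is a
resolution-preserving refinement block, since three spatial upsamplings
already restore the input grid. The head is a 1×1 convolution with no
output nonlinearity; its output is treated as logits, so thresholding the
probability map at 0.5 equals `logits > 0`. The network is implemented
directly in numpy (im2col convolutions, hand-derived backpropagation, Adam),
in float32 by default with a float64 mode used by the gradient-check tests;
analytic gradients agree with central finite differences to ~1e-8 in
float64.

Training uses the Soft-Jaccard loss `1 − (Σpg+ε)/(Σp+Σg−Σpg+ε)` with ε = 1,
**aggregated over the batch**: a per-sample formulation starves slices with
empty masks (the gradient on false positives decays as 1/(Σp)², so the
model never unlearns them), while batch pooling keeps those slices under
normal gradient pressure. Data are 96×96 crops of synthetic coronal slices
resampled in-plane to 1.3125 mm (within the recipe's 1–1.5 mm band), split
80/20 into training and validation by exact counts, augmented per epoch
with paired flips, small rotations and scalings (nearest-neighbour for the
mask, which stays binary) and image-only blur and noise. Desk-scale
defaults are batch 4, cosine learning-rate decay from 2e-3, and at most 20
epochs with early stopping on validation Dice; batch 64 remains the
faithful full-scale default in the model configuration. Training slices are
drawn from bone-free phantoms: at 1.3 mm, rib cross-sections are nearly
isointense with lung and abut the lung boundary, a materially harder task
than the easy-geometry floor this recipe targets.

Volume inference runs the fully-convolutional network on each coronal slice
resampled to the training resolution and padded to a multiple of 8,
thresholds, maps masks back to the acquisition grid, stacks them to 3D and
assigns the two largest components right/left by centroid column; slices
with no suprathreshold pixels stay empty.

## Liver reference ROI

The ROI lives in the coronal slice nearest the right lung's 3D centroid.
Its center column is the (continuous) centroid column; the center row sits
exactly 8.75 mm below the bottom-most right-lung voxel of that slice and
column. Membership is the pixelized disc of the prescribed area: the
`N = round(12.5 cm² / voxel area)` in-plane voxels nearest the center —
equivalently all voxel centers within an effective radius. Selecting by
quantized count keeps the realized ROI area within half a voxel of the
nominal 12.5 cm² for every sub-voxel center position, whereas counting
centers inside the nominal radius `r = √(A/π) ≈ 19.95 mm` can deviate by
several voxels depending on where the center falls on the lattice. Because
a 12.5 cm² disc centered 8.75 mm below the lung necessarily overlaps lung
in its upper part, lung-labeled voxels are excluded from the mean, keeping
the reference purely hepatic. The ROI mean is taken on the normalized
image; placement uses raw-geometry masks only.

## Coil-shading normalization

Per coronal slice the normalization map `M` minimizes

    Σ_{x∈body} (M(x) − S(x))² + λ² ‖Δ M‖²

over the full slice grid, with Δ the 5-point discrete Laplacian under
Neumann boundary conditions. The body support is voxels above the volume
mean minus the segmented lungs (largest component). Slices without body
voxels copy the nearest fitted slice; the field is floored at 1e-3 of its
body median before division.

Numerical choices:

* **Intensity pre-scaling.** Slice data are divided by the mean body
  intensity before fitting and the map rescaled afterwards. The Tikhonov
  problem is homogeneous in the data, so this leaves the fit unchanged while
  making the λ grid — and hence every LWD output — exactly invariant to a
  global rescaling of the input image.
* **Coarse grid.** The fit runs on an 8× block-averaged grid (~28 mm
  blocks) and is interpolated back bilinearly. Coil sensitivity varies on
  the scale of coil elements (≥ 80 mm), so the coarse grid samples the field
  generously, while organ-scale anatomy (the liver's 70-vs-85% dip, bowel)
  becomes unfittable at any λ — structure a shading map must not absorb. A
  4× grid was evaluated and rejected: it can still resolve the liver dip,
  which biases regional LWD by 2–3 percentage points at moderate smoothing.
  The factor remains a configuration parameter.
* **Full-resolution residual.** The L-curve residual adds the within-block
  variance of the body signal (a term constant in `M`) to the coarse
  residual, i.e. it is the exact fine-grid residual of the blockwise-
  constant fit. Without it the residual can vanish at small λ and the
  curve's corner disappears.

**λ selection (L-curve).** λ is chosen on a fixed grid of 30 log-spaced
values spanning six decades centered on the geometric mean of the coarse
slice dimensions. For each λ the log residual norm and log Laplacian
seminorm are accumulated over slices; curvature of that curve versus log λ
is computed from Savitzky–Golay local quadratics over a 13-point stencil
(the discrete curvature forms a near-flat plateau spanning about a decade,
and a 3-point estimate picks its maximum from sampling noise). Among
candidates with curvature ≥ 75% of the peak, the largest λ is selected:
on the plateau extra smoothing costs essentially no residual, and
smoothness is the safer prior for a coil field — consistent with the
strongly-smoothed, highly stable per-image optimum the method exhibits in
vivo, which also motivates the exposed fixed-λ mode that skips the search
entirely. A flag is raised if the selected λ sits on the grid boundary.

## LWD map and regional summaries

`LWD(x) = 70 · S(x)/S̄_liver` on lung voxels of the normalized image, NaN
elsewhere, with no clipping (clipping would bias means). Two identities
anchor the scale: a lung voxel whose normalized signal equals the liver
mean maps to exactly 70%, and multiplying the input volume by any k > 0
changes nothing. When the map is a pure coil trend the hepatic assumption
cancels exactly: `M ≈ C·w̄` gives `LWD = 70·(WD/w̄)/(70/w̄) = WD`.

Lung-containing coronal slices, ordered anterior→posterior, are split into
three contiguous groups whose sizes differ by at most one; when the count
is not divisible by 3 the extra slices go to the mid group first, then
posterior, keeping the anterior/posterior extremes — the reported contrast —
balanced. The summary reports global, per-segment and per-lung mean LWD and
the lung volume in liters.

## Synthetic phantoms

**Vial phantom.** Ten 12 mm-radius cylinders at 10–100% water in 10% steps
in a water bath, one flagged as the 100% reference; analysis discs shrink
to 0.8 of the vial radius to stay clear of partial-volume edges. The
validation experiment generates seeded repeats, pools known-vs-measured
pairs for ordinary least squares, Bland–Altman bias/limits of agreement and
ICC(A,1) (two-way mixed effects, absolute agreement, single measures,
computed from the ANOVA mean squares; the choice of the absolute-agreement
variant is deliberate, as known-vs-measured comparisons must penalize
systematic offsets), and reports per-repeat ICCs alongside.

**Thorax phantom.** Ellipsoidal body filling most of a tight field of view,
two ellipsoidal lungs (right larger and lower), a liver block filling the
space directly under the right lung's bottom face (~45 mm deep, fixed at
70% water), an optional airway tube reaching the superior volume face, a
rib cage and vertebral column at 55% water (marrow-containing bone),
smooth soft-tissue heterogeneity (seeded Gaussian random field, 25 mm
correlation length, 6% relative SD, excluded from the liver since it is the
method's reference tissue), and a posterior-weighted sum-of-Gaussians coil
field with a max/min cap. The lung LWD profile is piecewise linear in
slice index through three knots at the centers of the anterior/mid/
posterior slice groups; knot values are solved from a 3×3 linear system so
each group's lung-voxel-weighted mean equals its target exactly (plain
interpolation through the targets leaves a ~0.3–0.6 pp discretization
bias). The supine default targets are (21.2, 23.5, 28.1)%; the prone flag
reverses the gradient. Everything is bit-reproducible per seed.

The anatomy realism matters for one specific reason: with a perfectly
homogeneous body the Tikhonov fit can reproduce the body signal almost
exactly at tiny λ and the L-curve has no meaningful corner. Sub-resolution
bone and tissue texture give the body signal the irreducible structure real
thoraces have, which is what pins the corner at useful smoothing. Bone
water density is set at 55% rather than lower values so bone lies
deterministically inside the mean-threshold body mask; values near the
threshold make rib inclusion a noise lottery that injects seed-dependent
2-pp regional biases.

What the phantoms do **not** emulate: vasculature and lobar fissures,
respiratory and cardiac motion, k-space/reconstruction artifacts, Rician
noise floors, partial-volume mixing at tissue boundaries, and liver
heterogeneity (fat infiltration, iron). Passing tests on these phantoms
therefore demonstrates the correctness of the processing chain under its
own model assumptions, not in-vivo accuracy.

## Problem sizes and runtime choices

The default thorax is 72×112×112 voxels at 3.5 mm; the test suite uses
48×96×96, which preserves every geometric relationship. The segmentation
network trains on 200 slices at 96×96 with batch 4 — a deliberate
desk-scale analogue of the full recipe (16k slices, batch 64), evaluated
against the same Dice floor. The normalization solve factorizes one sparse
~200-unknown system per slice per λ; a full L-curve on the default volume
takes a few seconds on one CPU.

## Known limitations

* The classical segmenter clips high-signal lung at the global-mean
  threshold (see above); it is a convenience front end, not the method.
* The L-curve plateau means λ* is only defined up to roughly a grid step;
  quantification is insensitive to this by design (the plateau choice
  prefers the flat, accurate regime), but reported λ* values should not be
  over-interpreted.
* Regional recovery degrades gracefully with stronger soft-tissue
  heterogeneity than the default 6%; organ-scale anatomy that mimics coil
  shading is a fundamental confound of data-driven normalization.
* ICC(A,1) from mean squares can fall below −1 on adversarial tables; it is
  reported as computed.
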