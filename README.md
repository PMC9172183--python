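# lungwater

Quantitative **lung water density (LWD) mapping** from proton-density-weighted
thoracic MRI, with a fully automated processing pipeline and digital phantoms
for end-to-end validation.

Pulmonary edema — fluid leaking into the lung interstitium — is a hallmark of
heart failure, and its *redistribution* (with posture, or exercise) carries
diagnostic information. At low flip angle the MR magnitude signal is
proportional to mobile water content times a smooth receive-coil sensitivity
`C(x)`:

```
S(x) ≈ C(x) · WD(x)/100 · S0
```

The package computes, per lung voxel, the water density in percent

```
LWD(x) = 70 · S̃(x) / S̃_liver
```

where `S̃` is the image after dividing out a coil-shading normalization map —
fitted per coronal slice to the body signal by Tikhonov-regularized least
squares, `min Σ_body (M−S)² + λ²‖ΔM‖²`, with the smoothing parameter chosen
by the L-curve criterion — and `S̃_liver` is the mean over a circular
12.5 cm² reference region placed automatically in the liver, 8.75 mm below
the bottom of the right lung, under the assumption that hepatic tissue is
70% water. Summaries report global, left/right, and anterior/mid/posterior
mean LWD (three contiguous coronal slice groups of equal size), which
captures the gravity-dependent fluid gradient: supine, the posterior lung is
wettest; prone, the gradient flips.

Lung masks come from either a weight-free classical pipeline
(threshold + cavity analysis) or a 2D **residual U-Net** (3 downsampling
layers, bridge, 4 upsampling layers; blocks of two batch-norm/conv/leaky-ReLU
cycles; Soft-Jaccard training loss) implemented in pure numpy and trainable
on synthetic slices in minutes on a CPU.

Because no public datasets exist for this problem, the package ships
generators for two digital phantoms with exact ground truth: a 10-vial
water/D2O dilution phantom (10–100% in 10% steps) and a thorax with lungs,
liver, airway, rib cage, soft-tissue texture, a prescribed regional LWD
gradient, coil shading and noise. See `docs/methods.md` for the model and
all numerical choices.

## Worked example

```bash
python examples/thorax_pipeline.py
```

```
selected smoothing lambda*      5.873 (L-curve, boundary warning: False)
liver ROI: slice 23, area 12.495 cm^2, mean signal 0.879
lung volume                     1.13 L

               estimated   truth
  global LWD     23.91%       -
  anterior LWD   20.79%     21.20%
  mid LWD        23.32%     23.50%
  posterior      28.15%     28.10%
```

The phantom was built with anterior/mid/posterior LWD of
(21.2, 23.5, 28.1)% under coil shading and noise; the pipeline recovers the
regional means to a few tenths of a percentage point, and the liver-ROI area
lands within half a voxel of the nominal 12.5 cm². Other examples:
`examples/vial_phantom_validation.py` (dilution-series agreement
statistics), `examples/gravity_gradient.py` (supine/prone sign flip),
`examples/train_segmentation.py` (desk-scale U-Net training).

## Command line

```bash
lwd simulate --preset supine --seed 1 --out-dir phantoms/
lwd run --input phantoms/thorax.nii.gz --seg classical \
        --lambda lcurve --out report.json --overlay lwd.nii.gz
lwd phantom --repeats 3 --noise 0.02 --seeds 1,2,3 --out stats.json
lwd train-seg --slices 200 --epochs 20 --seed 1 --out model.npz
```

Reports are JSON with the full resolved configuration; overlays are NIfTI
LWD% maps with non-lung voxels set to −1.

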