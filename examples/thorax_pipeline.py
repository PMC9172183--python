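"""Quantify lung water density in a synthetic thorax, end to end.

Generates a supine thorax with a known anterior/mid/posterior LWD gradient,
coil shading and noise; runs classical segmentation, automatic liver-ROI
placement, L-curve-selected coil-shading normalization, and regional
summaries; prints the estimates next to the generator's ground truth.
"""

from lungwater import run_pipeline
from lungwater.synthetic import ThoraxTruth, generate_thorax_phantom

truth = ThoraxTruth(shape=(48, 96, 96), noise_sd=0.01, seed=1)
volume, labels, realized = generate_thorax_phantom(truth)

result = run_pipeline(volume, segmentation_mode="classical")
reg = result.regional
report = result.report

print(f"selected smoothing lambda*      {report['lambda']:.3f} "
      f"(L-curve, boundary warning: {report.get('lambda_warning')})")
print(f"liver ROI: slice {result.roi.slice_index}, "
      f"area {result.roi.pre_exclusion_area_cm2:.3f} cm^2, "
      f"mean signal {result.lwd_map.liver_mean:.3f}")
print(f"lung volume                     {reg.lung_volume_l:.2f} L")
print()
print("               estimated   truth")
for name, est, true in [
    ("global LWD  ", reg.global_mean, None),
    ("anterior LWD", reg.anterior, realized.regional_means[0]),
    ("mid LWD     ", reg.mid, realized.regional_means[1]),
    ("posterior   ", reg.posterior, realized.regional_means[2]),
]:
    true_s = f"{true:6.2f}%" if true is not None else "   -"
    print(f"  {name}  {est:6.2f}%    {true_s}")
print()
print("LWD is percent water per lung voxel, anchored to a 70% hepatic")
print("reference; in the supine posture the posterior segment is wettest —")
print("the gravity-dependent fluid gradient the method is built to image.")
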