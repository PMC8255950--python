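"""Sparse-view dynamic CT: FBP vs Tikhonov vs TV vs directional TV.

Generates a 17-frame gel phantom with contrast diffusing into five
cavities, simulates a 360-angle parallel-beam scan with 1% Gaussian noise,
keeps only every 20th projection (18 views - a 20x dose/time reduction)
and reconstructs with four methods.  The mean PSNR ordering
dTV >= TV >= Tikhonov >= FBP shows how much prior structure buys at high
undersampling; the time-activity curve tracks the contrast uptake in one
cavity.
"""

import numpy as np

from multitomo import make_dynamic_gel_phantom, run_dynamic_comparison

truth = make_dynamic_gel_phantom(num_frames=17, size=64, n_cavities=5,
                                 seed=0)
report = run_dynamic_comparison(truth, angle_step=20, seed=7)

print("Dynamic gel phantom, 64x64, 17 frames, 18 of 360 projections")
print(f"  sinogram noise sigma = {report.parameters['sigma']:.3f} "
      "(1% of the peak line integral)\n")
print("  method     mean PSNR   mean SSIM")
for method in ("fbp", "tikhonov", "tv", "dtv"):
    print(f"  {method:9s} {report.mean_psnr[method]:8.2f} dB"
          f"   {report.mean_ssim[method]:8.3f}")
print("\n  dTV uses noiseless dense-angle FBP reconstructions of the first"
      "\n  and last frames as structural references, so its edges stay"
      "\n  circular even at 18 views; TV suppresses streaks but loses"
      "\n  contrast; Tikhonov oversmooths; FBP streaks badly.")

_, truth_curve = report.extras["truth_curve"]
print("\n  centre-of-cavity time-activity curve (frames 0, 8, 16):")
print(f"  truth: {truth_curve[0]:.3f}  {truth_curve[8]:.3f}  "
      f"{truth_curve[16]:.3f}")
for method in ("fbp", "tv", "dtv"):
    _, curve = report.curves[method]
    osc = np.abs(np.diff(curve)).sum() - abs(curve[-1] - curve[0])
    print(f"  {method:5s} {curve[0]:.3f}  {curve[8]:.3f}  {curve[16]:.3f}"
          f"   (excess oscillation {osc:.3f})")
print("  regularized curves track the monotone uptake; sparse-view FBP "
      "oscillates")
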