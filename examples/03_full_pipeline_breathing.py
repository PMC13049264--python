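"""Run the complete motion-correction pipeline on a breathing phantom.

Deep sawtooth breathing (foot-head translation between -4 and +4 px) is
injected frame by frame; the pipeline detects the heart ROI, compresses the
coils into one heart-weighted virtual coil, builds the synthetic k-space
reference and registers every frame to it.  The printout compares the
estimated foot-head trace with the injected one and shows the sharpening of
the temporal average.
"""

import numpy as np

from kccmoco import (
    ComplexKFrame,
    KGrid,
    PhantomConfig,
    SamplingSpec,
    apply_rigid,
    invert_rigid,
    kccmoco_run,
    make_motion_trace,
    simulate_dataset,
    sos_reconstruct,
)
from kccmoco.evaluation import ssim, temporal_average

n, n_frames, n_coils = 128, 16, 4
grid = KGrid(n, n)
config = PhantomConfig(n=n, n_frames=n_frames, n_coils=n_coils)
ds = simulate_dataset(
    config, make_motion_trace("sawtooth_deep", n_frames),
    SamplingSpec("full", 1, n_frames, grid), seed=3,
)

corrected, params, diag = kccmoco_run(ds.kspace, masks=ds.masks)

est = np.array([p.theta3 for p in params])
gt = ds.motion.as_array()[:, 2]
rmse = np.sqrt(np.mean((est + gt) ** 2))  # the correction is minus the motion
print("frame  injected  estimated")
for t in range(n_frames):
    print(f"{t:4d}   {gt[t]:+7.2f}   {est[t]:+7.2f}")
print(f"foot-head tracking RMSE: {rmse:.3f} px")

# image-quality direction: corrected average closer to ground-truth-corrected
gt_ks = np.empty_like(ds.kspace)
for t in range(n_frames):
    inv = invert_rigid(ds.motion.params[t])
    for c in range(n_coils):
        gt_ks[t, c] = apply_rigid(ComplexKFrame(ds.kspace[t, c], ds.masks[t], grid), inv).data
omega = diag["roi"].omega_mask((n, n))
ref_avg = temporal_average(sos_reconstruct(gt_ks), omega)
print(f"SSIM vs ground-truth-corrected average: "
      f"corrected {ssim(temporal_average(sos_reconstruct(corrected), omega), ref_avg):.4f}, "
      f"uncorrected {ssim(temporal_average(sos_reconstruct(ds.kspace), omega), ref_avg):.4f}")
# Corrected SSIM should clearly exceed the uncorrected value.
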