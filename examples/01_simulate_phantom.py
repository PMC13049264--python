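"""Simulate a first-pass perfusion phantom acquisition and inspect it.

Builds a small dynamic contrast phantom (stylized short-axis heart with a
gamma-variate bolus transiting RV -> LV -> myocardium), injects deep
sawtooth breathing motion in k-space, undersamples with golden-angle radial
spokes, and prints the basic bookkeeping.
"""

import numpy as np

from kccmoco import (
    KGrid,
    PhantomConfig,
    SamplingSpec,
    make_motion_trace,
    simulate_dataset,
)
from kccmoco.phantom import LV, MYO, RV

n, n_frames = 128, 16
config = PhantomConfig(n=n, n_frames=n_frames, n_coils=4, cnr=20.0)
motion = make_motion_trace("sawtooth_deep", n_frames)
sampling = SamplingSpec("golden_radial_cartesian", 8, n_frames, KGrid(n, n))

ds = simulate_dataset(config, motion, sampling, seed=7)

print(f"k-space shape (frames, coils, ky, kx): {ds.kspace.shape}")
print(f"samples acquired per frame: {int(ds.masks[0].sum())} of {n*n} "
      f"(acceleration ~{n*n/ds.masks[0].sum():.0f}x)")
print(f"noise std per channel (peak LV amplitude / CNR): {ds.noise_std:.4f}")

for code, name in [(RV, "RV pool"), (LV, "LV pool"), (MYO, "myocardium")]:
    curve = [np.abs(ds.clean_images[t])[ds.label_map == code].mean() for t in range(n_frames)]
    print(f"{name:12s} peak frame {int(np.argmax(curve)):2d}, peak intensity {max(curve):.3f}")

th3 = ds.motion.as_array()[:, 2]
print(f"injected foot-head sawtooth: min {th3.min():+.1f} px, max {th3.max():+.1f} px")
# Expected: RV enhances before LV, LV before myocardium; the sawtooth spans
# the full +-4 px deep-breathing range.
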