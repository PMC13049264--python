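# kccmoco

Rigid inter-frame respiratory motion correction for highly accelerated
dynamic contrast-enhanced (first-pass perfusion) cardiac MRI, formulated
entirely in k-space — together with the digital perfusion phantom and the
evaluation suite used to validate it.

## The problem

Free-breathing first-pass perfusion CMR acquires one heavily undersampled
k-space frame per heartbeat while a contrast bolus transits the heart.
Respiration displaces the heart between frames, and any reconstruction or
quantification that assumes aligned frames degrades badly. Image-based
registration needs an initial reconstruction, which is exactly what is
untrustworthy at accelerations of 10–50×. This package estimates and
corrects the inter-frame rigid motion *before* any reconstruction, directly
on the multi-coil undersampled k-space, so that model-based or learned
reconstructions can start from motion-consistent data.

## The method

A rigid motion of the object maps onto k-space without leaving it: a
rotation of the image rotates k-space identically, and a translation
becomes a linear phase ramp,

    S_c(k; Θ) = S_m(R_Θᵀ k) · exp(j 2π Θ_Tᵀ k),      Θ = (θ₁; θ₂, θ₃).

Each frame's k-space S_m is registered to a **synthetic reference**
S_f(k) = G₁(k) · mean_t S(k, t) — the pointwise temporal mean of the
coil-compressed k-space weighted by a Gaussian G₁ (σ = 20 Δk) that damps
high spatial frequencies where rotating radial patterns rarely coincide.
The similarity metric is a Gaussian-normalized cross-correlation evaluated
in k-space (by Parseval's theorem the k-space inner product equals the
image-domain one), with a Gaussian-weighted mean removal suppressing the
contrast-change energy near the k-space center:

    V(Θ) = Σ_k X̃_f(k) X̃_c*(k; Θ) / sqrt(Σ|X̃_f|² Σ|X̃_c|²),
    Θ̂    = argmin_Θ  −|V(Θ)|².

Per frame the estimate runs in two stages — rotation first (on the
translation-invariant k-space magnitude correlation, evaluated on the
frame's transported sampling support), then translation on the
rotation-corrected k-space — each solved with a Polak–Ribière nonlinear
conjugate gradient with Armijo backtracking. The rotation itself is applied
by the exact FFT 3-shear decomposition (no spatial interpolation anywhere),
and the final parameters are applied coil-by-coil to the original
multi-coil k-space.

The pipeline in front of the estimator: zero-filled sum-of-squares
reconstruction → automatic heart-ROI detection (largest connected region of
high temporal standard deviation, 80×80 px window) → ROVir compression of
the coils into a single virtual coil whose image energy is maximized inside
the ROI (generalized eigenproblem on the coil Gram matrices).

The phantom module simulates the whole study: a stylized short-axis slice
(RV/LV pools, myocardial annulus, epicardial and chest-wall fat, spine,
liver, textured torso), a gamma-variate bolus, smooth complex coil maps,
per-frame rigid motion injected in k-space, complex Gaussian noise scaled
by a CNR parameter, and golden-angle radial / pseudo-spiral /
Gaussian-variable-density (k,t)-undersampling.

## Worked example

`examples/03_full_pipeline_breathing.py` injects a deep-breathing sawtooth
(foot–head translation between −4 and +4 px) into a 128×128, 16-frame,
4-coil phantom and runs the full pipeline:

```
frame  injected  estimated
   6     +4.00     -3.93
   7     +0.00     +0.05
   8     -4.00     +4.04
   ...
foot-head tracking RMSE: 0.069 px
SSIM vs ground-truth-corrected average: corrected 0.9878, uncorrected 0.8573
```

The estimated correction is (minus) the injected motion to within a tenth
of a pixel, and the temporal average after correction is nearly
indistinguishable from the average obtained with the exact ground-truth
correction, while the uncorrected average is visibly blurred. The other
examples cover phantom simulation (`01`), single-frame estimation (`02`),
effective acceleration of the synthetic reference (`04`) and the evaluation
metrics with myocardial sector curves (`05`).

## Command line

The same pipeline is scriptable from the shell around an HDF5 container:

```
kccmoco simulate --config c.yaml --out d.h5 --seed 7
kccmoco moco --in d.h5 --out corrected.h5 --params params.csv
kccmoco eval --corrected corrected.h5 --truth d.h5 --report report.json
```

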