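# Methods

This note documents the models, conventions and numerical choices behind
`kccmoco`, and what its synthetic-data validation does and does not show.

## Fourier conventions and exact rigid transforms

All k-space arrays are even-sized and centered: k = 0 sits at array index
`(n//2, n//2)` and coordinates are `{-N/2, ..., N/2-1}/N` cycles per pixel.
The forward transform is orthonormal and uses the `e^{+j2πkx}` analysis
kernel, chosen so that multiplying k-space by
`exp(+j2π(θ₂k_x + θ₃k_y))` moves the image toward the positive x
(columns, right–left) and y (rows, foot–head) axes for positive parameters;
the shift-theorem tests pin the sign down. With the standard `e^{-j2πkx}`
kernel the same phase would shift the other way.

Rotation is the 3-shear decomposition
`R(θ) = Shear_x(-tan θ/2) · Shear_y(sin θ) · Shear_x(-tan θ/2)`, each shear
realized as a bank of 1D FFT phase ramps. No spatial interpolation occurs
anywhere, each pass is exactly unitary (energy is conserved to machine
precision), and the decomposition is restricted to |θ| < π/4 — far beyond
the ≲ 0.1 rad of respiratory motion. Shears are circular: content that
crosses an array border wraps. For objects surrounded by air inside the
field of view (every MRI use case, and the phantom) the wrap is confined to
negligible-magnitude border content; the accuracy tests therefore evaluate
the central half of the field of view, and a `pad=True` option embeds the
array in a 2× zero-padded field for larger angles. Binary sampling masks
are transported through the same shear sequence and thresholded at 0.5
magnitude, so downstream consumers keep a consistent sampling pattern.

The rigid composition is rotation first, then translation; `invert_rigid`
returns the exact group inverse (θ₁' = -θ₁, t' = -R(-θ₁)t).

## Sampling schemes and the effective acceleration

Golden-angle radial masks advance a *global* spoke counter by 111.246° per
spoke across frames, so patterns rotate from frame to frame; spokes are
diameters through k = 0, rasterized by nearest-neighbor assignment of N
equispaced radial samples. Pseudo-spiral arms are Archimedean with 1.5
turns by default (a larger turn count saturates the grid and destroys the
variable-density profile) and rotate per arm and per frame by the golden
angle. Gaussian variable-density sampling draws distinct full-readout rows
without replacement with probability ∝ exp(-offset²/2σ²), σ = N/6.

`effective_af` measures how well the *union* of all frames' masks covers
the region where the Gaussian reference weight (σ = 20 Δk) is at least 10%
of its maximum: region points divided by region points sampled at least
once. At 4 spokes/frame × 32 frames on a 200² grid this is ≈ 1.08 — the
synthetic reference is effectively almost fully sampled where it matters,
even though each frame alone is undersampled ~50×.

## The phantom

The generator emulates an ECG-triggered free-breathing first-pass
perfusion acquisition on a stylized 2D short-axis slice; defaults are a
200×200 matrix (320 mm FOV at 1.6 mm), 32 frames, 16 coils.

* **Anatomy.** Elliptical torso with a chest-wall fat rim and a spine; RV
  pool abutting the myocardial annulus (septum side) around the LV pool; an
  epicardial fat ring; a liver block; and a fixed field of smooth Gaussian
  blobs texturing torso and liver. The static bright structures and texture
  matter: real thoraxes carry abundant time-invariant k-space content that
  anchors inter-frame registration, and a phantom made only of uniform
  dynamic regions would misrepresent the problem (the bolus would be almost
  the entire signal and any correlation metric would track it). The heart
  sits near — deliberately not exactly at — the image center, as in a
  planned short-axis acquisition; the residual offset keeps automatic ROI
  detection meaningful.
* **Bolus.** Per-tissue gamma-variate enhancement
  `baseline + A·(t/αβ)^α e^{α-t/β}` (peak at delay + αβ), timed so the RV
  enhances first, then the LV, then the myocardium, with the myocardial
  peak well below the LV peak. Pools enhance 5× over baseline, myocardium
  ~1.5×.
* **Coils.** Gaussian magnitude lobes centered on a ring around the FOV
  with gentle coil-specific linear phases; the sum-of-squares magnitude is
  strictly positive everywhere.
* **Motion.** Injected frame-by-frame *in k-space* with the same exact
  operators the estimator uses. `random_rigid` draws translations from
  U(−4, 4) px per axis and rotations from U(−r, r) with r = 0.05 rad by
  default (the rotation range is a config knob). The breathing patterns are
  asymmetric sawtooths in the foot–head translation only: period 8 frames,
  rise/fall quantized to 6/2 intervals on the frame grid, amplitude ±1 px
  (shallow) or ±4 px (deep), with both extremes attained exactly.
* **Noise.** Complex Gaussian with per-channel std = (peak LV enhancement
  amplitude)/CNR, added before the sampling mask is applied. CNR = ∞
  disables noise. The empirical std matches the configured one to < 0.1%.
* **Determinism.** (config, motion, sampling, seed) fully determine the
  dataset bit-for-bit.

What the phantom does **not** model: Bloch/saturation-recovery signal
formation (TR/TE/TS are metadata only), through-plane motion, cardiac-phase
jitter, elastic deformation of the abdomen, and anatomical detail beyond
the stylization above. Tests passing on this phantom show that the
estimator recovers rigid inter-frame motion under realistic undersampling,
contrast dynamics and noise — not that it survives through-plane motion or
non-rigid deformation, which rigid correction cannot represent.

## ROI detection and ROVir compression

The heart is localized on the zero-filled sum-of-squares series as the
largest 8-connected component of the Otsu-binarized temporal
standard-deviation map; an 80×80 px window is centered on its centroid
(clamped to the grid), and can be supplied manually instead. ROVir builds
the coil Gram matrices A (over the ROI Ω) and B (over its complement Φ)
from the *time-averaged* zero-filled coil images — averaging suppresses
undersampling artifacts; a per-frame accumulation mode exists — and keeps
the leading unit-norm eigenvector of `A w = λ(B + εI) w`,
ε = 1e-6·tr(B)/n_coils. Only the top virtual coil is retained.

## The estimator

The reference is built once per run: `S_f = G₁ · mean_t S(k,t)` over the
zero-filled virtual-coil frames, G₁ Gaussian with σ = 20 Δk. The GNCC
used for translation follows the weighted-mean-removal form: the G-weighted
scalar mean `m_X = ΣGX/ΣG` is subtracted as `m_X·G(k)` (config enum also
offers plain scalar subtraction, a pointwise `(1-G)X` central-component
removal, and no centering), and the objective is `−|V|²`, so a global phase
between frame and reference is ignored. G defaults to the same σ = 20 Δk
as G₁ and is a separate config key.

**Rotation stage.** The GNCC value is not translation-invariant, and each
frame's translation is untreated while its rotation is estimated. With the
literal complex metric the rotation stage measurably absorbs part of the
translation (verified by exhaustive objective scans: the minimum itself is
displaced, by far more than the optimizer tolerance). The default rotation
objective therefore correlates the k-space *magnitudes*, which the shift
theorem makes exactly translation-invariant, evaluated only on the frame's
transported sampling support so that a rotating spoke pattern cannot act as
an angular window on the reference; the normalization uses the same
support. The complex-GNCC rotation stage remains available
(`rotation_metric="complex"`). The translation stage is the GNCC objective
unchanged, on the rotation-corrected k-space.

**Optimizer.** Hand-rolled Polak–Ribière nonlinear conjugate gradient with
restart on negative conjugacy coefficient, central finite-difference
gradients (steps 1e-3 px / 1e-4 rad), Armijo backtracking (c = 1e-4,
ρ = 0.5, ≤ 30 backtracks), per-parameter convergence tolerances (1e-3 px /
1e-4 rad), 50 iterations maximum, initial trial steps scaled to 1 px /
0.02 rad, and the best-seen iterate returned (monotone objective). All of
these are package defaults — none comes from a published protocol. Frames
are initialized at zero and estimated independently; a warm-start option
initializes at the previous frame's estimate. Frames whose optimization
raises fall back to identity parameters with a logged warning. The final
per-frame |V| is reported as a registration-quality indicator.

## Evaluation

Metrics operate on the temporal *mean* of the magnitude images ("adding
across time" up to the 1/T scale, which SSIM ignores and which keeps MSE
comparable across frame counts), restricted to Ω when a ROI is given:
SSIM (11×11 Gaussian window, σ = 1.5, K₁ = 0.01, K₂ = 0.03, dynamic range
= reference max−min), MSE, and HF-SER — an HFEN-style ratio
`20·log₁₀(‖H·ref‖/‖H·(ref−test)‖)` with H a 15×15 Laplacian-of-Gaussian
(σ = 1.5); identical images return +∞ by convention. Regional curves
average the magnitude over six equiangular myocardial sectors about the LV
center (mid-ventricular convention); the mask can be transported by a
rigid estimate first. Curve smoothness is the normalized cumulative energy
E(j) of the orthonormal DCT-II coefficients; aligned series concentrate
energy in fewer coefficients, operationalized in the tests both as the
coefficient count to reach 99% energy and as mean E(j) over the small-j
range (the very first coefficients are excluded from the per-j comparison:
motion blur *flattens* a curve toward its mean, which can slightly inflate
the uncorrected DC share without making the curve smoother).

## Validation experiments and problem sizes

The test suite runs on 200×200, 32-frame phantoms with 8 coils (the
estimation operates on a single virtual coil, so the coil count affects
runtime, not difficulty). Parameter-recovery experiments inject random
rigid motion per frame and register each moved frame against the reference
built from the fully-sampled motion-free series — the analogue of the
best-achievable "reference" correction — using the moved dataset's own
ROI/ROVir weights; errors are medians over 24 frames per sampling level
(full, 32/16/8/4 spokes). The breathing-pattern, image-quality and
curve-smoothness experiments use the fully self-referenced pipeline on the
deep sawtooth phantom, whose per-period mean of exactly zero avoids
biasing the temporal-mean reference.

Known limitations surfaced by the phantom: the frame-vs-temporal-mean
contrast difference leaves a residual per-frame bias of up to ~0.5 px in
the bolus-peak frames even without motion (median ≈ 0.09 px across a
series); an undersampled reference adds a further bias at 8 spokes and
below; and the self-referenced pipeline inherits the sample mean of the
injected motion as a common offset when that mean is nonzero.
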