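"""Digital first-pass perfusion phantom with k-space motion injection.

Emulates an ECG-triggered free-breathing first-pass perfusion cardiac MR
acquisition on a stylized 2D short-axis slice: an elliptical torso containing
a right-ventricular (RV) blood pool, a left-ventricular (LV) blood pool
wrapped by a myocardial annulus, and a liver block.  A gamma-variate contrast
bolus transits RV -> LV -> myocardium, smooth complex coil sensitivities
modulate the image, per-frame rigid motion is injected directly in k-space
(exactly as the correction method models it), complex Gaussian noise is
scaled by a contrast-to-noise ratio (CNR), and the data are undersampled by a
(k,t) mask.

Defaults follow a 200 x 200 matrix (320 mm field of view at 1.6 mm
resolution), 32 time frames and 16 receiver coils.  The geometry is a
stylization, not an anatomical model: the registration problem needs a
bright dynamic heart near (not exactly at) the image center, plus the
static structures — fat, spine, textured torso — that anchor inter-frame
registration in real thoraxes, and confounding dynamic background (liver).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kspace import ComplexKFrame, KGrid, RigidParams, apply_rigid, forward_transform
from .sampling import SamplingSpec, make_mask

__all__ = [
    "TissueParams",
    "PhantomConfig",
    "MotionTrace",
    "PhantomDataset",
    "bolus_signal",
    "make_coil_maps",
    "make_motion_trace",
    "render_frame",
    "make_label_map",
    "simulate_dataset",
]

# label-map codes
BG, TORSO, RV, LV, MYO, LIVER, FAT, RIM, SPINE = 0, 1, 2, 3, 4, 5, 6, 7, 8


@dataclass(frozen=True)
class TissueParams:
    """Gamma-variate bolus curve parameters for one tissue.

    Signal(t) = baseline + amplitude * g(t - delay), with
    g(t) = (t / (alpha beta))^alpha * exp(alpha - t / beta) for t > 0
    (normalized so max g = 1, attained at t = alpha * beta) and g = 0 before
    the delay.
    """

    baseline: float
    amplitude: float
    delay: float
    alpha: float
    beta: float


#: default bolus timing (frames): RV enhances first, then LV, then myocardium
DEFAULT_BOLUS: dict[str, TissueParams] = {
    "torso": TissueParams(baseline=0.15, amplitude=0.0, delay=0.0, alpha=1.0, beta=1.0),
    "rv": TissueParams(baseline=0.20, amplitude=1.0, delay=2.0, alpha=3.0, beta=1.0),
    "lv": TissueParams(baseline=0.20, amplitude=1.0, delay=5.0, alpha=3.0, beta=1.3),
    "myo": TissueParams(baseline=0.30, amplitude=0.45, delay=9.0, alpha=4.0, beta=2.2),
    "liver": TissueParams(baseline=0.25, amplitude=0.20, delay=12.0, alpha=4.0, beta=3.0),
    # static bright structures: epicardial fat, chest-wall fat rim, spine
    "fat": TissueParams(baseline=0.85, amplitude=0.0, delay=0.0, alpha=1.0, beta=1.0),
    "rim": TissueParams(baseline=0.70, amplitude=0.0, delay=0.0, alpha=1.0, beta=1.0),
    "spine": TissueParams(baseline=0.50, amplitude=0.0, delay=0.0, alpha=1.0, beta=1.0),
}


def bolus_signal(frame_index: float, tissue: TissueParams) -> float:
    """Tissue intensity at a (possibly fractional) frame index."""
    if tissue.alpha <= 0:
        raise ValueError(f"gamma-variate shape alpha must be positive, got {tissue.alpha}")
    if tissue.beta <= 0:
        raise ValueError(f"gamma-variate scale beta must be positive, got {tissue.beta}")
    t = frame_index - tissue.delay
    if t <= 0 or tissue.amplitude == 0.0:
        return tissue.baseline
    g = (t / (tissue.alpha * tissue.beta)) ** tissue.alpha * math.exp(
        tissue.alpha - t / tissue.beta
    )
    return tissue.baseline + tissue.amplitude * g


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom acquisition parameters.

    ``cnr`` is the contrast-to-noise ratio controlling the complex Gaussian
    noise: per-channel std = (peak LV enhancement amplitude) / cnr;
    ``math.inf`` disables noise.  Geometry is expressed as fractions of the
    matrix size so it scales with ``n``.
    """

    n: int = 200
    n_frames: int = 32
    n_coils: int = 16
    cnr: float = math.inf
    fov_mm: float = 320.0
    bolus: dict[str, TissueParams] = field(default_factory=lambda: dict(DEFAULT_BOLUS))
    # geometry as (row, col) centers / extents in fractions of n
    torso_center: tuple[float, float] = (0.50, 0.50)
    torso_semi: tuple[float, float] = (0.35, 0.45)  # (rows, cols)
    # the heart sits near (not exactly at) the image center, as in a planned
    # short-axis acquisition; the residual offset keeps ROI detection honest
    lv_center: tuple[float, float] = (0.47, 0.55)
    lv_radius: float = 0.055
    myo_outer_radius: float = 0.095
    # RV abuts the myocardial ring (septum side), as in a short-axis view
    rv_center: tuple[float, float] = (0.49, 0.43)
    rv_radius: float = 0.07
    liver_rows: tuple[float, float] = (0.64, 0.79)
    liver_cols: tuple[float, float] = (0.35, 0.65)
    fat_thickness: float = 0.02  # epicardial fat ring around the myocardium
    rim_thickness: float = 0.03  # chest-wall fat band at the torso boundary
    spine_center: tuple[float, float] = (0.78, 0.50)
    spine_radius: float = 0.045

    def __post_init__(self) -> None:
        if self.n % 2:
            raise ValueError("matrix size n must be even")
        if self.n_frames < 1 or self.n_coils < 1:
            raise ValueError("n_frames and n_coils must be >= 1")
        if not (self.cnr > 0):
            raise ValueError("cnr must be positive (math.inf for noiseless)")
        if self.myo_outer_radius <= self.lv_radius:
            raise ValueError("myocardium annulus must enclose the LV pool")

    @property
    def resolution_mm(self) -> float:
        return self.fov_mm / self.n

    @property
    def lv_center_px(self) -> tuple[float, float]:
        return (self.lv_center[0] * self.n, self.lv_center[1] * self.n)


@dataclass(frozen=True)
class MotionTrace:
    """Ground-truth per-frame rigid motion with a provenance label."""

    params: tuple[RigidParams, ...]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("random_rigid", "sawtooth_shallow", "sawtooth_deep", "none"):
            raise ValueError(f"unknown motion kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.params)

    def as_array(self) -> np.ndarray:
        """(n_frames, 3) array of (theta1 rad, theta2 px, theta3 px)."""
        return np.array([p.as_array() for p in self.params])


def make_motion_trace(
    kind: str,
    n_frames: int,
    seed: int = 0,
    trans_range: float = 4.0,
    rot_range: float = 0.05,
    period: int = 8,
    rise_fraction: float = 0.7,
) -> MotionTrace:
    """Build a ground-truth motion trace.

    ``random_rigid`` draws independent per-frame translations from
    U(-trans_range, trans_range) pixels on both axes and rotations from
    U(-rot_range, rot_range) radians.  The sawtooth kinds emulate breathing:
    the foot-head translation theta3 follows an asymmetric sawtooth (rise
    ``rise_fraction`` of each ``period``-frame cycle, quantized to the frame
    grid) with amplitude +-1 px (shallow) or +-4 px (deep), both extremes
    attained exactly; rotation and right-left translation stay zero.
    """
    if kind == "none":
        return MotionTrace(tuple(RigidParams() for _ in range(n_frames)), kind)
    if kind == "random_rigid":
        rng = np.random.default_rng([seed, 101])
        params = []
        for _ in range(n_frames):
            th1 = rng.uniform(-rot_range, rot_range)
            th2 = rng.uniform(-trans_range, trans_range)
            th3 = rng.uniform(-trans_range, trans_range)
            params.append(RigidParams(th1, th2, th3))
        return MotionTrace(tuple(params), kind)
    if kind in ("sawtooth_shallow", "sawtooth_deep"):
        amp = 1.0 if kind == "sawtooth_shallow" else 4.0
        rise = max(1, min(period - 1, round(rise_fraction * period)))
        params = []
        for t in range(n_frames):
            p = t % period
            if p <= rise:
                th3 = -amp + 2.0 * amp * p / rise
            else:
                th3 = amp - 2.0 * amp * (p - rise) / (period - rise)
            params.append(RigidParams(0.0, 0.0, th3))
        return MotionTrace(tuple(params), kind)
    raise ValueError(f"unknown motion kind {kind!r}")


def make_coil_maps(n: int, n_coils: int) -> np.ndarray:
    """Smooth complex sensitivity maps for a ring of surface coils.

    Each coil is a broad Gaussian magnitude lobe centered on a ring around
    the field of view, with a gentle coil-specific linear phase.  The
    sum-of-squares magnitude is strictly positive everywhere.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c = n / 2.0
    ring_r = 0.55 * n
    sigma = 0.45 * n
    maps = np.empty((n_coils, n, n), dtype=complex)
    for i in range(n_coils):
        ang = 2.0 * np.pi * i / n_coils
        cy = c + ring_r * math.sin(ang)
        cx = c + ring_r * math.cos(ang)
        mag = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
        # mild linear phase, distinct per coil, < 0.05 rad/pixel
        py = 0.03 * math.sin(ang + 0.7)
        px = 0.03 * math.cos(ang + 0.7)
        phase = py * (yy - c) + px * (xx - c) + ang / 3.0
        maps[i] = mag * np.exp(1j * phase)
    return maps


def make_label_map(config: PhantomConfig) -> np.ndarray:
    """Tissue label map (codes BG/TORSO/RV/LV/MYO/LIVER), later labels on top."""
    n = config.n
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    lab = np.zeros((n, n), dtype=np.uint8)

    tcy, tcx = (config.torso_center[0] * n, config.torso_center[1] * n)
    tsy, tsx = (config.torso_semi[0] * n, config.torso_semi[1] * n)
    ell = ((yy - tcy) / tsy) ** 2 + ((xx - tcx) / tsx) ** 2
    torso = ell <= 1.0
    lab[torso] = TORSO
    # chest-wall fat band just inside the torso boundary (static, bright)
    inner = (1.0 - config.rim_thickness) ** 2
    lab[(ell <= 1.0) & (ell > inner)] = RIM

    scy, scx = (config.spine_center[0] * n, config.spine_center[1] * n)
    spine = (yy - scy) ** 2 + (xx - scx) ** 2 <= (config.spine_radius * n) ** 2
    lab[spine & torso] = SPINE

    r0, r1 = (int(config.liver_rows[0] * n), int(config.liver_rows[1] * n))
    c0, c1 = (int(config.liver_cols[0] * n), int(config.liver_cols[1] * n))
    liver = np.zeros_like(torso)
    liver[r0:r1, c0:c1] = True
    lab[liver & torso] = LIVER

    # epicardial fat ring drawn first, then chambers on top: fat survives
    # where the RV does not cover it (lateral/inferior borders)
    lcy, lcx = (config.lv_center[0] * n, config.lv_center[1] * n)
    d2 = (yy - lcy) ** 2 + (xx - lcx) ** 2
    fat_outer = (config.myo_outer_radius + config.fat_thickness) * n
    lab[d2 <= fat_outer**2] = FAT

    rcy, rcx = (config.rv_center[0] * n, config.rv_center[1] * n)
    rv = (yy - rcy) ** 2 + (xx - rcx) ** 2 <= (config.rv_radius * n) ** 2
    lab[rv] = RV

    myo = d2 <= (config.myo_outer_radius * n) ** 2
    lab[myo] = MYO
    lv = d2 <= (config.lv_radius * n) ** 2
    lab[lv] = LV
    return lab


_LABEL_TISSUE = {
    TORSO: "torso", RV: "rv", LV: "lv", MYO: "myo", LIVER: "liver",
    FAT: "fat", RIM: "rim", SPINE: "spine",
}


def make_static_texture(config: PhantomConfig, label_map: np.ndarray) -> np.ndarray:
    """Static anatomical texture: a fixed sum of smooth Gaussian blobs.

    Real thoraxes carry rich time-invariant structure (chest wall, lungs,
    spine, muscle) that anchors inter-frame registration; a phantom made of
    uniform regions would make the contrast bolus the only k-space content
    and bias the correlation.  The field is deterministic (fixed internal
    seed, scaled with the matrix size) and confined to the torso/liver —
    blood pools and myocardium stay uniform so their bolus curves remain
    exact.
    """
    n = config.n
    rng = np.random.default_rng(20260927)  # fixed: texture is part of the anatomy
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    field = np.zeros((n, n))
    for _ in range(80):
        cy, cx = rng.uniform(0.1, 0.9, size=2) * n
        sig = rng.uniform(0.015, 0.05) * n
        amp = rng.uniform(0.08, 0.30) * rng.choice([-1.0, 1.0])
        field += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sig**2))
    textured = (label_map == TORSO) | (label_map == LIVER)
    return np.where(textured, field, 0.0)


def render_frame(
    config: PhantomConfig,
    label_map: np.ndarray,
    frame_index: int,
    static_texture: np.ndarray | None = None,
) -> np.ndarray:
    """Real-valued tissue image at one time frame, from the bolus curves."""
    img = np.zeros(label_map.shape, dtype=float)
    for code, name in _LABEL_TISSUE.items():
        val = bolus_signal(frame_index, config.bolus[name])
        img[label_map == code] = val
    if static_texture is not None:
        img = np.clip(img + static_texture, 0.0, None)
    return img


@dataclass
class PhantomDataset:
    """Simulated acquisition plus every ground-truth intermediate.

    ``kspace`` holds the observed data (motion-injected, noisy, masked),
    shape (frames, coils, n, n); ``clean_images`` the motion-free dynamic
    series the correction is judged against.
    """

    config: PhantomConfig
    sampling: SamplingSpec
    motion: MotionTrace
    seed: int
    clean_images: np.ndarray  # (frames, n, n) complex
    coil_maps: np.ndarray  # (coils, n, n) complex
    kspace: np.ndarray  # (frames, coils, n, n) complex
    masks: np.ndarray  # (frames, n, n) uint8
    label_map: np.ndarray  # (n, n) uint8
    myo_mask: np.ndarray  # (n, n) bool
    noise_std: float

    @property
    def lv_center_px(self) -> tuple[float, float]:
        return self.config.lv_center_px


def simulate_dataset(
    config: PhantomConfig,
    motion: MotionTrace,
    sampling: SamplingSpec,
    seed: int = 0,
) -> PhantomDataset:
    """Run the full simulation pipeline.

    Per frame: render the tissue image -> multiply by each coil map ->
    forward transform -> inject the frame's rigid motion in k-space -> add
    complex Gaussian noise (std = peak LV amplitude / CNR per channel) ->
    apply the frame's sampling mask.
    """
    if len(motion) != config.n_frames:
        raise ValueError(
            f"motion trace length {len(motion)} != config.n_frames {config.n_frames}"
        )
    if sampling.n_frames != config.n_frames:
        raise ValueError(
            f"sampling n_frames {sampling.n_frames} != config.n_frames {config.n_frames}"
        )
    if sampling.grid.shape != (config.n, config.n):
        raise ValueError(
            f"sampling grid {sampling.grid.shape} != phantom matrix ({config.n}, {config.n})"
        )
    n, n_frames, n_coils = config.n, config.n_frames, config.n_coils
    grid = KGrid(n, n)
    label_map = make_label_map(config)
    coil_maps = make_coil_maps(n, n_coils)

    texture = make_static_texture(config, label_map)
    clean = np.empty((n_frames, n, n), dtype=complex)
    for t in range(n_frames):
        clean[t] = render_frame(config, label_map, t, static_texture=texture)

    noise_std = 0.0 if math.isinf(config.cnr) else config.bolus["lv"].amplitude / config.cnr
    rng = np.random.default_rng([seed, 777])

    kspace = np.empty((n_frames, n_coils, n, n), dtype=complex)
    masks = np.empty((n_frames, n, n), dtype=np.uint8)
    for t in range(n_frames):
        mask = make_mask(sampling, t)
        masks[t] = mask
        p = motion.params[t]
        for c in range(n_coils):
            s = forward_transform(clean[t] * coil_maps[c])
            frame = ComplexKFrame(data=s, mask=np.ones((n, n), dtype=np.uint8), grid=grid)
            moved = apply_rigid(frame, p).data
            if noise_std > 0.0:
                moved = moved + noise_std * (
                    rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
                )
            kspace[t, c] = moved * mask

    return PhantomDataset(
        config=config,
        sampling=sampling,
        motion=motion,
        seed=seed,
        clean_images=clean,
        coil_maps=coil_maps,
        kspace=kspace,
        masks=masks,
        label_map=label_map,
        myo_mask=label_map == MYO,
        noise_std=noise_std,
    )
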