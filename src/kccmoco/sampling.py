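"""(k,t)-undersampling mask generation and effective-acceleration measurement.

Dynamic MRI accelerates acquisition by sampling only a fraction of k-space in
each time frame, with the pattern rotating from frame to frame so that the
union over time covers k-space more densely than any single frame.  Three
schemes are provided, all rasterized onto the Cartesian grid:

* golden-angle radial — straight diameters ("spokes") through k = 0, each
  successive spoke advanced by the golden angle 111.246 deg, with a global
  spoke counter so the pattern differs per frame;
* golden-angle pseudo-spiral — Archimedean spiral arms rotated per arm and
  per frame by the golden-angle increment;
* Gaussian variable-density lines — full readout rows drawn at random with
  probability concentrated near the k-space center.

`effective_af` quantifies how well a time-averaged (synthetic-reference)
k-space is covered inside the Gaussian-weighted region that actually matters
for registration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kspace import KGrid

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "SamplingSpec",
    "golden_radial_mask",
    "pseudo_spiral_mask",
    "gaussian_vd_mask",
    "make_mask",
    "make_masks",
    "effective_af",
    "effective_temporal_resolution",
]

GOLDEN_ANGLE_DEG = 111.246

_SCHEMES = ("golden_radial_cartesian", "pseudo_spiral", "gaussian_vd_lines", "full")


@dataclass(frozen=True)
class SamplingSpec:
    """Per-frame undersampling specification.

    ``units_per_frame`` counts spokes (radial), arms (spiral) or phase-encode
    lines (Gaussian-VD); it is ignored by the ``full`` scheme.  ``seed`` feeds
    only the Gaussian-VD random draw.
    """

    scheme: str
    units_per_frame: int
    n_frames: int
    grid: KGrid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {_SCHEMES}")
        if self.scheme != "full" and self.units_per_frame < 1:
            raise ValueError("units_per_frame must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _check_frame(spec: SamplingSpec, frame_index: int) -> None:
    if not 0 <= frame_index < spec.n_frames:
        raise ValueError(f"frame_index {frame_index} outside [0, {spec.n_frames})")


def golden_radial_mask(spec: SamplingSpec, frame_index: int) -> np.ndarray:
    """Golden-angle radial spokes on the Cartesian grid for one frame.

    Spoke ``s`` (a global counter continuing across frames) is a diameter
    through k = 0 at angle ``s * 111.246 deg``, rasterized by nearest-neighbor
    assignment of N equispaced radial samples spanning the grid.
    """
    _check_frame(spec, frame_index)
    g = spec.grid
    n = max(g.n_y, g.n_x)
    cy, cx = g.center
    mask = np.zeros(g.shape, dtype=np.uint8)
    t = np.arange(n) - n // 2  # radial sample positions, includes 0
    golden = math.radians(GOLDEN_ANGLE_DEG)
    for j in range(spec.units_per_frame):
        s = frame_index * spec.units_per_frame + j
        alpha = s * golden
        rows = np.rint(cy + t * math.sin(alpha)).astype(int)
        cols = np.rint(cx + t * math.cos(alpha)).astype(int)
        keep = (rows >= 0) & (rows < g.n_y) & (cols >= 0) & (cols < g.n_x)
        mask[rows[keep], cols[keep]] = 1
    return mask


def pseudo_spiral_mask(spec: SamplingSpec, frame_index: int, n_turns: float = 1.5) -> np.ndarray:
    """Archimedean pseudo-spiral arms for one frame.

    Each arm starts at k = 0 and grows linearly in radius over ``n_turns``
    turns; arms are rotated per arm and per frame by the golden-angle
    increment, decorrelating consecutive frames.
    """
    _check_frame(spec, frame_index)
    g = spec.grid
    n = max(g.n_y, g.n_x)
    cy, cx = g.center
    mask = np.zeros(g.shape, dtype=np.uint8)
    golden = math.radians(GOLDEN_ANGLE_DEG)
    # enough samples along the arc that neighboring rasterized points touch
    n_samp = int(4 * n * max(1.0, n_turns))
    u = np.linspace(0.0, 1.0, n_samp)
    r = u * (n / 2.0)
    for arm in range(spec.units_per_frame):
        offset = (frame_index * spec.units_per_frame + arm) * golden
        phi = u * n_turns * 2.0 * np.pi + offset
        rows = np.rint(cy + r * np.sin(phi)).astype(int)
        cols = np.rint(cx + r * np.cos(phi)).astype(int)
        keep = (rows >= 0) & (rows < g.n_y) & (cols >= 0) & (cols < g.n_x)
        mask[rows[keep], cols[keep]] = 1
    return mask


def gaussian_vd_mask(spec: SamplingSpec, frame_index: int, sigma: float | None = None) -> np.ndarray:
    """Gaussian variable-density random line sampling for one frame.

    Draws ``units_per_frame`` distinct phase-encode rows without replacement,
    with probability proportional to a zero-mean Gaussian over the centered
    row offset (default sigma = N/6); each selected row is fully read out.
    The draw is reproducible per (seed, frame_index).
    """
    _check_frame(spec, frame_index)
    g = spec.grid
    if spec.units_per_frame > g.n_y:
        raise ValueError(
            f"units_per_frame {spec.units_per_frame} exceeds number of rows {g.n_y}"
        )
    if sigma is None:
        sigma = g.n_y / 6.0
    offsets = np.arange(g.n_y) - g.n_y // 2
    p = np.exp(-(offsets.astype(float) ** 2) / (2.0 * sigma**2))
    p /= p.sum()
    rng = np.random.default_rng([spec.seed, frame_index])
    rows = rng.choice(g.n_y, size=spec.units_per_frame, replace=False, p=p)
    mask = np.zeros(g.shape, dtype=np.uint8)
    mask[rows, :] = 1
    return mask


def make_mask(spec: SamplingSpec, frame_index: int) -> np.ndarray:
    """Dispatch on ``spec.scheme``."""
    if spec.scheme == "full":
        _check_frame(spec, frame_index)
        return np.ones(spec.grid.shape, dtype=np.uint8)
    if spec.scheme == "golden_radial_cartesian":
        return golden_radial_mask(spec, frame_index)
    if spec.scheme == "pseudo_spiral":
        return pseudo_spiral_mask(spec, frame_index)
    return gaussian_vd_mask(spec, frame_index)


def make_masks(spec: SamplingSpec) -> np.ndarray:
    """All per-frame masks stacked, shape (n_frames, n_y, n_x), uint8."""
    return np.stack([make_mask(spec, t) for t in range(spec.n_frames)])


def effective_af(
    masks: np.ndarray, sigma: float = 20.0, cutoff_fraction: float = 0.10
) -> float:
    """Effective acceleration factor of the time-averaged reference k-space.

    The effective region is the set of grid points whose radial distance r
    (in grid steps) satisfies ``exp(-r^2 / (2 sigma^2)) >= cutoff_fraction``,
    i.e. where the Gaussian reference weight retains at least that fraction of
    its maximum.  Returns (region point count) / (region points sampled at
    least once across all frames); +inf if no region point is ever sampled.
    """
    masks = np.asarray(masks)
    if masks.ndim == 2:
        masks = masks[None]
    if masks.ndim != 3 or masks.shape[0] == 0:
        raise ValueError("expected a non-empty stack of 2D masks")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 < cutoff_fraction < 1.0:
        raise ValueError("cutoff_fraction must lie in (0, 1)")
    n_y, n_x = masks.shape[1:]
    cy, cx = n_y // 2, n_x // 2
    yy, xx = np.mgrid[0:n_y, 0:n_x]
    r2 = (yy - cy) ** 2.0 + (xx - cx) ** 2.0
    region = np.exp(-r2 / (2.0 * sigma**2)) >= cutoff_fraction
    union = masks.any(axis=0)
    covered = int(np.count_nonzero(region & union))
    total = int(np.count_nonzero(region))
    if covered == 0:
        return float("inf")
    return total / covered


def effective_temporal_resolution(spokes_per_frame: int, tr_ms: float) -> float:
    """Effective temporal footprint of one frame: spokes/frame x TR, in ms.

    E.g. 14 spokes per frame at TR = 2.57 ms gives 35.98 ms.
    """
    if spokes_per_frame < 1:
        raise ValueError("spokes_per_frame must be >= 1")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    return spokes_per_frame * tr_ms
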