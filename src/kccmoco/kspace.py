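"""Centered Fourier conventions and interpolation-free rigid transforms on Cartesian k-space.

MRI acquires data in k-space, the 2D spatial-frequency domain.  A rigid motion
of the object maps onto k-space without leaving it: a rotation of the image
rotates k-space identically, and a translation becomes a linear phase ramp.
This module fixes a single DFT convention for the whole package and implements
both operations exactly on the Cartesian grid — the rotation via the 3-shear
FFT decomposition, so no spatial interpolation is ever performed.

Conventions
-----------
* Grids are even-sized; the k = 0 sample sits at array index ``(n//2, n//2)``
  after centering.  Coordinates are in cycles-per-pixel,
  ``{-N/2, ..., N/2 - 1} / N`` along each axis.
* ``x`` indexes columns (axis 1, right-left), ``y`` indexes rows (axis 0,
  foot-head).
* The forward transform uses the ``e^{+j 2 pi k x}`` analysis kernel
  (orthonormal), so that multiplying k-space by
  ``exp(+j 2 pi (theta2 kx + theta3 ky))`` shifts the image toward the
  positive x / y axes for positive parameters.  The shift-theorem tests pin
  this sign down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KGrid",
    "RigidParams",
    "ComplexKFrame",
    "forward_transform",
    "inverse_transform",
    "apply_translation",
    "translate_array",
    "rotate_3shear",
    "rotate_array_3shear",
    "apply_rigid",
    "invert_rigid",
]

#: validity guard for the 3-shear decomposition as used here
MAX_ROTATION = math.pi / 4


def _check_even(n_y: int, n_x: int) -> None:
    if n_y % 2:
        raise ValueError(f"axis 0 (rows) has odd size {n_y}; even-sized grids required")
    if n_x % 2:
        raise ValueError(f"axis 1 (columns) has odd size {n_x}; even-sized grids required")


@dataclass(frozen=True)
class KGrid:
    """Even-sized centered k-space grid with coordinates in cycles-per-pixel."""

    n_y: int
    n_x: int

    def __post_init__(self) -> None:
        if self.n_y < 2 or self.n_x < 2:
            raise ValueError("grid must be at least 2x2")
        _check_even(self.n_y, self.n_x)

    @property
    def k_y(self) -> np.ndarray:
        return (np.arange(self.n_y) - self.n_y // 2) / self.n_y

    @property
    def k_x(self) -> np.ndarray:
        return (np.arange(self.n_x) - self.n_x // 2) / self.n_x

    @property
    def center(self) -> tuple[int, int]:
        return (self.n_y // 2, self.n_x // 2)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_y, self.n_x)


@dataclass(frozen=True)
class RigidParams:
    """In-plane rigid transform: rotation about the image center plus translation.

    Parameters
    ----------
    theta1 : float
        Rotation in radians, counter-clockwise positive in (x, y) coordinates.
        Limited to ``|theta1| < pi/4``, the guard for the 3-shear rotation.
    theta2 : float
        Translation along x (columns, right-left), in pixels.
    theta3 : float
        Translation along y (rows, foot-head), in pixels.
    """

    theta1: float = 0.0
    theta2: float = 0.0
    theta3: float = 0.0

    def __post_init__(self) -> None:
        for name in ("theta1", "theta2", "theta3"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if abs(self.theta1) >= MAX_ROTATION:
            raise ValueError(
                f"|theta1| = {abs(self.theta1):.4f} rad exceeds the 3-shear validity "
                f"guard pi/4"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3], dtype=float)


def invert_rigid(params: RigidParams) -> RigidParams:
    """Exact inverse of rotation-then-translation.

    ``apply_rigid(apply_rigid(S, p), invert_rigid(p))`` is the identity up to
    shear wrap-around at the borders.
    """
    c, s = math.cos(-params.theta1), math.sin(-params.theta1)
    tx, ty = params.theta2, params.theta3
    # translation rotated by R(-theta1), then negated
    return RigidParams(
        theta1=-params.theta1,
        theta2=-(c * tx - s * ty),
        theta3=-(s * tx + c * ty),
    )


@dataclass
class ComplexKFrame:
    """One frame of k-space samples plus its binary sampling mask.

    ``data`` is zero wherever ``mask`` is zero (zero-filled convention).
    """

    data: np.ndarray
    mask: np.ndarray
    grid: KGrid = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2D array")
        if self.grid is None:
            self.grid = KGrid(*self.data.shape)
        if self.data.shape != self.grid.shape:
            raise ValueError(f"data shape {self.data.shape} != grid {self.grid.shape}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape, dtype=np.uint8)
        self.mask = np.asarray(self.mask)
        if self.mask.shape != self.data.shape:
            raise ValueError(f"mask shape {self.mask.shape} != data shape {self.data.shape}")


# ---------------------------------------------------------------------------
# transforms

def forward_transform(image: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D DFT (synthesis-kernel sign; see module docstring)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2D array")
    _check_even(*image.shape)
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(image), norm="ortho"))


def inverse_transform(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`forward_transform`; exact to machine precision."""
    kspace = np.asarray(kspace)
    if kspace.ndim != 2:
        raise ValueError("expected a 2D array")
    _check_even(*kspace.shape)
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(kspace), norm="ortho"))


def apply_translation(frame: ComplexKFrame, theta2: float, theta3: float) -> ComplexKFrame:
    """Translate the underlying image by (theta2, theta3) pixels via a k-space phase ramp.

    Multiplies the data pointwise by ``exp(+j 2 pi (theta2 kx + theta3 ky))``;
    the sampling mask is unchanged and the k-space energy is preserved exactly.
    """
    if not (math.isfinite(theta2) and math.isfinite(theta3)):
        raise ValueError(f"non-finite translation ({theta2!r}, {theta3!r})")
    g = frame.grid
    phase = np.exp(
        2j * np.pi * (theta2 * g.k_x[None, :] + theta3 * g.k_y[:, None])
    )
    return ComplexKFrame(data=frame.data * phase, mask=frame.mask.copy(), grid=g)


def translate_array(arr: np.ndarray, theta2: float, theta3: float) -> np.ndarray:
    """Raw-array version of :func:`apply_translation` (no mask bookkeeping)."""
    if not (math.isfinite(theta2) and math.isfinite(theta3)):
        raise ValueError(f"non-finite translation ({theta2!r}, {theta3!r})")
    arr = np.asarray(arr)
    g = KGrid(*arr.shape)
    phase = np.exp(2j * np.pi * (theta2 * g.k_x[None, :] + theta3 * g.k_y[:, None]))
    return arr * phase


def _shear(arr: np.ndarray, amount: float, axis: int) -> np.ndarray:
    """Shear a 2D array along `axis` by a per-line shift proportional to the
    centered orthogonal coordinate: line j shifts by ``amount * (j - c)``.

    Realized as 1D FFT along `axis`, linear phase, inverse FFT — circular
    (wrap-around) and exactly energy-preserving.
    """
    n_shift = arr.shape[axis]
    n_ortho = arr.shape[1 - axis]
    f = np.fft.fftfreq(n_shift)  # cycles per sample along the shifted axis
    ortho = np.arange(n_ortho) - n_ortho // 2
    shifts = amount * ortho  # one shift per orthogonal line
    if axis == 1:  # shift rows along x; ortho coordinate is the row index
        phase = np.exp(-2j * np.pi * shifts[:, None] * f[None, :])
        return np.fft.ifft(np.fft.fft(arr, axis=1) * phase, axis=1)
    phase = np.exp(-2j * np.pi * f[:, None] * shifts[None, :])
    return np.fft.ifft(np.fft.fft(arr, axis=0) * phase, axis=0)


def rotate_array_3shear(arr: np.ndarray, theta1: float, pad: bool = False) -> np.ndarray:
    """Rotate a 2D complex array about its center by `theta1` rad (CCW in (x, y))
    using the 3-shear decomposition R = Sx(a) Sy(b) Sx(a), a = -tan(theta/2),
    b = sin(theta).

    Every shear is a bank of FFT phase ramps, so the rotation involves no
    spatial interpolation and is exactly energy-preserving.  Shears wrap
    circularly; `pad` embeds the array in a 2x zero-padded field first, for
    use with larger angles.
    """
    if not math.isfinite(theta1):
        raise ValueError(f"non-finite rotation {theta1!r}")
    if abs(theta1) >= MAX_ROTATION:
        raise ValueError(
            f"|theta1| = {abs(theta1):.4f} rad outside the 3-shear validity guard pi/4"
        )
    arr = np.asarray(arr, dtype=complex)
    if theta1 == 0.0:
        return arr.copy()
    if pad:
        ny, nx = arr.shape
        big = np.zeros((2 * ny, 2 * nx), dtype=complex)
        big[ny // 2 : ny // 2 + ny, nx // 2 : nx // 2 + nx] = arr
        out = rotate_array_3shear(big, theta1, pad=False)
        return out[ny // 2 : ny // 2 + ny, nx // 2 : nx // 2 + nx]
    a = -math.tan(theta1 / 2.0)
    b = math.sin(theta1)
    out = _shear(arr, a, axis=1)
    out = _shear(out, b, axis=0)
    out = _shear(out, a, axis=1)
    return out


def rotate_3shear(frame: ComplexKFrame, theta1: float, pad: bool = False) -> ComplexKFrame:
    """Rotate a k-space frame (data and mask) by `theta1` radians.

    The binary mask is transported by applying the same shear sequence to it
    as a real array and thresholding the magnitude at 0.5, so downstream
    consumers keep a consistent sampling pattern.
    """
    data = rotate_array_3shear(frame.data, theta1, pad=pad)
    if theta1 == 0.0:
        mask = frame.mask.copy()
    else:
        m = rotate_array_3shear(frame.mask.astype(float), theta1, pad=pad)
        mask = (np.abs(m) >= 0.5).astype(frame.mask.dtype)
    return ComplexKFrame(data=data, mask=mask, grid=frame.grid)


def apply_rigid(frame: ComplexKFrame, params: RigidParams, pad: bool = False) -> ComplexKFrame:
    """Rigidly transform a k-space frame: rotation first, then translation.

    This is the k-space realization of moving the underlying image by
    ``params`` — the rotation acts identically on k-space and the translation
    becomes the linear phase ramp of :func:`apply_translation`.
    """
    out = rotate_3shear(frame, params.theta1, pad=pad)
    return apply_translation(out, params.theta2, params.theta3)
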