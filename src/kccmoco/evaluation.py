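"""Quantitative evaluation of motion-corrected dynamic series.

Metrics operate on the temporal average of the dynamic magnitude images —
sharp when the frames are aligned, blurred under residual motion — compared
against a reference-corrected average: structural similarity (SSIM), mean
squared error (MSE), and a high-frequency signal-to-error ratio (HF-SER,
an HFEN-style Laplacian-of-Gaussian band ratio in dB).  Regional perfusion
is summarized by time-intensity curves averaged over equiangular myocardial
sectors (the 6-sector mid-ventricular convention), whose smoothness is
quantified by the normalized cumulative energy of their DCT coefficients:
aligned series give smoother curves, concentrating energy in low-order
coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft
import scipy.ndimage
from skimage.metrics import structural_similarity

from .kspace import RigidParams

__all__ = [
    "MetricReport",
    "temporal_average",
    "ssim",
    "mse",
    "hf_ser",
    "sector_curves",
    "dct_cumulative_energy",
]


def temporal_average(dynamic_images: np.ndarray, omega: np.ndarray | None = None) -> np.ndarray:
    """Pixel-wise mean of the magnitude images, optionally restricted to a ROI.

    With ``omega`` (a boolean mask), pixels outside the ROI are zeroed so all
    metrics compare the same support.
    """
    imgs = np.abs(np.asarray(dynamic_images))
    if imgs.ndim == 2:
        imgs = imgs[None]
    if imgs.shape[0] < 1:
        raise ValueError("need at least one frame")
    avg = imgs.mean(axis=0)
    if omega is not None:
        avg = np.where(np.asarray(omega, bool), avg, 0.0)
    return avg


def ssim(test: np.ndarray, reference: np.ndarray) -> float:
    """Structural similarity with an 11x11 Gaussian window (sigma 1.5),
    K1 = 0.01, K2 = 0.03, dynamic range = reference max - min."""
    test = np.asarray(test, float)
    reference = np.asarray(reference, float)
    if test.shape != reference.shape:
        raise ValueError(f"shape mismatch {test.shape} vs {reference.shape}")
    dr = float(reference.max() - reference.min())
    if dr == 0.0:
        dr = 1.0
    return float(
        structural_similarity(
            test,
            reference,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            data_range=dr,
        )
    )


def mse(test: np.ndarray, reference: np.ndarray) -> float:
    test = np.asarray(test, float)
    reference = np.asarray(reference, float)
    if test.shape != reference.shape:
        raise ValueError(f"shape mismatch {test.shape} vs {reference.shape}")
    return float(np.mean((test - reference) ** 2))


def _log_kernel(size: int = 15, sigma: float = 1.5) -> np.ndarray:
    """Laplacian-of-Gaussian kernel, zero-sum."""
    half = size // 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    r2 = yy**2 + xx**2
    k = (r2 - 2.0 * sigma**2) / sigma**4 * np.exp(-r2 / (2.0 * sigma**2))
    return k - k.mean()


def hf_ser(test: np.ndarray, reference: np.ndarray, size: int = 15, sigma: float = 1.5) -> float:
    """High-frequency signal-to-error ratio in dB.

    ``20 log10(||H ref||_2 / ||H (ref - test)||_2)`` with H a 15x15
    Laplacian-of-Gaussian filter (sigma 1.5).  Identical images return +inf.
    """
    test = np.asarray(test, float)
    reference = np.asarray(reference, float)
    if test.shape != reference.shape:
        raise ValueError(f"shape mismatch {test.shape} vs {reference.shape}")
    h = _log_kernel(size, sigma)
    ref_hf = scipy.ndimage.convolve(reference, h, mode="nearest")
    err_hf = scipy.ndimage.convolve(reference - test, h, mode="nearest")
    err_norm = float(np.linalg.norm(err_hf))
    if err_norm == 0.0:
        return float("inf")
    return 20.0 * float(np.log10(np.linalg.norm(ref_hf) / err_norm))


def _transport_mask(mask: np.ndarray, params: RigidParams) -> np.ndarray:
    """Move a binary mask by a rigid transform (nearest-neighbor resampling).

    Matches the k-space convention: rotation by theta1 (counter-clockwise in
    (x, y)) about the grid center at (n//2, n//2), then translation by
    (theta2, theta3) pixels toward (+x, +y).
    """
    n_y, n_x = mask.shape
    center = np.array([n_y // 2, n_x // 2], dtype=float)  # (row, col)
    t = np.array([params.theta3, params.theta2], dtype=float)  # (row, col)
    c, s = np.cos(params.theta1), np.sin(params.theta1)
    # R(theta) acting on (row, col) components of an (x, y)-CCW rotation
    rot_inv = np.array([[c, -s], [s, c]])  # = R(-theta) in (row, col)
    # output pixel o samples input at R(-theta) @ (o - t - center) + center
    offset = -rot_inv @ (t + center) + center
    moved = scipy.ndimage.affine_transform(
        mask.astype(float), rot_inv, offset=offset, order=0, mode="constant", cval=0.0
    )
    return moved >= 0.5


def sector_curves(
    dynamic_images: np.ndarray,
    myocardium_mask: np.ndarray,
    lv_center: tuple[float, float],
    n_sectors: int = 6,
    reference_angle: float = 0.0,
    transport: RigidParams | None = None,
) -> np.ndarray:
    """Per-sector mean time-intensity curves of the myocardium.

    Myocardial pixels are partitioned into ``n_sectors`` equiangular wedges
    about ``lv_center`` (row, col), counter-clockwise from
    ``reference_angle``.  Returns an (n_sectors, n_frames) array; a sector
    containing no pixels yields a NaN curve.  ``transport`` optionally moves
    the mask by a rigid transform first (e.g. the last frame's estimate, when
    the mask was drawn on the last frame).
    """
    imgs = np.abs(np.asarray(dynamic_images))
    mask = np.asarray(myocardium_mask, bool)
    if imgs.ndim != 3:
        raise ValueError("expected (frames, n_y, n_x)")
    if mask.shape != imgs.shape[1:]:
        raise ValueError("mask shape does not match images")
    if not mask.any():
        raise ValueError("myocardium mask is empty")
    if n_sectors < 1:
        raise ValueError("n_sectors must be >= 1")
    if transport is not None:
        mask = _transport_mask(mask, transport)
        if not mask.any():
            raise ValueError("mask transported outside the field of view")
    rows, cols = np.nonzero(mask)
    # angle in (x, y) coordinates, counter-clockwise from reference_angle
    ang = np.arctan2(rows - lv_center[0], cols - lv_center[1])
    sector = np.floor(((ang - reference_angle) % (2.0 * np.pi)) / (2.0 * np.pi / n_sectors))
    sector = sector.astype(int) % n_sectors
    n_frames = imgs.shape[0]
    curves = np.full((n_sectors, n_frames), np.nan)
    pix = imgs[:, rows, cols]  # (frames, n_pix)
    for s in range(n_sectors):
        sel = sector == s
        if sel.any():
            curves[s] = pix[:, sel].mean(axis=1)
    return curves


def dct_cumulative_energy(curve: np.ndarray) -> np.ndarray:
    """Normalized cumulative energy of the orthonormal DCT-II coefficients.

    ``E[j] = sum_{k<=j} X[k]^2 / sum_k X[k]^2`` — non-decreasing with
    ``E[N] = 1``; smoother curves reach 1 faster.
    """
    x = np.asarray(curve, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("curve must be 1D with at least 2 samples")
    if not np.any(x != 0):
        raise ValueError("curve is identically zero")
    coeffs = scipy.fft.dct(x, norm="ortho")
    energy = coeffs**2
    return np.cumsum(energy) / energy.sum()


@dataclass
class MetricReport:
    """Image-quality metrics plus optional parameter-error bookkeeping."""

    ssim: float
    mse: float
    hf_ser_db: float
    sector_energy: dict[str, list[float]] = field(default_factory=dict)
    parameter_errors: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "ssim": self.ssim,
            "mse": self.mse,
            "hf_ser_db": self.hf_ser_db,
            "sector_energy": self.sector_energy,
        }
        if self.parameter_errors is not None:
            d["parameter_errors"] = self.parameter_errors.to_dict(orient="list")
        return d

    def to_json(self, path: str) -> None:
        def _default(o):
            if isinstance(o, float) and (np.isinf(o) or np.isnan(o)):
                return str(o)
            raise TypeError(o)

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_default)
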