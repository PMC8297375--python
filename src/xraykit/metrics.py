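"""Full-reference image quality metrics: MSE, PSNR, SSIM, histogram.

All metrics operate on the native intensity scale ``[0, peak]`` — MSE is
never normalized, so the peak term of PSNR is consistent with it:

* ``MSE = (1/MN) * sum (I - I')**2``
* ``PSNR = 10 log10(peak**2 / MSE)`` dB, ``+inf`` when MSE is zero.

SSIM is computed in its three-component form.  Per local window with
means ``mu_x, mu_y``, standard deviations ``sigma_x, sigma_y`` and
cross-covariance ``sigma_xy``::

    l = (2 mu_x mu_y + C1) / (mu_x^2 + mu_y^2 + C1)       # luminance
    c = (2 sigma_x sigma_y + C2) / (sigma_x^2 + sigma_y^2 + C2)   # contrast
    s = (sigma_xy + C3) / (sigma_x sigma_y + C3)          # structure

    SSIM = mean over windows of l^alpha * c^beta * s^gamma

with ``C1 = (K1 peak)^2``, ``C2 = (K2 peak)^2`` and ``C3 = C2 / 2``.
With the default unit exponents this reduces to the familiar simplified
two-factor form.  The default window is the field-standard 11x11
Gaussian with sigma 1.5; a uniform window of any side and a single
global window are exposed for sensitivity checks and closed-form tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import GrayImage

__all__ = [
    "SSIMParams",
    "QualityReport",
    "mse",
    "psnr",
    "ssim",
    "quality_report",
    "histogram",
]


@dataclass(frozen=True)
class SSIMParams:
    """Exponents, regularizers and window of the SSIM computation."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    K1: float = 0.01
    K2: float = 0.03
    window: str = "gaussian"   # "gaussian" | "uniform" | "global"
    win_size: int = 11
    sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.window not in ("gaussian", "uniform", "global"):
            raise ValueError(f"unknown window mode {self.window!r}")
        if self.window != "global" and (self.win_size < 1 or self.win_size % 2 == 0):
            raise ValueError(f"win_size must be odd and positive, got {self.win_size}")

    def C1(self, peak: int) -> float:
        return (self.K1 * peak) ** 2

    def C2(self, peak: int) -> float:
        return (self.K2 * peak) ** 2

    def C3(self, peak: int) -> float:
        return self.C2(peak) / 2.0


@dataclass(frozen=True)
class QualityReport:
    """(SSIM, MSE, PSNR) triple for one (reference, test) pair."""

    ssim: float
    mse: float
    psnr: float  # dB; math.inf when mse == 0


def _check_pair(ref: GrayImage, test: GrayImage) -> None:
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if ref.bit_depth != test.bit_depth:
        raise ValueError(f"bit depth mismatch: {ref.bit_depth} vs {test.bit_depth}")


def mse(ref: GrayImage, test: GrayImage) -> float:
    """Mean squared error on the native intensity scale."""
    _check_pair(ref, test)
    diff = ref.astype_float() - test.astype_float()
    return float(np.mean(diff * diff))


def psnr(ref: GrayImage, test: GrayImage) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    err = mse(ref, test)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(ref.peak**2 / err)


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    r = size // 2
    g = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def _power(base: np.ndarray, exponent: float) -> np.ndarray:
    if exponent == 1.0:
        return base
    # negative structure terms only arise with non-unit gamma; keep the sign
    return np.sign(base) * np.abs(base) ** exponent


def ssim(ref: GrayImage, test: GrayImage, params: SSIMParams | None = None) -> float:
    """Mean structural similarity between two images of equal shape and depth."""
    params = params or SSIMParams()
    _check_pair(ref, test)
    x = ref.astype_float()
    y = test.astype_float()
    peak = ref.peak

    if params.window == "global":
        mu_x, mu_y = x.mean(), y.mean()
        var_x, var_y = x.var(), y.var()
        cov = float(np.mean((x - mu_x) * (y - mu_y)))
        mu_x = np.array([mu_x]); mu_y = np.array([mu_y])
        var_x = np.array([var_x]); var_y = np.array([var_y])
        cov = np.array([cov])
    else:
        size = params.win_size
        if size > min(ref.shape):
            raise ValueError(f"window side {size} exceeds image extent {ref.shape}")
        if params.window == "gaussian":
            kernel = _gaussian_kernel(size, params.sigma)
        else:
            kernel = np.full((size, size), 1.0 / size**2)

        def local(arr: np.ndarray) -> np.ndarray:
            full = ndimage.correlate(arr, kernel, mode="constant")
            r = size // 2
            return full[r:-r, r:-r] if r else full

        mu_x = local(x)
        mu_y = local(y)
        var_x = local(x * x) - mu_x**2
        var_y = local(y * y) - mu_y**2
        cov = local(x * y) - mu_x * mu_y

    var_x = np.maximum(var_x, 0.0)
    var_y = np.maximum(var_y, 0.0)
    sd_x = np.sqrt(var_x)
    sd_y = np.sqrt(var_y)

    c1, c2, c3 = params.C1(peak), params.C2(peak), params.C3(peak)
    lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    con = (2 * sd_x * sd_y + c2) / (var_x + var_y + c2)
    struct = (cov + c3) / (sd_x * sd_y + c3)

    combined = _power(lum, params.alpha) * _power(con, params.beta) * _power(struct, params.gamma)
    return float(np.mean(combined))


def quality_report(ref: GrayImage, test: GrayImage, params: SSIMParams | None = None) -> QualityReport:
    """Convenience bundle of all three metrics for one image pair."""
    return QualityReport(ssim=ssim(ref, test, params), mse=mse(ref, test), psnr=psnr(ref, test))


def histogram(img: GrayImage, bins: int = 256) -> np.ndarray:
    """Counts over ``bins`` equal-width intensity bins spanning ``[0, peak]``.

    Level ``v`` falls in bin ``floor(v * bins / (peak + 1))``; counts sum
    to the pixel count.
    """
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    idx = np.minimum(img.pixels * bins // (img.peak + 1), bins - 1)
    return np.bincount(idx.ravel(), minlength=bins)
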