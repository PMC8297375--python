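"""Deterministic synthetic X-ray-like test images.

Clinical chest radiographs cannot be redistributed with the toolkit, so
every codec, enhancer and metric is exercised on generated phantoms
instead.  The ``chest_like`` phantom emulates the gross intensity
structure of a frontal chest X-ray — dark air background, a bright
elliptical body, two darker lung fields and thin high-intensity ribs —
plus additive Gaussian noise clamped to the intensity range.  The other
kinds are analytic patterns chosen to be extremal for specific codecs
(``constant`` maximizes RLE runs, ``blocky`` is exactly representable by
BTC and DC-only DCT, ``checkerboard`` is adversarial for RLE).

All randomness flows through ``numpy.random.default_rng(seed)``, so a
fixed spec regenerates bit-identical images on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import GrayImage

__all__ = ["PhantomSpec", "make_phantom", "PHANTOM_KINDS"]

PHANTOM_KINDS = ("constant", "ramp", "checkerboard", "blocky", "chest_like")

# chest_like geometry, as fractions of the image extent; fixed so the
# fixture is stable across versions
_BODY_CENTER = (0.52, 0.50)
_BODY_AXES = (0.44, 0.38)
_LUNG_CENTERS = ((0.46, 0.32), (0.46, 0.68))
_LUNG_AXES = (0.26, 0.13)
_RIB_SPACING = 0.09        # fraction of height between rib bands
_RIB_THICKNESS = 1 / 128   # fraction of height, at least one pixel
_LEVELS = {"background": 0.08, "body": 0.70, "lung": 0.28, "rib": 0.90}


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic image."""

    kind: str = "chest_like"
    size: tuple[int, int] = (256, 256)
    bit_depth: int = 8
    noise_sigma: float = 0.0   # additive Gaussian noise, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {PHANTOM_KINDS}")
        if self.size[0] < 16 or self.size[1] < 16:
            raise ValueError(f"size must be at least 16x16, got {self.size}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


def _ellipse_mask(m: int, n: int, center: tuple[float, float], axes: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:m, 0:n]
    cy, cx = center[0] * m, center[1] * n
    ay, ax = axes[0] * m, axes[1] * n
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _chest_like(m: int, n: int, peak: int) -> np.ndarray:
    img = np.full((m, n), _LEVELS["background"] * peak)
    body = _ellipse_mask(m, n, _BODY_CENTER, _BODY_AXES)
    img[body] = _LEVELS["body"] * peak
    lungs = np.zeros((m, n), dtype=bool)
    for c in _LUNG_CENTERS:
        lungs |= _ellipse_mask(m, n, c, _LUNG_AXES)
    lungs &= body
    img[lungs] = _LEVELS["lung"] * peak
    # thin bright rib bands crossing the lung fields
    thickness = max(1, round(_RIB_THICKNESS * m))
    spacing = max(thickness + 1, round(_RIB_SPACING * m))
    rows = np.zeros(m, dtype=bool)
    for start in range(spacing // 2, m, spacing):
        rows[start : start + thickness] = True
    ribs = lungs & rows[:, None]
    img[ribs] = _LEVELS["rib"] * peak
    return img


def make_phantom(spec: PhantomSpec) -> GrayImage:
    """Generate the phantom described by ``spec``; bit-exact for a fixed seed."""
    m, n = spec.size
    peak = (1 << spec.bit_depth) - 1
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "constant":
        base = np.full((m, n), 0.5 * peak)
    elif spec.kind == "ramp":
        rows = np.round(np.arange(m) * peak / (m - 1))
        base = np.broadcast_to(rows[:, None], (m, n)).astype(np.float64)
    elif spec.kind == "checkerboard":
        yy, xx = np.mgrid[0:m, 0:n]
        cells = ((yy // 8) + (xx // 8)) % 2
        base = np.where(cells == 0, 0.25 * peak, 0.75 * peak)
    elif spec.kind == "blocky":
        gm, gn = -(-m // 8), -(-n // 8)
        tiles = rng.integers(0, peak + 1, size=(gm, gn)).astype(np.float64)
        base = np.repeat(np.repeat(tiles, 8, axis=0), 8, axis=1)[:m, :n]
    else:  # chest_like
        base = _chest_like(m, n, peak)

    if spec.noise_sigma > 0:
        base = base + rng.normal(0.0, spec.noise_sigma, size=(m, n))

    pixels = np.clip(np.floor(base + 0.5), 0, peak).astype(np.int64)
    return GrayImage(pixels, spec.bit_depth)
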