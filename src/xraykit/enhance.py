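"""Spatial-domain enhancement: tiled adaptive histogram equalization and
grayscale morphology.

AHE partitions the image into a grid of tiles, builds a per-tile
histogram and CDF-based intensity mapping, and evaluates each pixel as
the bilinear interpolation of the four surrounding tile mappings (tile
centers are the interpolation nodes; pixels outside the outer centers
fall back to the nearest available mappings).  A non-zero ``clip_limit``
turns the method into CLAHE: tile histograms are clipped at
``clip_limit`` times the mean bin height and the excess is redistributed
uniformly before the CDF is formed.

The morphological operators are flat-structuring-element grayscale
morphology (neighborhood minimum / maximum and their compositions) with
edge-replication borders.  The background enhancer adds the white
top-hat and subtracts the black top-hat::

    enhanced = clamp(img + (img - open(img)) - (close(img) - img))

which brightens small bright structures and suppresses small dark
background variation without sharpening large-scale anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import GrayImage, _round_half_up

__all__ = [
    "AHEConfig",
    "MorphConfig",
    "ahe",
    "morpho_primitive",
    "morpho_enhance",
]


@dataclass(frozen=True)
class AHEConfig:
    """Tile grid, histogram resolution and optional CLAHE clip limit.

    ``clip_limit`` is expressed as a multiple of the mean bin height;
    0 disables clipping (plain AHE, the default).
    """

    tiles: tuple[int, int] = (8, 8)
    bins: int = 256
    clip_limit: float = 0.0

    def __post_init__(self) -> None:
        if self.tiles[0] < 1 or self.tiles[1] < 1:
            raise ValueError(f"tiles must be >= (1, 1), got {self.tiles}")
        if self.bins < 2:
            raise ValueError(f"bins must be >= 2, got {self.bins}")
        if self.clip_limit < 0:
            raise ValueError(f"clip_limit must be >= 0, got {self.clip_limit}")


@dataclass(frozen=True)
class MorphConfig:
    """Structuring element descriptor plus operation mode.

    ``selem`` is ``("disk", radius)`` or ``("rect", (h, w))``; both are
    symmetric about their center, which the duality and idempotence
    properties rely on.
    """

    selem: tuple = ("disk", 3)
    mode: str = "tophat_enhance"

    def footprint(self) -> np.ndarray:
        kind = self.selem[0]
        if kind == "disk":
            r = int(self.selem[1])
            if r < 0:
                raise ValueError(f"disk radius must be >= 0, got {r}")
            yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
            fp = (yy * yy + xx * xx) <= r * r
        elif kind == "rect":
            h, w = (int(v) for v in self.selem[1])
            if h < 1 or w < 1 or h % 2 == 0 or w % 2 == 0:
                raise ValueError(f"rectangle sides must be odd positives, got {h}x{w}")
            fp = np.ones((h, w), dtype=bool)
        else:
            raise ValueError(f"unknown structuring element kind {kind!r}")
        if not fp.any():
            raise ValueError("empty structuring element")
        return fp


# ---------------------------------------------------------------------------
# Adaptive histogram equalization
# ---------------------------------------------------------------------------

def _tile_edges(length: int, count: int) -> np.ndarray:
    """Start offsets of ``count`` contiguous, nearly equal tiles plus the end."""
    return np.round(np.linspace(0, length, count + 1)).astype(np.int64)


def _tile_lut(tile: np.ndarray, bins: int, peak: int, clip_limit: float) -> np.ndarray:
    """Intensity lookup table (length peak+1) for one tile.

    The CDF is rescaled so the lowest occupied level maps to 0 and the
    highest to ``peak``; a fully degenerate (single-level) tile keeps the
    identity mapping so constant regions stay constant.
    """
    if tile.min() == tile.max():
        return np.arange(peak + 1, dtype=np.int64)

    # equal-width bins over [0, peak]: level v falls in floor(v * bins / (peak+1))
    levels = np.arange(peak + 1, dtype=np.float64)
    bin_of = np.minimum((levels * bins / (peak + 1)).astype(np.int64), bins - 1)
    hist = np.bincount(bin_of[tile.ravel()], minlength=bins).astype(np.float64)
    if clip_limit > 0:
        threshold = clip_limit * tile.size / bins
        excess = np.maximum(hist - threshold, 0.0).sum()
        hist = np.minimum(hist, threshold) + excess / bins

    cdf = np.cumsum(hist)
    cdf_min = cdf[np.flatnonzero(cdf)[0]]
    total = cdf[-1]
    if total <= cdf_min:  # single occupied bin but multiple levels: spread over bin
        mapping = np.full(bins, peak / 2.0)
    else:
        mapping = (cdf - cdf_min) / (total - cdf_min) * peak

    return _round_half_up(mapping[bin_of]).astype(np.int64)


def ahe(img: GrayImage, cfg: AHEConfig | None = None) -> GrayImage:
    """Adaptive histogram equalization with tiled, bilinearly interpolated mappings.

    With a 1x1 tile grid and ``clip_limit`` 0 this reduces exactly to
    global histogram equalization.  Deterministic; output shape and bit
    depth match the input.
    """
    cfg = cfg or AHEConfig()
    tr, tc = cfg.tiles
    m, n = img.shape
    if m < tr or n < tc:
        raise ValueError(f"image {img.shape} smaller than tile grid {cfg.tiles}")

    peak = img.peak
    row_edges = _tile_edges(m, tr)
    col_edges = _tile_edges(n, tc)

    luts = np.empty((tr, tc, peak + 1), dtype=np.int64)
    for i in range(tr):
        for j in range(tc):
            tile = img.pixels[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            luts[i, j] = _tile_lut(tile, cfg.bins, peak, cfg.clip_limit)

    centers_r = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    centers_c = (col_edges[:-1] + col_edges[1:] - 1) / 2.0

    def _nodes(coords: np.ndarray, centers: np.ndarray):
        """Bracketing tile indices and interpolation weight for each coordinate."""
        hi = np.searchsorted(centers, coords, side="right")
        i1 = np.clip(hi, 0, len(centers) - 1)
        i0 = np.clip(hi - 1, 0, len(centers) - 1)
        span = centers[i1] - centers[i0]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(span > 0, (coords - centers[i0]) / np.where(span > 0, span, 1.0), 0.0)
        return i0, i1, np.clip(w, 0.0, 1.0)

    r0, r1, wr = _nodes(np.arange(m, dtype=np.float64), centers_r)
    c0, c1, wc = _nodes(np.arange(n, dtype=np.float64), centers_c)

    px = img.pixels
    r0c = r0[:, None]
    r1c = r1[:, None]
    c0c = c0[None, :]
    c1c = c1[None, :]
    v00 = luts[r0c, c0c, px]
    v01 = luts[r0c, c1c, px]
    v10 = luts[r1c, c0c, px]
    v11 = luts[r1c, c1c, px]

    wrc = wr[:, None]
    wcc = wc[None, :]
    out = (
        (1 - wrc) * (1 - wcc) * v00
        + (1 - wrc) * wcc * v01
        + wrc * (1 - wcc) * v10
        + wrc * wcc * v11
    )
    out = np.clip(_round_half_up(out), 0, peak).astype(np.int64)
    return GrayImage(out, img.bit_depth)


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

_PRIMITIVES = {
    "erode": ndimage.grey_erosion,
    "dilate": ndimage.grey_dilation,
    "open": ndimage.grey_opening,
    "close": ndimage.grey_closing,
}


def morpho_primitive(img: GrayImage, cfg: MorphConfig) -> GrayImage:
    """Flat grayscale erosion, dilation, opening or closing.

    Erosion is the neighborhood minimum, dilation the maximum; opening is
    dilation of the erosion and closing the erosion of the dilation.
    Borders use edge replication.
    """
    func = _PRIMITIVES.get(cfg.mode)
    if func is None:
        raise ValueError(f"unknown morphology mode {cfg.mode!r}; use one of {sorted(_PRIMITIVES)}")
    out = func(img.pixels, footprint=cfg.footprint(), mode="nearest")
    return GrayImage(out, img.bit_depth)


def morpho_enhance(img: GrayImage, cfg: MorphConfig | None = None) -> GrayImage:
    """Background enhancement: add the white top-hat, subtract the black top-hat."""
    cfg = cfg or MorphConfig()
    fp = cfg.footprint()
    opened = ndimage.grey_opening(img.pixels, footprint=fp, mode="nearest")
    closed = ndimage.grey_closing(img.pixels, footprint=fp, mode="nearest")
    out = img.pixels + (img.pixels - opened) - (closed - img.pixels)
    return GrayImage(np.clip(out, 0, img.peak), img.bit_depth)
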