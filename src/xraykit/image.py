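"""Grayscale image data model and raster/DICOM input-output.

The toolkit operates on plain 2-D grids of non-negative integer
intensities with a declared bit depth.  :class:`GrayImage` is the
universal currency passed between codecs, enhancers and metrics: pixels
live on the native ``[0, 2**bit_depth - 1]`` scale, row-major, origin at
the top-left corner, 0-based indices.

Raster formats (8/16-bit grayscale PNG and TIFF) are read and written
through :mod:`imageio`; DICOM reading is deliberately minimal —
single-frame MONOCHROME1/2 only, with rescale slope/intercept applied —
because the toolkit uses DICOM purely as a source of grayscale matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GrayImage",
    "CompressionResult",
    "UnsupportedFormatError",
    "read_gray",
    "write_gray",
    "requantize",
]

#: Rec.601 luminance weights used when a raster file turns out to be RGB.
_REC601 = np.array([0.299, 0.587, 0.114])

_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}
_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}


class UnsupportedFormatError(ValueError):
    """Raised for files or attribute combinations the toolkit does not handle."""


def _round_half_up(x: np.ndarray | float) -> np.ndarray:
    # np.rint rounds halves to even; the codecs need a deterministic,
    # platform-independent half-up rule.
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of integer intensities with a declared bit depth.

    Parameters
    ----------
    pixels:
        2-D integer array, every value in ``[0, peak]``.
    bit_depth:
        Number of bits per sample, between 1 and 16.  ``peak`` is always
        exactly ``2**bit_depth - 1`` (255 for the common 8-bit case).
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError(f"pixels must be a non-empty 2-D grid, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"pixels must be integer-valued, got dtype {arr.dtype}")
        if not (1 <= int(self.bit_depth) <= 16):
            raise ValueError(f"bit_depth must be in 1..16, got {self.bit_depth}")
        peak = (1 << int(self.bit_depth)) - 1
        lo, hi = int(arr.min()), int(arr.max())
        if lo < 0 or hi > peak:
            raise ValueError(f"pixel range [{lo}, {hi}] outside [0, {peak}]")
        arr = np.ascontiguousarray(arr.astype(np.int64, copy=False))
        arr.setflags(write=False)
        object.__setattr__(self, "pixels", arr)
        object.__setattr__(self, "bit_depth", int(self.bit_depth))

    # -- derived quantities -------------------------------------------------
    @property
    def peak(self) -> int:
        """Largest representable intensity, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def raw_bits(self) -> int:
        """Uncompressed size of the image in bits."""
        return self.height * self.width * self.bit_depth

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.bit_depth == other.bit_depth and np.array_equal(self.pixels, other.pixels)


def clamp_to_image(values: np.ndarray, like: GrayImage, bit_depth: int | None = None) -> GrayImage:
    """Round, clamp to ``[0, peak]`` and wrap a float array as a GrayImage."""
    depth = like.bit_depth if bit_depth is None else bit_depth
    peak = (1 << depth) - 1
    out = np.clip(_round_half_up(values), 0, peak).astype(np.int64)
    return GrayImage(out, depth)


@dataclass(frozen=True)
class CompressionResult:
    """Outcome of one codec run: reconstruction plus exact bit accounting."""

    codec: str
    reconstruction: GrayImage
    encoded_bits: int
    original_bits: int = field(default=0)

    @property
    def compression_ratio(self) -> float:
        """Raw size over encoded size; values below 1 mean expansion."""
        return self.original_bits / self.encoded_bits


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _depth_from_dtype(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise UnsupportedFormatError(f"unsupported raster sample type {dtype}; need uint8 or uint16")


def _read_raster(path: Path) -> GrayImage:
    import imageio.v3 as iio

    arr = iio.imread(path)
    depth = _depth_from_dtype(arr.dtype)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise UnsupportedFormatError(f"unsupported channel count {arr.shape[2]}")
        luma = arr[..., :3].astype(np.float64) @ _REC601
        arr = _round_half_up(luma).astype(np.int64)
    elif arr.ndim != 2:
        raise UnsupportedFormatError(f"unsupported raster dimensionality {arr.ndim}")
    return GrayImage(np.asarray(arr, dtype=np.int64), depth)


def _read_dicom(path: Path) -> GrayImage:
    import pydicom

    ds = pydicom.dcmread(path)
    frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if frames != 1:
        raise UnsupportedFormatError(f"multi-frame DICOM unsupported (NumberOfFrames={frames})")
    samples = int(getattr(ds, "SamplesPerPixel", 1) or 1)
    if samples != 1:
        raise UnsupportedFormatError(f"color DICOM unsupported (SamplesPerPixel={samples})")
    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise UnsupportedFormatError(
            f"unsupported PhotometricInterpretation={photometric!r}; need MONOCHROME1/2"
        )
    bits_stored = int(getattr(ds, "BitsStored", 16) or 16)
    depth = 8 if bits_stored <= 8 else 16
    peak = (1 << depth) - 1

    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    arr = arr * slope + intercept
    if photometric == "MONOCHROME1":  # inverted display convention
        arr = peak - arr
    arr = np.clip(_round_half_up(arr), 0, peak).astype(np.int64)
    return GrayImage(arr, depth)


def read_gray(path: str | Path) -> GrayImage:
    """Read a grayscale image from PNG, TIFF or single-frame grayscale DICOM.

    RGB rasters are converted to luminance with the Rec.601 weighted sum
    and rounded.  The bit depth is taken from the file's sample depth;
    DICOM ``BitsStored`` is mapped to 8 or 16.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    UnsupportedFormatError
        For multi-frame or color DICOM, or unknown sample layouts; the
        message names the offending attribute.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()
    if suffix in _RASTER_SUFFIXES:
        return _read_raster(path)
    if suffix in _DICOM_SUFFIXES or suffix == "":
        return _read_dicom(path)
    raise UnsupportedFormatError(f"unrecognized image extension {suffix!r}")


def write_gray(img: GrayImage, path: str | Path) -> None:
    """Write ``img`` losslessly as 8- or 16-bit grayscale PNG or TIFF.

    The round trip ``read_gray(write_gray(img))`` is pixel-exact; lossy
    containers (JPEG and friends) are rejected so fixtures can never be
    silently degraded.
    """
    import imageio.v3 as iio

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in _RASTER_SUFFIXES:
        raise UnsupportedFormatError(
            f"refusing to write {suffix!r}; use lossless .png/.tif/.tiff"
        )
    if img.bit_depth not in (8, 16):
        raise ValueError(f"raster output requires bit_depth 8 or 16, got {img.bit_depth}")
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    iio.imwrite(path, img.pixels.astype(dtype))


def requantize(img: GrayImage, bits: int) -> GrayImage:
    """Reduce an image to ``bits`` bits per pixel by uniform rescaling.

    Each pixel maps to ``round(v * (2**bits - 1) / peak)`` so full scale
    maps to full scale; the mapping is monotone and is the identity when
    ``bits == img.bit_depth``.
    """
    if not (1 <= bits <= img.bit_depth):
        raise ValueError(f"bits must be in 1..{img.bit_depth}, got {bits}")
    if bits == img.bit_depth:
        return img
    new_peak = (1 << bits) - 1
    out = _round_half_up(img.pixels * (new_peak / img.peak)).astype(np.int64)
    return GrayImage(out, bits)
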