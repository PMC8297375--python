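"""Run-length encoding and moment-preserving block truncation coding.

RLE is exactly lossless: each image row is scanned left to right and
maximal runs of a repeated intensity are stored as ``(value, length)``
pairs.  Runs never cross row boundaries, matching the common BMP/PCX
dialects, which keeps the stream trivially seekable by row.

BTC is lossy: the image is tiled into small blocks and each block is
replaced by two intensity levels plus a bitmap.  The levels are chosen
so the reconstructed block keeps the original block's mean and
(population) standard deviation — the classic moment-preserving
quantizer.  With block mean ``mu``, standard deviation ``sigma``,
``m = B*B`` pixels and ``q`` pixels at or above the mean::

    a = round(mu - sigma * sqrt(q / (m - q)))      # low level
    b = round(mu + sigma * sqrt((m - q) / q))      # high level

Pixels equal to the mean count toward the high group so the bitmap is
reproducible.  Degenerate blocks (constant, or all pixels on one side)
collapse to ``a = b = round(mu)``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .image import CompressionResult, GrayImage, _round_half_up

__all__ = [
    "RLEStream",
    "BTCStream",
    "CorruptStreamError",
    "rle_encode",
    "rle_decode",
    "btc_encode",
    "btc_decode",
]

_MAGIC_RLE = b"XRLE"
_MAGIC_BTC = b"XBTC"


class CorruptStreamError(ValueError):
    """An encoded stream violates its own invariants."""


# ---------------------------------------------------------------------------
# RLE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RLEStream:
    """Row-confined run-length stream: ordered ``(value, length)`` pairs."""

    runs: tuple[tuple[int, int], ...]
    shape: tuple[int, int]
    bit_depth: int

    @property
    def encoded_bits(self) -> int:
        """Each run stores its value (bit_depth bits) and a 16-bit length."""
        return len(self.runs) * (self.bit_depth + 16)

    def to_bytes(self) -> bytes:
        """Little-endian dump: 16-byte header then (uint16 value, uint16 length) pairs."""
        header = struct.pack(
            "<4sIIBB2x", _MAGIC_RLE, self.shape[0], self.shape[1], self.bit_depth, 0
        )
        body = b"".join(struct.pack("<HH", v, ln) for v, ln in self.runs)
        return header + body

    @classmethod
    def from_bytes(cls, blob: bytes) -> "RLEStream":
        magic, m, n, depth, _ = struct.unpack_from("<4sIIBB2x", blob)
        if magic != _MAGIC_RLE:
            raise CorruptStreamError(f"bad magic {magic!r}")
        runs = tuple(
            struct.unpack_from("<HH", blob, 16 + 4 * i)
            for i in range((len(blob) - 16) // 4)
        )
        return cls(runs, (m, n), depth)


def rle_encode(img: GrayImage) -> RLEStream:
    """Losslessly encode an image as maximal per-row runs."""
    runs: list[tuple[int, int]] = []
    for row in img.pixels:
        change = np.flatnonzero(np.diff(row)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(row)]))
        runs.extend((int(row[s]), int(e - s)) for s, e in zip(starts, ends))
    return RLEStream(tuple(runs), img.shape, img.bit_depth)


def rle_decode(stream: RLEStream) -> GrayImage:
    """Expand a run-length stream back into the original image."""
    m, n = stream.shape
    if not stream.runs:
        raise CorruptStreamError("empty run list")
    values = np.array([v for v, _ in stream.runs], dtype=np.int64)
    lengths = np.array([ln for _, ln in stream.runs], dtype=np.int64)
    if (lengths <= 0).any():
        raise CorruptStreamError("non-positive run length")
    total = int(lengths.sum())
    if total != m * n:
        raise CorruptStreamError(f"run lengths sum to {total}, expected {m * n}")
    ends = np.cumsum(lengths)
    starts = ends - lengths
    if ((starts // n) != ((ends - 1) // n)).any():
        raise CorruptStreamError("run crosses a row boundary")
    flat = np.repeat(values, lengths)
    return GrayImage(flat.reshape(m, n), stream.bit_depth)


# ---------------------------------------------------------------------------
# BTC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BTCStream:
    """Per-block two-level quantization: low/high levels plus a bitmap.

    ``low`` and ``high`` are ``(rows, cols)`` integer grids of block
    levels; ``bitmap`` is the padded-size boolean grid, True exactly
    where the original pixel was >= its block mean.
    """

    block_size: int
    low: np.ndarray
    high: np.ndarray
    bitmap: np.ndarray
    shape: tuple[int, int]
    bit_depth: int

    @property
    def n_blocks(self) -> int:
        return self.low.size

    @property
    def encoded_bits(self) -> int:
        """Two levels (bit_depth bits each) plus a B*B bitmap per block."""
        return self.n_blocks * (2 * self.bit_depth + self.block_size**2)

    def to_bytes(self) -> bytes:
        header = struct.pack(
            "<4sIIBB2x", _MAGIC_BTC, self.shape[0], self.shape[1],
            self.bit_depth, self.block_size,
        )
        body = (
            self.low.astype("<u2").tobytes()
            + self.high.astype("<u2").tobytes()
            + np.packbits(self.bitmap.astype(np.uint8)).tobytes()
        )
        return header + body

    @classmethod
    def from_bytes(cls, blob: bytes) -> "BTCStream":
        magic, m, n, depth, bsz = struct.unpack_from("<4sIIBB2x", blob)
        if magic != _MAGIC_BTC:
            raise CorruptStreamError(f"bad magic {magic!r}")
        pm, pn = -(-m // bsz) * bsz, -(-n // bsz) * bsz
        nb = (pm // bsz) * (pn // bsz)
        off = 16
        low = np.frombuffer(blob, "<u2", nb, off).astype(np.int64)
        off += 2 * nb
        high = np.frombuffer(blob, "<u2", nb, off).astype(np.int64)
        off += 2 * nb
        bits = np.unpackbits(np.frombuffer(blob, np.uint8, -1, off))[: pm * pn]
        grid = (pm // bsz, pn // bsz)
        return cls(bsz, low.reshape(grid), high.reshape(grid),
                   bits.reshape(pm, pn).astype(bool), (m, n), depth)


def btc_encode(img: GrayImage, block_size: int = 4) -> BTCStream:
    """Moment-preserving BTC encoding with edge-replication padding."""
    if block_size < 2:
        raise ValueError(f"block_size must be >= 2, got {block_size}")
    b = block_size
    m, n = img.shape
    pm, pn = -(-m // b) * b, -(-n // b) * b
    x = np.pad(img.astype_float(), ((0, pm - m), (0, pn - n)), mode="edge")

    blocks = x.reshape(pm // b, b, pn // b, b).swapaxes(1, 2)  # (rb, cb, b, b)
    mu = blocks.mean(axis=(2, 3))
    sigma = blocks.std(axis=(2, 3))  # population SD
    above = blocks >= mu[..., None, None]
    q = above.sum(axis=(2, 3)).astype(np.float64)
    m_px = float(b * b)

    degenerate = (q == 0) | (q == m_px) | (sigma == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = mu - sigma * np.sqrt(q / (m_px - q))
        bb = mu + sigma * np.sqrt((m_px - q) / q)
    a = np.where(degenerate, mu, a)
    bb = np.where(degenerate, mu, bb)

    peak = img.peak
    low = np.clip(_round_half_up(a), 0, peak).astype(np.int64)
    high = np.clip(_round_half_up(bb), 0, peak).astype(np.int64)
    # rounding may not cross the levels, but guard the invariant anyway
    high = np.maximum(low, high)

    bitmap = above.swapaxes(1, 2).reshape(pm, pn)
    return BTCStream(b, low, high, bitmap, (m, n), img.bit_depth)


def btc_decode(stream: BTCStream) -> GrayImage:
    """Reconstruct from a BTC stream: high level where the bitmap is set, else low."""
    if (stream.low > stream.high).any():
        raise CorruptStreamError("block with low level > high level")
    b = stream.block_size
    low = np.repeat(np.repeat(stream.low, b, axis=0), b, axis=1)
    high = np.repeat(np.repeat(stream.high, b, axis=0), b, axis=1)
    full = np.where(stream.bitmap, high, low)
    m, n = stream.shape
    return GrayImage(full[:m, :n], stream.bit_depth)


def btc_compress(img: GrayImage, block_size: int = 4) -> CompressionResult:
    """Encode-decode convenience wrapper with bit accounting."""
    stream = btc_encode(img, block_size)
    return CompressionResult(
        codec="BTC",
        reconstruction=btc_decode(stream),
        encoded_bits=stream.encoded_bits,
        original_bits=img.raw_bits,
    )
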