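"""Compress -> enhance -> evaluate orchestration.

:func:`run_benchmark` reproduces the canonical 11-row evaluation matrix:
each codec (DCT, DWT, BTC, RLE) is run once, its reconstruction is
scored against the original, and the same reconstruction is then passed
through the enhancers (AHE for every codec; morphological enhancement
for DWT, BTC and RLE) and scored again.  Metrics are always computed
against the ORIGINAL image so all rows are commensurable.

RLE is exactly lossless on the raw image, which would pin its row at
MSE 0 / PSNR inf.  To let the RLE rows exercise the quality metrics the
benchmark can requantize the image to ``rle_prequant_bits`` bits before
encoding (4 by default) and re-expand the decoded result to the original
depth; setting the flag to 0 keeps RLE strictly lossless.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

from .blockcodec import btc_compress, rle_decode, rle_encode
from .enhance import AHEConfig, MorphConfig, ahe, morpho_enhance
from .image import CompressionResult, GrayImage, _round_half_up, requantize
from .metrics import SSIMParams, QualityReport, quality_report
from .transform import TransformCodecConfig, dct_compress, dwt_compress

__all__ = [
    "BenchmarkConfig",
    "BenchmarkRow",
    "BenchmarkTable",
    "CANONICAL_LABELS",
    "run_benchmark",
    "compression_ratio",
]

#: Canonical row labels, in order.  Every codec gets an AHE row; DCT has
#: no morphological row in the canonical table.
CANONICAL_LABELS = (
    "DCT",
    "AHE(DCT)",
    "DWT",
    "AHE(DWT)",
    "MO(DWT)",
    "BTC",
    "AHE(BTC)",
    "MO(BTC)",
    "RLE",
    "AHE(RLE)",
    "MO(RLE)",
)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Bundle of every stage's configuration."""

    transform: TransformCodecConfig = field(default_factory=TransformCodecConfig)
    btc_block_size: int = 4
    rle_prequant_bits: int = 4   # 0 disables pre-quantization (strictly lossless RLE)
    ahe: AHEConfig = field(default_factory=AHEConfig)
    morph: MorphConfig = field(default_factory=MorphConfig)
    ssim: SSIMParams = field(default_factory=SSIMParams)
    full_grid: bool = False      # append the off-canon MO(DCT) row

    def __post_init__(self) -> None:
        if self.rle_prequant_bits < 0:
            raise ValueError("rle_prequant_bits must be >= 0")


@dataclass(frozen=True)
class BenchmarkRow:
    index: int
    label: str
    ssim: float
    mse: float
    psnr: float


@dataclass(frozen=True)
class BenchmarkTable:
    """Ordered rows of method-combination labels with their quality triples."""

    rows: tuple[BenchmarkRow, ...]
    ratios: dict[str, float] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.rows)

    def row(self, label: str) -> BenchmarkRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_csv(self, path: str | Path) -> None:
        """Write ``index,method,ssim,mse,psnr``; infinity rendered as ``inf``."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["index", "method", "ssim", "mse", "psnr"])
            for r in self.rows:
                writer.writerow(
                    [r.index, r.label, f"{r.ssim:.17g}", f"{r.mse:.17g}",
                     "inf" if math.isinf(r.psnr) else f"{r.psnr:.17g}"]
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "BenchmarkTable":
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.append(
                    BenchmarkRow(
                        index=int(rec["index"]),
                        label=rec["method"],
                        ssim=float(rec["ssim"]),
                        mse=float(rec["mse"]),
                        psnr=float(rec["psnr"]),
                    )
                )
        return cls(tuple(rows))


def compression_ratio(stream_bits: int, img: GrayImage) -> float:
    """Raw image bits over encoded bits; < 1 means honest expansion."""
    if stream_bits <= 0:
        raise ValueError(f"stream_bits must be positive, got {stream_bits}")
    return img.raw_bits / stream_bits


def _rle_compress(img: GrayImage, prequant_bits: int) -> CompressionResult:
    """RLE with optional bit-depth pre-quantization.

    When pre-quantization is active the decoded image is re-expanded to
    the original depth by the inverse full-scale mapping so the metrics
    compare like with like.
    """
    if prequant_bits and prequant_bits < img.bit_depth:
        small = requantize(img, prequant_bits)
        stream = rle_encode(small)
        decoded = rle_decode(stream)
        recon_px = _round_half_up(decoded.pixels * (img.peak / small.peak)).astype(int)
        recon = GrayImage(recon_px, img.bit_depth)
    else:
        stream = rle_encode(img)
        recon = rle_decode(stream)
    return CompressionResult(
        codec="RLE",
        reconstruction=recon,
        encoded_bits=stream.encoded_bits,
        original_bits=img.raw_bits,
    )


def run_benchmark(img: GrayImage, config: BenchmarkConfig | None = None) -> BenchmarkTable:
    """Produce the canonical 11-row compression x enhancement matrix.

    Enhancement rows reuse the parent codec row's reconstruction (AHE
    and MO are applied to the already-decompressed image), and every row
    is scored against the original input.  The run is fully
    deterministic for a fixed image and configuration.
    """
    config = config or BenchmarkConfig()

    def guarded(label: str, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:  # re-raise with the failing row's label
            raise RuntimeError(f"benchmark stage {label!r} failed: {exc}") from exc

    results = {
        "DCT": guarded("DCT", dct_compress, img, config.transform),
        "DWT": guarded("DWT", dwt_compress, img, config.transform),
        "BTC": guarded("BTC", btc_compress, img, config.btc_block_size),
        "RLE": guarded("RLE", _rle_compress, img, config.rle_prequant_bits),
    }

    labels = list(CANONICAL_LABELS)
    if config.full_grid:
        labels.append("MO(DCT)")

    rows = []
    for i, label in enumerate(labels, start=1):
        if "(" in label:
            enhancer, codec = label.rstrip(")").split("(")
            base = results[codec].reconstruction
            if enhancer == "AHE":
                test = guarded(label, ahe, base, config.ahe)
            else:
                test = guarded(label, morpho_enhance, base, config.morph)
        else:
            test = results[label].reconstruction
        report: QualityReport = guarded(label, quality_report, img, test, config.ssim)
        rows.append(BenchmarkRow(i, label, report.ssim, report.mse, report.psnr))

    ratios = {name: res.compression_ratio for name, res in results.items()}
    return BenchmarkTable(tuple(rows), ratios)
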