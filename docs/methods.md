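# Methods

This note records the models, defaults and numerical choices behind
`xraykit`, and what the test suite does and does not demonstrate.

## Image model

All stages share one currency: a 2-D grid of non-negative integers with
a declared bit depth `d ∈ {1..16}` and peak value `2^d − 1`. Pixels are
row-major with the origin at the top-left. Metrics always operate on
this native scale — MSE is never normalized to `[0, 1]`, so the peak
term of PSNR is dimensionally consistent with it. Rounding throughout
the package is deterministic half-up (`floor(x + 0.5)`) rather than
banker's rounding, so encoded streams and reconstructions are bit-exact
across platforms.

DICOM support is deliberately minimal: single-frame MONOCHROME1/2 with
rescale slope/intercept applied and the result clamped to `[0, peak]`;
MONOCHROME1 is inverted to the white-is-bright convention. Everything
else (multi-frame, color, other photometric interpretations) is
rejected with the offending attribute named. RGB rasters are collapsed
by the Rec.601 luminance sum. The toolkit never writes DICOM, and
refuses lossy raster containers so fixtures cannot silently degrade.

## Codecs

### Two-stage blockwise DCT (lossy)

Stage one reduces spatial resolution: block averaging at
`downsample_factor` (default 2) followed by bilinear interpolation back
to the original grid, with pixel-center alignment. Stage two pads the
result to a multiple of `block_size` (default 8) by edge replication,
applies the orthonormal type-II 2-D DCT per block, keeps the
`ceil(keep_fraction · B²)` largest-magnitude coefficients per block
(default keep_fraction 0.25), and inverts. Ties in magnitude are broken
by zig-zag scan rank, low frequency first, so the retained set is
unique. Because the transform is orthonormal, discarding a coefficient
removes exactly its squared value from the reconstruction energy, which
makes magnitude ranking the correct greedy rule and makes the MSE
monotone in `keep_fraction`.

The encoded size is analytic, not an entropy-coded container: 16 bits
per retained coefficient plus a B²-bit significance bitmap per block.
The factor and interpolation of stage one are design choices — the
procedure's two purposes (resolution reduction, then blockwise coding)
constrain the structure but not the numbers.

### Single-level Haar DWT (lossy)

One level of the orthonormal 2-D Haar analysis (closed-form 2×2
butterflies; odd dimensions are edge-padded to even and cropped back on
inversion). Haar was chosen as the wavelet family because it admits
exact closed-form tests and is the canonical entry point of
wavelet-based image coding; the analysis level and family are
config-extensible. Each of the four subbands is uniformly quantized to
`coeff_bits` bits (default 4) over that subband's own `[min, max]`
range — per-subband ranges keep a 4-bit budget meaningful across the
disparate scales of the approximation and detail bands. The two range
endpoints per subband are charged as 32-bit reals in the header. The
per-coefficient quantization error is bounded by half a step,
`Δ/2 = (max − min) / (2(2^bits − 1))`, which the tests check
coefficient-wise.

### Run-length encoding (lossless)

Maximal runs of identical intensities, scanned row-major and confined
to rows (no wrap), stored as (value, 16-bit length) pairs. Row
confinement matches the common BMP/PCX dialects and keeps streams
seekable by row; it costs at most one extra run per row versus a
whole-raster run. RLE is exactly lossless on every input; compression
depends entirely on image content, from `raw_bits/24`-per-row on
constant images to ~4× expansion on a checkerboard — expansion is
reported honestly as a ratio below 1.

### Moment-preserving BTC (lossy)

Blocks of side 4 by default (the classic choice). Per block with mean
μ, population SD σ and `q` pixels at or above the mean out of `m = B²`:

    a = round(μ − σ√(q/(m−q)))    b = round(μ + σ√((m−q)/q))

and a bitmap marking the ≥-μ pixels. Pixels exactly at the mean count
toward the high group — the tie rule must be deterministic for the
bitmap to be reproducible. Degenerate blocks (σ = 0 or one-sided)
collapse to `a = b = round(μ)`. Before rounding, the reconstruction has
exactly the block's mean and SD; rounding perturbs them by at most 0.5
(mean) and ~1.0 (SD), the tolerances the tests assert. Any block taking
at most two distinct values is a fixed point.

## Enhancers

### Tiled AHE / CLAHE

The image is split into a `tiles` grid (default 8×8) of contiguous,
nearly equal tiles. Per tile, a histogram over `bins` equal-width bins
(default 256) spanning `[0, peak]` is formed; with `clip_limit > 0`
bins are clipped at `clip_limit ×` the mean bin height and the excess
is redistributed uniformly (CLAHE); the CDF is then rescaled by
`(cdf − cdf_min)/(count − cdf_min) · peak` so the lowest occupied level
maps to 0. A fully degenerate single-level tile keeps the identity
mapping, so constant regions remain constant. Each pixel's output is
the bilinear interpolation of the four surrounding tile mappings, with
tile centers as nodes; pixels outside the outer centers clamp to the
available mappings. With one tile and no clipping the method reduces
*exactly* to global histogram equalization, which is the test oracle.
Default clip limit is 0 (plain AHE); clipping is exposed because it is
the variant practitioners reach for on noisy radiographs.

### Morphological background enhancement

Flat grayscale morphology (neighborhood min/max and compositions)
under a symmetric structuring element, default disk of radius 3 —
smaller than anatomical structures, larger than pixel noise at the
256–512 px scale. Borders use edge replication, which preserves the
duality `dilate(x) = peak − erode(peak − x)` and the idempotence of
opening/closing. The enhancement composite is

    enhanced = clamp(img + (img − open(img)) − (close(img) − img))

i.e. white top-hat added, black top-hat subtracted: the standard
contrast composite for improving background uniformity rather than
sharpening. The primitives are fixed; the composite is the package's
design choice for "background enhancement".

## Metrics

MSE and PSNR are as stated in the README. PSNR of identical images is
reported as `+inf` (rendered `inf` in CSV). SSIM uses the
three-component form with exponents α = β = γ = 1, `K1 = 0.01`,
`K2 = 0.03`, `C3 = C2/2`, and an 11×11 Gaussian window with σ = 1.5 —
the field-standard mean-SSIM configuration. Local moments are weighted
population moments; windows are restricted to positions fully inside
the image. The implementation agrees with scikit-image's
`structural_similarity` (gaussian_weights, population covariance) to
better than 1e-10, and that library is used only as a cross-check, never
as the implementation. Uniform and single-global-window modes exist for
sensitivity analysis and closed-form tests: on constant images only the
luminance term survives, `SSIM = (2ab + C1)/(a² + b² + C1)`.

A note on PSNR conventions: compact write-ups sometimes print PSNR as
`20 log₁₀(255/MSE)`, which is dimensionally inconsistent (the error
term under the logarithm must be an RMS amplitude, not a squared
error). The toolkit implements the standard
`10 log₁₀(peak²/MSE) ≡ 20 log₁₀(peak/√MSE)` and makes no attempt to
match numbers produced under other readings. Similarly, the collapsed
one-line "simplified SSIM" sometimes shown with σxσy in the luminance
slot is treated as a typo for μxμy; the component form is unambiguous
and is what is implemented.

## Phantoms

The generator emulates only the gross intensity layout of a frontal
chest radiograph: dark air background (8% of peak), a bright body
ellipse (70%), two darker lung ellipses (28%), thin bright rib bands
(90%), plus clamped additive Gaussian noise. Geometry constants are
fixed in code so fixtures are stable. It does **not** model X-ray
physics — no beam hardening, scatter, Poisson noise or anatomical
texture — so passing tests demonstrate algorithmic correctness and
ordering properties, not clinical image quality. In particular the
phantom is piecewise-smooth, which flatters block codecs: on the
standard phantom BTC attains the highest codec PSNR, whereas on
textured clinical radiographs transform coding typically leads. The
benchmark therefore reports the codec ranking as a concordance note
rather than asserting it.

Other kinds are extremal by construction: `constant` (maximal RLE
ratio), `checkerboard` (worst-case RLE), `blocky` (8×8 constant tiles;
exactly representable by BTC and by DC-only DCT when grid-aligned),
`ramp` (uniform histogram). All randomness flows through
`numpy.random.default_rng(seed)`.

## Benchmark

The canonical table has 11 rows in fixed order: DCT, AHE(DCT), DWT,
AHE(DWT), MO(DWT), BTC, AHE(BTC), MO(BTC), RLE, AHE(RLE), MO(RLE) — a
morphological DCT row is not part of the canon but `--full-grid`
appends it. Two conventions make the rows commensurable:

- every row is scored against the **original** image, including
  enhanced rows (enhancers intentionally change the image, so their
  similarity scores drop — that is information, not error);
- enhancement rows reuse their parent codec row's reconstruction.

Raw RLE would pin its rows at zero error, so the benchmark requantizes
to `rle_prequant_bits` (default 4) before RLE and re-expands after
decoding; setting the flag to 0 restores strict losslessness. The
problem size used throughout testing and the acceptance script is a
256×256 phantom with noise σ = 2 intensity units, seed-controlled —
large enough for an 8×8 tile grid and 11×11 SSIM windows, small enough
to keep the full suite interactive.

## Known limitations

- Encoded sizes are analytic bit counts, not real bitstreams; no
  entropy coding, so ratios understate what a production codec with an
  arithmetic-coded back end would achieve.
- Single-level, Haar-only DWT by default; multi-level pyramids and
  longer filters are out of scope.
- SSIM exponents other than 1 use a signed power for the (possibly
  negative) structure term.
- DICOM reading covers exactly the single-frame grayscale subset
  described above.
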