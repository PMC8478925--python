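# Methods

This note documents the models, parameter choices and numerical conventions
behind `virtualck`, and what the synthetic phantoms do and do not establish.

## Color deconvolution

Brightfield absorption follows Beer–Lambert: per RGB channel,
`OD_c = -log10((v_c + ε)/255)` with ε = 1 so an 8-bit value of 0 stays
finite (configurable). Concentrations are `OD · M⁻¹` where `M` is the
stain matrix — by default the published Ruifrok–Johnston
hematoxylin/eosin/DAB vectors, row-normalized to unit length; any 3×3
non-singular, non-negative matrix can be supplied. Negative solutions
(out-of-gamut colors) are clamped to zero. The forward renderer
`stain_to_rgb` is the exact inverse up to 8-bit quantization; round-trip
error stays below 0.02 OD while all rendered channels remain ≳ 40, and
grows near the dark end where quantization and the log-ε dominate — an
intrinsic 8-bit limit, not an implementation artifact.

Single-stain channels are mapped to 8-bit rasters linearly with saturation
at `c_max = 1.0` OD, a convention chosen so the pipeline's DAB threshold of
80 corresponds to concentration ≈ 0.314. The absolute 0–255 scale of
deconvolved channels is not standardized anywhere, so `c_max` is exposed as
configuration.

## Registration

Assumption: a re-stained section differs from its first scan by pure
translation (no rotation or non-rigid deformation), which the de-stain /
re-stain protocol justifies. Estimation operates on binarized stain
channels: eosin for H&E, DAB for CK. Binarization is locally adaptive —
foreground iff value > (Gaussian-weighted local mean − offset) with block
151, σ = (block−1)/6, reflect boundary, offset 10 — followed by removal of
8-connected components with area strictly below 200 px. Blocks larger than
the image are legal (the Gaussian window simply spans it).

The shift between two masks is the argmax of their zero-padded *linear*
cross-correlation (computed via FFT, rounded to exact integer counts so
ties are deterministic and break to the lexicographically smallest shift;
wrap-around peaks cannot win). Convention: the returned `(drow, dcol)` is
the displacement of the moving (CK) content relative to the reference
(H&E); sampling CK at `(r + drow, c + dcol)` realigns it.

Global estimation runs at 32× mean-pooled resolution, so its error is
bounded by the downsample factor; local refinement then measures per-patch
residuals (1024-px patches within 10,240-px regions at full resolution),
skips near-white patches, and averages per-region after outlier rejection.
The rejection rule is component-wise: a patch shift is discarded if either
component deviates from the region median by more than 3 × MAD, with the
MAD floored at 1 px. The floor matters: patches straddling the slide
background correlate at zero displacement (the white surround is static in
both masks), and a wider band would re-admit them whenever the true
residual is small. Regions with no usable patch inherit the global shift.

## Patch curation

Registered pairs are tiled into disjoint 256×256 patches (partial edge
tiles dropped; 0-based half-open origins). Grayscale is ITU-R 601 luma,
rounded. All threshold comparisons are strict, matching their stated
directions: white background ⇔ > 95 % of pixels > 220; little-dyed ⇔ < 5 %
of pixels with 8-bit DAB > 80. Little-dyed pairs are subsampled uniformly
without replacement (seeded, recorded in provenance) to
`k = round(f/(1−f) · n_informative)`, which puts their share within one
pair of the target fraction f = 0.10 of the final set; the fraction is
interpreted relative to the final set, after white-background removal.

## The adversarial staining model

Generator: U-Net — `depth` stride-2 4×4 convolutions (widths doubling from
`base`, capped at 8×base), mirrored by transposed convolutions with skip
concatenation, tanh output on inputs scaled to [−1, 1]. No dropout
anywhere, so inference is bit-deterministic — a requirement for a scoring
pipeline. Discriminator: patch-level classifier over the concatenated
(H&E, CK) pair; with the default three stride-2 blocks its receptive field
is the customary ~70 px. Normalization is per-sample instance norm (batch
size is 1). Weights initialize N(0, 0.02); the adversarial objective is
binary cross-entropy on the patch grid, with the non-saturating target-1
form driving the generator.

The generator loss adds two reconstruction terms with **mean** (not sum)
reduction, so λ₁ = 10 and λ₂ = 0.9 are resolution-independent: an RGB L1 on
[0,1]-scaled intensities, and an HED-space L1 computed through a smooth
deconvolution that omits 8-bit rounding and the non-negativity clamp so
gradients flow (the scoring path uses the quantized version; the
divergence is intentional and documented). The HED term is computed on
OD-scale concentrations of [0,1] inputs.

Training alternates one discriminator step (real + fake, each weighted ½)
with one generator step per sample, Adam with lr 2·10⁻⁴, β₁ = 0.5,
β₂ = 0.999, 200 epochs at full scale. The whole stack is NumPy with
hand-written backward passes (im2col/col2im; the transposed convolution is
the exact adjoint of the strided convolution), verified against
finite-difference gradients in the test suite. A reduced configuration
(64×64 patches, base 8, depth 3, single-block discriminator) trains in
seconds on one CPU and is used throughout the tests; the full-scale
configuration is the default in `PipelineConfig`.

## dTSR scoring

Per hotspot polygon (0-based level-0 vertices, rasterized with
`skimage.draw.polygon2mask`; pixels outside the polygon are whitened to
background): tissue = grayscale < 200, tumor = 8-bit DAB > 80 **restricted
to tissue** so that tumor + stroma = tissue exactly (DAB-positive pixels
outside the tissue mask are not counted), stroma = tissue \ tumor, and
dTSR = 100·stroma/(tumor+stroma). The slide score is the unweighted mean
over hotspots; class is dTSR-high iff the mean is strictly greater than
the 65 % cut-off. A tissue-free hotspot raises an undefined-score error
rather than returning a number.

## Agreement evaluation

The 2×2 table is fixed as rows = vTSR {low, high}, columns = dTSR
{low, high}. κ = (p_o − p_e)/(1 − p_e) from the table's own margins;
p_e = 1 raises an undefined-κ signal. AUC is the Mann–Whitney rank-sum
with half credit for ties (equivalently, trapezoidal area under the
empirical ROC), positive class = vTSR-high, scores = continuous dTSR
percent. Report percentages are rounded half-up to two decimals.
Recomputing κ from the published table's printed counts (98/30/23/207)
gives 0.6738 by this standard formula, which differs from the 0.623
printed alongside those counts; the package implements the standard
formula and makes no attempt to reverse-engineer the difference.

## Synthetic phantoms

Each phantom is a disc of tissue on a white canvas containing a compact
tumor grown outward from the tissue center to an exact pixel count
(`round(tumor_fraction · |tissue|)`, counting non-lumen pixels), plus pale
lumen-like blobs at two scales: gland-size discs (radius 6–14 px) that
survive 32× downsampling and drive the global correlation, and
nuclei-scale speckle (radius 1–3 px) that sharpens the patch-level
correlation peak. Without such texture, adaptive-threshold masks of a flat
phantom would be structure-free — something no real slide is. Stain
chemistry (OD units): stroma H 0.25 / E 0.5; tumor H 0.6 / E 0.3; lumina
H 0.15 / E 0.1; the CK render uses an H 0.25 counterstain with DAB 0.9 in
tumor. These levels put every class cleanly on its side of the pipeline's
thresholds (DAB 0.9 → 8-bit 230 ≫ 80; all tissue luma < 200 with margin).
Geometry is hard-edged (no anti-aliasing) so area accounting is exact;
additive Gaussian noise (default σ = 3 in 8-bit units) is applied after
rendering and clamped; truth masks are defined pre-noise. Everything is
deterministic under the `PhantomSpec` seed.

What passing phantom tests shows: the registration, curation, scoring and
evaluation arithmetic is correct, and the adversarial model can learn a
deterministic H&E→CK mapping. What it does not show: performance on real
tissue, where staining variability, cellular texture, scanning artifacts
and ambiguous histology dominate — the phantoms deliberately model none of
these.

## Problem sizes used in tests and the acceptance script

Registration phantoms are 2048 px (64 px at 32× downsampling) with
planted shifts (64, −96) and (70, 0); training runs use eight 64×64 pairs,
150 generator steps, three seeds; the scoring sweep covers true stroma
fractions 10–90 % at 512 px; the benchmark is ten 256-px slides spanning
fractions 10–95 %. These sizes were chosen as the smallest at which each
property is non-trivially exercised on a single CPU.

## Known limitations

- Translation-only registration; rotation or non-rigid deformation is out
  of scope by design.
- Flat PNG/TIFF rasters only; pyramidal WSI formats must be exported to a
  single level first.
- The NumPy network stack targets correctness and CPU-scale experiments,
  not full-scale 256×256/200-epoch training runs.
- Hotspot selection is manual (annotation input); automatic hotspot
  detection is not implemented.
- Survival and clinicopathologic association analyses are not part of the
  package.
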