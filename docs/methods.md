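# Methods

This note documents the models behind each analysis stage, what the
synthetic-data generators do and do not emulate, the numerical choices,
and the design decisions taken where several reasonable options existed.

## Synthetic-data generators

The generators exist so that every stage of the pipeline can be exercised
end to end, with known ground truth, at the acquisition scales of a typical
multimodal glycation study (2048 × 2048-px two-channel images, 100 Raman
spectra per condition acquired as a 10 × 10 grid, 512 × 512-px / 2.5 µm AFM
scans). All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, one sub-stream per generated object,
so equal seeds give bit-identical outputs.

### Glycation presets

A preset ties a (ribose concentration, incubation day) cell to three effect
sizes: the Raman band-change strength `effect_scale`, the fraction `g` of
collagen signal transferred from the SHG into the TPEF channel, and the
surface roughness. All three follow one dose–time response

    r(c, d) = log(1 + c / 5 mM) / log(1 + 200 mM / 5 mM) · (d / 30 days)

— saturating in concentration, linear in time, 0 for untreated and 1 at
200 mM / 30 d. No quantitative dose–response is available for these
effects, so the response shape and its two calibration constants are the
package's own choices:

* `G_MAX = 0.26`: with channels calibrated to equal expected means, the
  expected TPEF ratio is (1 + g)/2, so g = 0.26 reproduces the upper ratio
  (~0.63) reported for strongly glycated tissue at full dose.
* Roughness interpolates linearly in `r` between 11.64 nm (untreated) and
  21.78 nm (200 mM), the reported mean RMS roughness values.

### Raman spectra

Eleven collagen/elastin fingerprint bands (816, 856, 873, 922, 938, 1002,
1244, 1272, 1451, 1640, 1666 cm⁻¹) are modeled as Lorentzian lines; widths
default to 12–20 cm⁻¹ FWHM and relative amplitudes are set so the CH₂/CH₃
band at 1451 cm⁻¹ and amide I dominate. Glycation shifts amplitudes
linearly with `effect_scale` via a documented delta table: increases at 938
cm⁻¹ and new bands at 1372 (broad, 30 cm⁻¹ FWHM), 1634 and 1643 cm⁻¹;
decreases at 922, at the amide III envelope (1272) and at amide I (1666).
The 1451 band is the normalization anchor and is never modified; for that
reason the CH₂-region decrease that a discriminant analysis of real tissue
shows near 1442 cm⁻¹ has no counterpart in this 11-band model — a known
model limitation.

Each generated spectrum adds, on top of the band sum:

* a per-spectrum log-normal multiplicative gain (sd 0.10 of log-intensity)
  — the acquisition-gain variation EMSC is designed to divide out;
* a random linear baseline (slope sd 2·10⁻⁴ per cm⁻¹, offset sd 0.05);
* per-band relative amplitude jitter (sd 3%);
* spot-to-spot glycation heterogeneity: the preset's `effect_scale` is
  perturbed by N(0, 0.02) and clipped to [0, 1], emulating inhomogeneously
  distributed crosslinks (untreated spots can thus show small native-
  crosslink-like effects);
* i.i.d. Gaussian noise, sd 1% of the maximum band amplitude.

The heterogeneity sd is the one generator constant that was calibrated
against the pipeline itself: it was chosen (once, from a small grid run
across several seeds) so that the 5-fold PLS-LDA accuracy of the generated
10/20/30-day datasets brackets the ordering reported for real tissue
(~65% → ~82% → ~90%); sd 0.02 yields roughly 0.56 / 0.81 / 0.95. Because
the class information is a single latent dose dimension, this knob directly
sets the difficulty of the classification task.

What the generator does **not** emulate: cosmic-ray spikes, detector
etaloning, wavenumber miscalibration, water-band hydration shifts, or any
spectral signature with more than one latent degree of freedom per class.
A high CV accuracy here therefore demonstrates that the preprocessing and
classifier recover a dose-ordered signal under gain/baseline/noise
nuisance, not that real tissue is equally separable.

### TPEF/SHG image pairs

Collagen is rendered as wavy ridges (Gaussian cross-section, σ = 3 px,
sinusoidal centerline) and elastin as parallel rectilinear ridges, both
with jittered stratified vertical placement so the fields are densely and
fairly uniformly packed at the 100-px ROI scale, as in well-organized
unidirectional fiber bundles. The default 400 collagen / 200 elastin
fibers keep the per-ROI channel means within a few percent of the
full-image means; sparser fields would make 10-ROI ratio estimates very
noisy. Channels are composed as

    SHG  = (1 − g)·C + |N(0, σ)|        TPEF = E + g·C + |N(0, σ)|

Noise is folded-normal so the channels stay non-negative without clipping
and the expected channel means remain exactly computable (the folded
normal has mean σ√(2/π)). At σ = 0, TPEF + SHG = E + C exactly for any g:
glycation transfers signal, it does not create it. The closed-form
expected ratio (mE + g·mC + c)/(mE + mC + 2c) and its inverse in `g` are
exposed (`expected_tpef_ratio`, `fluor_transfer_for_ratio`), along with
`calibrate_channels`, which rescales the elastin amplitude so the
untreated expected ratio is exactly 0.5. Not emulated: point-spread
functions, photon (Poisson) statistics, depth attenuation, fiber
crossings in 3-D.

### Topographies

Height = tilt plane (a·x + b·y + c, in nm/px) + per-scan-line Gaussian
offsets + raised-cosine D-banding + white Gaussian roughness. The banding
waveform `A/2 · (1 + cos 2πu/d)` (u = nm coordinate along the fiber axis)
is non-negative with unambiguous crest maxima; all fibrils share one
phase. Configurations violating Nyquist (d ≤ 2·pixel) are rejected. The
white-noise roughness model means a realistic-roughness scan (σ ≈ 12–22 nm)
buries 3-nm banding — the pipeline therefore measures roughness and
D-period on separate scans, mirroring how flat fibril-resolving scans are
chosen for D-band measurement in practice.

## Preprocessing (EMSC)

The "five linear functions" background is implemented as five
piecewise-linear hat functions on an equal 4-interval partition of the
fingerprint region (a linear spline basis: genuinely linear pieces that
span constant and slowly varying backgrounds); polynomial degrees 0–4 are
available as an alternative (`kind="poly"`), and the choice is recorded in
the preprocessing call. The EMSC fit is ordinary least squares of the
spectrum on [reference | basis]; the corrected spectrum `(s − B a)/b`
keeps the chemical residual. Fits with |b| < 10⁻⁸ are rejected as
degenerate. Spectra on a different axis are linearly interpolated onto the
reference axis. Normalization divides by the maximum intensity within
1451 ± 5 cm⁻¹ (window maximum rather than single-point lookup, robust to
axis discretization); crop boundaries are closed intervals.

## PLS-LDA

PLS is NIPALS PLS2 on the centered spectra matrix against the centered
one-hot class matrix (centering only, no variance scaling — spectra are
already band-normalized). Convergence tolerance 10⁻¹⁰ on the weight
vector; a collapsed deflation reduces the component count with a warning.
The default of 10 components is a conventional choice for ~500-spectrum
Raman datasets and is logged with each report. LDA solves the generalized
symmetric eigenproblem S_b v = λ S_w v on the PLS scores (ridge ε
proportional to trace(S_w) added only if S_w is numerically singular, with
a warning); for two classes LD1 equals the Fisher direction S_w⁻¹(m₁−m₂),
which the tests verify against the closed form. Prediction is nearest
class mean in LD space (Euclidean; ties go to the lowest class index).

Cross-validation uses stratified folds shuffled by the given seed; all
training-dependent statistics are refit inside each fold. The confusion
matrix pools out-of-fold predictions (rows = true class); per-fold
accuracies and their mean are reported alongside the pooled accuracy.
LD loading spectra are the LD directions composed with the PLS rotation,
sign-fixed so each loading's largest-magnitude element is positive; the
default loadings come from a model fit on all data (fold-wise loadings can
be computed by fitting on any subset).

## TPEF/SHG ratios

ROI top-left corners are drawn uniformly over all valid placements
(overlap permitted; a rejection-sampling `no_overlap` switch exists).
Per-ROI channel means are averaged across ROIs first and the ratio formed
on the averaged intensities (ratio of means — the form the defining
equations take on mean intensities); per-ROI pairs are kept as
diagnostics, and the SHG ratio is stored as 1 − TPEF ratio so the identity
holds exactly in floating point. Pixel coordinates are 0-based, row-major;
ROIs are half-open ranges. 16-bit TIFF inputs are promoted to float before
averaging.

## AFM analysis

Flattening order mirrors the standard correction chain: plane → line →
second-order polynomial → zero-minimum; the order is configurable and
recorded in the output metadata. Line flattening subtracts each row's
median (robust to fibril crests; mean available). Roughness is the
population (divisor N) second central moment within an image; across
images the summary uses the sample sd (divisor n − 1). Profiles are
sampled by bilinear interpolation at half-pixel spacing along a polyline
(pixel centers at integer multiples of the pixel size). Crest detection
uses prominence ≥ 10% of the profile's peak-to-peak range and minimum
separation 30 nm (below any plausible D-period, above the noise scale);
both are parameters. D-unit lengths are successive crest distances; the
multi-profile mean pools all unit lengths. On grid-sampled topographies
individual crest positions quantize to the pixel grid, so single unit
lengths carry ±1 px error while the pooled mean is much tighter.

## Problem sizes

The acceptance script and the end-to-end tests use 4 image pairs at
2048 × 2048 px with 10 ROIs each, 500 spectra (5 classes × 100) for the
classification experiments, and single 512 × 512 topographies per
roughness/D-period condition — the acquisition-scale sizes above. The demo
pipeline configuration (`RunConfig` defaults) uses smaller images and
topographies, chosen to make an interactive `run-all` complete in seconds;
every analysis parameter (ROI 100 px, n = 10 ROIs, K = 5, crop 800–1750,
anchor 1451) keeps its protocol value there.

## Known limitations

* The Raman class signal is one-dimensional by construction; classifiers
  richer than PLS-LDA cannot be meaningfully compared on these data.
* The image generator has no optics model; ratio results validate the ROI
  estimator and calibration algebra, not radiometry.
* The topography roughness model is white noise, so roughness and
  D-banding are measured on separate synthetic scans.
* No despiking, smoothing or wavenumber calibration is provided; inputs
  are assumed already calibrated.
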