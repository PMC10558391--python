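# glycoscope

Multimodal quantification of collagen glycation for tissue-engineering and
biophotonics workflows: two-channel multiphoton (TPEF/SHG) intensity ratios,
EMSC-preprocessed Raman spectral classification by PLS-LDA, and AFM
topography roughness / collagen D-period measurement — together with
synthetic-data generators that emulate untreated and ribose-glycated
pericardium so the whole pipeline is testable end to end without any
instrument data.

## The problem

Nonenzymatic glycation of collagen by reducing sugars produces advanced
glycation end products (AGEs) such as fluorescent pentosidine crosslinks.
Three label-free readouts track this process:

* **TPEF/SHG imaging.** Fibrillar collagen dominates the second-harmonic
  (SHG) channel; elastin and AGE-fluorescent collagen appear in the
  two-photon fluorescence (TPEF) channel. Glycation transfers collagen
  signal from SHG into TPEF. With ROI-averaged channel means
  `I_TPEF` and `I_SHG` (ten random 100 × 100-px regions per image),

  ```
  TPEF ratio = I_TPEF / (I_SHG + I_TPEF)        SHG ratio = 1 − TPEF ratio
  ```

  Balanced channels give a ratio near 0.5; strong glycation pushes it
  toward ~0.63.

* **Raman chemometrics.** Fingerprint spectra (800–1750 cm⁻¹) are
  baseline-corrected by extended multiplicative signal correction
  (`s = b·r + B a + e`, correction `(s − B a)/b` against an untreated
  reference `r` with five linear background components `B`), normalized to
  the CH₂/CH₃ band at 1451 cm⁻¹, and classified by partial least squares +
  linear discriminant analysis (PLS-LDA, written from scratch via NIPALS
  and the generalized symmetric eigenproblem) with stratified 5-fold
  cross-validation. Linear-discriminant loadings back-projected onto the
  wavenumber axis show which bands drive the separation (e.g. a broad
  putative crosslink band near 1372 cm⁻¹).

* **AFM topography.** Height maps are flattened (plane → per-line median →
  second-order polynomial → zero minimum), RMS roughness is the square
  root of the second central moment of heights, and the collagen D-period
  is the distance between maximum heights of adjoining crests in line
  profiles drawn along fibrils (≈63–67 nm).

## Worked example

```python
import numpy as np
from glycoscope import synthetic as syn, spectra as sp, chemometrics as chem
from glycoscope import multiphoton as mp, afm

# Raman: 5 classes (0/5/50/100/200 mM ribose, 30 d), preprocess, classify
cfg = syn.RamanGenConfig(seed=7)
ds = syn.generate_raman_dataset(cfg, syn.default_presets(day=30), 100)
pre, _ = sp.preprocess_dataset(ds, syn.untreated_reference(cfg))
report = chem.kfold_cv(pre, K=5, n_components=10, seed=0)
print(f"5-fold CV accuracy (30 d): {report.accuracy:.3f}")
print("per-class sensitivity:", np.round(report.sensitivity, 2))

# TPEF/SHG: calibrated untreated pair vs strongly glycated pair
icfg = syn.calibrate_channels(syn.ImageGenConfig(seed=1, noise_sd=5.0))
for conc in (0, 200):
    img = syn.generate_image_pair(icfg, syn.glycation_preset(conc, 30))
    res = mp.compute_ratios(img, mp.sample_rois(img, n=10, size=100, seed=0))
    print(f"{conc:>3} mM / 30 d: TPEF ratio {res.tpef_ratio:.3f}")

# AFM: roughness scan and D-banded scan
tcfg = syn.TopoGenConfig(background_rms_nm=11.64, band_amp_nm=0.0, seed=7)
flat = afm.flatten_chain(syn.generate_topography(tcfg))
print(f"RMS roughness: {afm.rms_roughness(flat):.2f} nm")
bcfg = syn.TopoGenConfig(seed=11)  # 63.8 nm banding, 0.3 nm noise
bflat = afm.flatten_chain(syn.generate_topography(bcfg))
results = [afm.d_periods(afm.extract_profile(bflat, line))
           for line in syn.along_fiber_lines(bflat, n=6)]
print(f"mean D-period: {afm.mean_d_period(results):.1f} nm")
```

prints

```
5-fold CV accuracy (30 d): 0.958
per-class sensitivity: [0.96 0.97 0.95 0.93 0.98]
  0 mM / 30 d: TPEF ratio 0.513
200 mM / 30 d: TPEF ratio 0.636
RMS roughness: 11.62 nm
mean D-period: 62.9 nm
```

The CV accuracy says how well the five ribose concentrations are
distinguished by their Raman fingerprints after 30 days of incubation; the
TPEF ratio rises from ~0.5 (balanced untreated channels) to ~0.63 as
collagen signal moves into the fluorescence channel; the AFM numbers
recover the configured surface roughness and fibril banding period.

A `glycoscope` CLI exposes the same steps (`generate`, `preprocess`,
`classify`, `ratios`, `afm`, `run-all`, `validate`); `glycoscope run-all
--seed 0 --out demo/` executes the whole pipeline and writes a combined
JSON report plus per-stage CSV/TIFF artifacts.

## Layout

```
src/glycoscope/
  synthetic.py     generators: Raman bands + glycation presets, fiber
                   image pairs, D-banded topographies
  spectra.py       Spectrum/SpectralDataset, crop, EMSC, normalization
  chemometrics.py  NIPALS PLS2, LDA, stratified K-fold CV, LD loadings
  multiphoton.py   ROI sampling, TPEF/SHG ratios, ratio series
  afm.py           flattening, RMS roughness, line profiles, D-periods
  pipeline.py/cli.py  configuration, end-to-end runs, command line
docs/methods.md    model assumptions, parameter choices, limitations
```
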