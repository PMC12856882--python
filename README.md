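# nanodesi4d

Processing toolkit for **discrete-mode nano-DESI native mass spectrometry
imaging** — the acquisition mode in which a liquid-junction sampling probe
parks on each tissue location for a dwell period instead of rastering over
it. While the probe dwells, analytes dissolve into the solvent at rates set
by their solubility, so every pixel records a *time series* of native mass
spectra in which soluble, membrane-associated and transmembrane proteins
elute in a chromatography-like fashion. This package turns those raw scan
streams into a 4D image store and exploits the elution-time dimension for
classification, imaging and MS² demultiplexing.

It is written for mass-spectrometry imaging practitioners and method
developers who want to process discrete-mode runs — or prototype against
realistic synthetic ones — without instrument data.

## What it does

- **Core conventions** — 0-based scan indices and half-open elution-time
  windows: scans *a…b* at scan period Δt map to `[a·Δt, (b+1)·Δt)`. At
  Δt = 2.6 s, scans 2–4 span 5.2–13.0 s and scans 19–21 span 49.4–57.2 s.
- **Forward simulator** — a tissue phantom (e.g. gray/white matter) sampled
  in discrete or continuous mode. Species carry charge-state envelopes at
  `m/z = (M + z·m_p)/z`, Orbitrap-like peak widths
  (FWHM = m/z / R_eff, R_eff = R_ref·√(200/(m/z))), and class-specific
  dissolution kinetics:
  - soluble: `exp(-t/τ_fast)`
  - membrane-associated: `(t/τ_rise)·exp(-t/τ_rise)` (unit peak at τ_rise)
  - transmembrane: `(1-exp(-t/τ_rise))·exp(-t/τ_slow)` (unit peak)
  Every run also returns a noiseless ground-truth table.
- **IO** — mzML scan streams (reader and writer; the writer's output is
  bit-identical when read back by Bioconductor's mzR), a JSON fallback
  dialect, and a lossless 4D (x, y, elution-time, m/z) store as
  processed-mode imzML with the scan slot in the z coordinate and a JSON
  sidecar for the time axis and schedule.
- **Pixelation** — tissue-contact detection, discrete-mode spot sampling
  (scan → pixel assignment with full audit), continuous-mode time binning,
  and acquisition planning (pixels, raster time, dead time).
- **Elution profiles** — multi-charge-state XICs (absolute or ppm
  tolerance, optional flank background correction), pixel-averaged
  mean ± SD profiles, profile features (peak time, early-signal fraction,
  flatness), a three-way solubility classifier, charge-series neutral-mass
  estimation, and lipid-PTM mass-shift matching
  (geranylgeranylation +272.2504 Da, farnesylation +204.1878 Da,
  myristoylation +210.1984 Da, methylation +14.0157 Da, monoisotopic).
- **Imaging & segmentation** — elution-time-filtered ion images, 2-m/z
  binning, TIC normalization, PCA (5 components) and seeded k-means (k = 2)
  tissue segmentation with per-class mean spectra and profiles.
- **MS² chimera simplification** — window-averaged product-ion spectra and
  single-linkage grouping of product ions by elution-profile correlation,
  separating co-isolated precursors of different solubility.

## Worked example

Simulate the default two-region brain phantom (420 pixels, 90 s dwell,
2.6 s scan period, peak SNR 20), assemble it into a 4D image, and run the
profile, classification and segmentation stages:

```python
import numpy as np
import nanodesi4d as nd
from nanodesi4d.simulate import Phantom, default_species_panel, simulate_discrete_run
from nanodesi4d.pixelation import spot_sample
from nanodesi4d.profiles import (average_profiles, classify_solubility,
                                 neutral_mass_from_series, profile_features)
from nanodesi4d.segmentation import bin_spectra, segment

sched = nd.AcquisitionSchedule.discrete_default()
phantom = Phantom.two_region_default()
panel = default_species_panel()
scans, truth = simulate_discrete_run(phantom, panel, sched, seed=7, snr=20)
image = spot_sample(scans, sched, phantom.pixel_order())
print(f"{image.n_pixels} pixels x {image.time_axis.size} scans per pixel")

for sp in panel:
    target = nd.XICTarget(sp.name, sp.mz_centers(), sp.charges, (60.0, "ppm"))
    feats = profile_features(average_profiles(image, target, background="flank"))
    cls = classify_solubility(feats)
    print(f"{sp.name:10s} t_peak={feats.t_peak_s:5.1f} s  "
          f"frac<30s={feats.frac_first_30s:.2f}  "
          f"flatness={max(feats.flatness, 0):.2f}  -> {cls}")

matrix, _ = bin_spectra(image, bin_width_mz=2.0, mz_range=(2400.0, 4000.0))
result = segment(matrix, n_components=5, k=2, seed=0)
print("segmentation class sizes:", result.class_sizes)
mass, sd = neutral_mass_from_series([(2788.9, 11), (3067.9, 10),
                                     (3408.5, 9), (3834.6, 8)])
print(f"VDAC1 neutral mass: {mass:.1f} +/- {sd:.1f} Da")
```

Output:

```
420 pixels x 34 scans per pixel
Arf3_GDP   t_peak=  0.0 s  frac<30s=0.96  flatness=0.00  -> soluble
CAH2_Zn    t_peak=  0.0 s  frac<30s=0.95  flatness=0.00  -> soluble
Rab3a_GDP  t_peak= 28.6 s  frac<30s=0.35  flatness=0.15  -> membrane_associated
MAL        t_peak= 15.6 s  frac<30s=0.37  flatness=0.51  -> transmembrane
VDAC1      t_peak= 10.4 s  frac<30s=0.37  flatness=0.53  -> transmembrane
segmentation class sizes: (369, 51)
VDAC1 neutral mass: 30668.0 +/- 1.0 Da
```

Reading the numbers: the two soluble complexes dump >94% of their signal
in the first 30 s of the dwell; the lipid-anchored complex peaks near its
30 s rise constant; the two transmembrane proteins give near-flat profiles
(flatness ≥ 0.5). Segmentation of the 2-m/z-binned, TIC-normalized spectra
recovers the 369-pixel gray-matter and 51-pixel white-matter classes
exactly, and the four-member charge-state series deconvolves to a neutral
mass of 30668 Da with 1 Da scatter.

The same pipeline is scriptable from the shell:

```bash
nanodesi4d simulate --seed 7 --out run.mzML
nanodesi4d assemble --mode discrete --schedule sched.json --cols 30 --rows 14 run.mzML image.imzML
nanodesi4d segment --pcs 5 --k 2 --seed 0 image.imzML labels.csv
nanodesi4d massmatch --delta 286
```

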