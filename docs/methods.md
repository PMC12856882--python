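# Methods

This note documents the models, conventions and numerical choices behind
`nanodesi4d`, in the order data flows through the package.

## Scan-index and time conventions

Scan indices are 0-based everywhere. An inclusive scan window `[a, b]`
at scan period Δt maps to the half-open time window `[a·Δt, (b+1)·Δt)`,
so adjacent windows tile the time axis without gap or overlap. This is
the only convention under which, at Δt = 2.6 s, scans 2–4 span
5.2–13.0 s *and* scans 19–21 span 49.4–57.2 s simultaneously; vendor
software is ambiguous about scan-index origin, so the convention is fixed
here by those two mappings rather than assumed. Δt is always a field of
the acquisition schedule, never hard-coded; 2.6 s is the discrete-mode
default.

`MassSpectrum.time_s` is seconds relative to a context-dependent
reference: acquisition start in a raw stream, pixel contact after
pixelation. After contact alignment, pre-contact scans carry negative
times; they are never silently dropped — pixelation flags and counts them
so scan audits reconcile exactly.

## The forward simulator

The simulator exists so that every downstream stage has a ground truth.
It emulates a selected-ion-monitoring acquisition over m/z 2400–4000 of a
two-region tissue phantom; it does **not** model electrospray or
ion-optics physics, isotopic fine structure (unresolved at native-MS
resolving powers for ~30 kDa species), detergent chemistry, or
instrument-control behaviour.

**Peaks.** Each species of average neutral mass M and charge z
contributes a Gaussian at (M + z·m_p)/z (m_p = 1.00728 Da), height
proportional to abundance × charge weight, and FWHM = (m/z)/R_eff with
R_eff = R_ref·√(200/(m/z)); R_ref = 7500 at m/z 200, matching the
low-resolution Orbitrap setting typical of native protein work.
Monoisotopic masses are used only in the PTM arithmetic, where the 1-Da
scale of the question demands them; intact proteins use average masses.

**Dissolution kinetics.** The measured elution profiles in real tissue
are empirical; the simulator uses parametric stand-ins chosen per
solubility class, each mapping time-since-contact t to a relative signal
in [0, 1]:

| class | form | default parameters |
|---|---|---|
| soluble | exp(−t/τ_fast) | τ_fast = 10 s |
| membrane-associated | (t/τ_rise)·e^(1−t/τ_rise) | τ_rise = 30 s |
| transmembrane | (1−e^(−t/τ_rise))·e^(−t/τ_slow), unit peak | τ_rise = 2.5 s, τ_slow = 300 s |

The soluble constant makes the species effectively gone after ~30 s
(e^−3 ≈ 0.05); the membrane-associated curve peaks exactly at τ_rise; the
transmembrane curve has its closed-form peak at τ_rise·ln((τ_rise+τ_slow)/τ_rise).
The transmembrane defaults deliberately describe the *near-flat* archetype
(wet-out within a few seconds, dissolution far slower than the 90 s
dwell): with a slow rise constant the rise-decay curve is *less* flat
than the membrane-associated gamma curve over a 90 s window, and the
flatness-based classifier below could not separate the classes. Rate
constants are calibrated only to qualitative profile shapes; no
quantitative dissolution rates are available for real tissue.

**Modes.** Discrete mode emits `floor(dwell/Δt)` tissue scans per pixel
at offsets k·Δt from pixel start (kinetics evaluated at scan mid-times),
followed by baseline-only "overhead" scans at offsets dwell + k·Δt while
the probe repositions; pixel p starts at p·(dwell + overhead). Continuous
mode exposes each location for a single effective transit time
(junction diameter / raster speed, 20 s at 100 μm and 5 μm/s), so every
species is sampled at one point of its kinetics curve — which is why
slowly dissolving proteins image poorly in continuous mode. Noise is
additive Gaussian per grid point, clipped at zero (intensities are
non-negative); `snr=x` sets the noise SD to (peak noiseless
intensity)/x. All randomness flows through one seeded generator;
identical seeds give bit-identical streams.

**Default panel and phantom.** Five species (two soluble, one
lipid-anchored, two transmembrane archetypes) with neutral masses taken
from printed charge-state series of the corresponding real proteins, so
all envelopes fall inside the SIM window. The default phantom is a
30 × 14 grid whose 51-pixel band plays white matter against a 369-pixel
gray-matter background — the class sizes the segmentation stage should
recover. The m/z grid step defaults to 0.25 Th so that even the
narrowest XIC tolerance in use (±0.15 Th) always covers at least one
grid point; a 1 Th grid is adequate (and 4× cheaper) when spectra are
only ever consumed through 2-m/z binning.

## 4D storage

Standard imzML has (x, y, z) coordinates and no time dimension. The
store writes one imzML spectrum per scan at 1-based (col+1, row+1,
slot+1), with the elution-time axis, acquisition schedule, per-pixel scan
times and contact indices in a JSON sidecar; the encoding is flagged
(`z-slot-elution-time-v1`) so readers can reject foreign dialects.
Processed-mode imzML (per-spectrum m/z arrays) is used because scans are
not resampled to a common grid; arrays are written as float64 and round
trips are bit-exact. The mzML writer emits plain (non-indexed) mzML 1.1
with uncompressed base64 float64 arrays and second-valued scan start
times; tests verify it reads back bit-identically both through the
package's own reader and through Bioconductor's mzR.

## Pixelation

Contact detection declares tissue contact at the first scan whose TIC
(optionally windowed in m/z) exceeds `threshold_factor` (default 5)
times the median TIC of all earlier scans; it therefore presumes at least
one pre-contact scan. Discrete spot sampling assigns scans to pixels by
*scan start time* (deterministic and order-preserving for scans
straddling boundaries); continuous time binning assigns by stage position
at the *scan midpoint*. Scans in overhead gaps, before contact, or past
the schedule are counted in an audit table rather than dropped silently,
so assigned + flagged always equals the stream length. The default
per-pixel overhead is 12.9 s, the value implied by ~1.4 h of dead time
spread over a 390-pixel image.

## Elution profiles and classification

XICs sum intensity within ± tolerance of each charge-state center
(absolute Th, or ppm with half-width = center·tol·10⁻⁶). Optional
background correction subtracts, per window and scan, the mean point
intensity of two flanking regions placed 5–7 Th from the center — beyond
the peak envelope, which at native-MS resolving powers (FWHM ≈ 1.5 Th at
m/z 3000) is much wider than the XIC window itself. Corrected sums may go
slightly negative on noise and are left so deliberately: the residuals
are zero-mean and cancel when averaged, whereas clamping each scan would
re-impose the noise-floor offset the correction removes. Only the final
pixel-averaged profile is clamped at zero. Uncorrected extraction is the
default; correction is recommended (and used by the package's own
benchmarks) whenever profiles feed the classifier, because an uncorrected
noise floor inflates the late-time tail of every profile.

Pixel-averaged profiles normalize each pixel's XIC to unit maximum
*before* averaging, making the ±1 SD band scale-free; raw-intensity
averaging is available via `normalize=False`. Pixels with unequal scan
counts align on the shortest common count.

Profile features: `t_peak_s` (argmax), `frac_first_30s` (share of
integrated signal at t < 30 s, half-open like every window here; a
uniform 90 s profile gives exactly 1/3), `flatness` (min/max of the
3-slot moving mean, nearest-edge padding), and `t_half_s` (first time the
cumulative signal reaches half its total). The classifier is a two-rule
cascade: `frac_first_30s ≥ 0.8` → soluble, else `flatness ≥ 0.5` →
transmembrane, else membrane-associated. The 0.8/0.5 thresholds are
package defaults, exposed as a parameter — they are not measured
constants, and the classes describe *observed elution*, not annotation: a
cytosolic protein that must wait for membrane dissolution (the
myelin-trapped deacetylase case) correctly classifies with the membrane
species.

Neutral mass from a charge series is the mean of z·(m/z − 1.00728) over
the series (SD > 5 Da flags an inconsistent series but still returns).
PTM matching enumerates all multisets of catalog entries up to
`max_copies` of each and returns those within tolerance of the observed
shift, sorted by |error|; with the default catalog this reproduces the
286 Da (geranylgeranylation + methylation) and ~558 Da (2× + methylation)
assignments within 1 Da, and shows farnesylation inconsistent with 286.

## Imaging and segmentation

Ion images integrate a target's XIC per pixel over a half-open
elution-time window; additivity over any partition of the time axis is
exact. The segmentation pipeline is deliberately standard MSI practice:
half-open 2-m/z bins over the SIM range (800 bins; total intensity in
range conserved exactly), per-pixel TIC normalization (the scale-free
choice when pixel-to-pixel signal varies), mean-centering via PCA
(centering only — no variance scaling by default), 5 components, and
k-means with k = 2, `n_init=10` and a fixed seed. Labels are
canonicalized so label 0 is the largest class, making runs comparable
across seeds; requesting more components than the matrix rank reduces
with a warning.

## MS² chimera handling

Precursor isolation is modelled only as a recorded (center, half-width)
window; the simulator emits product-ion envelopes directly, each product
inheriting its precursor's dissolution kinetics. Window-averaged spectra
require a shared m/z grid (true of SIM/simulator data) and recombine
exactly over a partition when weighted by scan counts. Product-ion
profiles average over discrete sampling locations (aligned on the
shortest), are background-corrected by default, and unit-normalized.
Grouping is single-linkage on Pearson correlation with threshold 0.8,
order-independent (series sorted by label), with zero-variance profiles
set aside as singletons. The correlation grouping automates what manual
time-window inspection does by hand and is flagged as such: it is an
extension of, not a substitute for, window filtering.

## Problem sizes and known limitations

The test and benchmark suites run desk-scale versions of the workflow:
profile recovery on 100 pixels, classification on 25-pixel repeats over
20 noise seeds, segmentation on the full 420-pixel phantom (coarse 1 Th
grid), MS² grouping on 5 locations × 20 seeds. Passing them shows the
pipeline recovers what the simulator generates under its stated noise
model; it does not show robustness to features real tissue adds —
chemical background (detergent clusters), pixel-to-pixel kinetic
variability, m/z drift, overlapping isobaric species, or profile shapes
outside the three parametric families. The transmembrane/membrane
separation in particular relies on the flatness contrast and would blur
for species with intermediate rise constants; the classifier reports
whichever side of the cascade the features fall on, with no confidence
measure. Continuous-mode leading-edge oversampling deconvolution and any
proteoform database search are out of scope.
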