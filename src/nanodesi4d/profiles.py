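"""Elution-profile extraction, solubility classification, and mass tools.

An elution profile is the intensity-vs-dissolution-time curve of one
species during a pixel's dwell, summed over its charge states.  Soluble
proteins dump most of their signal in the first ~30 s; membrane-associated
proteins peak later; transmembrane proteins give near-flat profiles.  The
profile-feature cascade here turns those contrasts into a three-way
classifier.  Neutral-mass estimation from a charge-state series and
lipid-PTM mass-shift matching round out the module.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import MassSpectrum, PROTON_MASS_DA, XICTarget
from .io import Image4D

# Monoisotopic element masses (Da) for PTM arithmetic.
_MONO = {"C": 12.0, "H": 1.00782503207, "O": 15.9949146196}


@dataclass
class ElutionProfile:
    """Mean +/- SD intensity vs elution time for one target."""

    target: XICTarget
    time_s: np.ndarray
    mean_intensity: np.ndarray
    sd: np.ndarray
    n_pixels: int
    normalized: bool

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.time_s.size == self.mean_intensity.size == self.sd.size):
            raise ValueError("profile arrays must have equal length")
        if np.any(self.sd < -1e-12):
            raise ValueError("sd must be non-negative")


@dataclass
class ProfileFeatures:
    """Scalar descriptors of an elution profile.

    ``frac_first_30s``: share of integrated signal at t < 30 s.
    ``flatness``: min/max of the 3-slot moving mean — near 1 for a flat
    (dissolution-limited, transmembrane-like) profile.
    ``t_half_s``: time at which the cumulative signal first reaches half
    its total.
    """

    t_peak_s: float
    frac_first_30s: float
    flatness: float
    t_half_s: float


def extract_xic(spectra: Sequence[MassSpectrum],
                target: XICTarget,
                background: str = "none") -> tuple[np.ndarray, np.ndarray]:
    """Per-scan summed intensity within the target's m/z windows.

    Each (mz_center, charge) window contributes its intensity sum; ppm
    tolerances use half-width = center * tol * 1e-6.  Windows entirely
    outside every scan's m/z range give zeros with a warning, not an error.

    ``background="flank"`` subtracts, per window and scan, a local
    background: the mean point intensity in two flanking regions placed
    5-7 Th either side of the center — beyond the peak envelope, which at
    native-MS resolving powers is much wider than the XIC window itself —
    times the number of in-window points.  Corrected sums may go slightly
    negative on noise; they are left so, because the residuals are
    zero-mean and cancel when profiles are averaged (clamping here would
    re-impose the very noise-floor offset the correction removes).  The
    default is uncorrected summation.
    """
    flank_offset, flank_width = 5.0, 2.0
    if background not in ("none", "flank"):
        raise ValueError("background must be 'none' or 'flank'")
    times = np.array([s.time_s for s in spectra], dtype=float)
    xic = np.zeros(len(spectra))
    any_overlap = False
    for i, s in enumerate(spectra):
        total = 0.0
        for center in target.mz_centers:
            h = target.half_width(center)
            lo = np.searchsorted(s.mz, center - h, side="left")
            hi = np.searchsorted(s.mz, center + h, side="right")
            if hi <= lo:
                continue
            any_overlap = True
            window_sum = float(s.intensity[lo:hi].sum())
            if background == "flank":
                l0 = np.searchsorted(s.mz, center - flank_offset - flank_width)
                l1 = np.searchsorted(s.mz, center - flank_offset)
                r0 = np.searchsorted(s.mz, center + flank_offset)
                r1 = np.searchsorted(s.mz, center + flank_offset + flank_width)
                flanks = np.concatenate([s.intensity[l0:l1], s.intensity[r0:r1]])
                if flanks.size:
                    window_sum -= float(flanks.mean()) * (hi - lo)
            total += window_sum
        xic[i] = total
    if spectra and not any_overlap:
        warnings.warn(f"target {target.label!r} falls outside the scanned "
                      "m/z range; XIC is all zeros")
    return times, xic


def average_profiles(image: Image4D, target: XICTarget,
                     normalize: bool = True,
                     background: str = "none") -> ElutionProfile:
    """Mean +/- SD elution profile of a target across an image's pixels.

    Per pixel the multi-charge-state XIC is computed; with ``normalize``
    each pixel's XIC is scaled to unit maximum first, so the SD band is
    scale-free.  Pixels with differing scan counts are aligned on the
    shortest common slot count (with a warning).  ``background`` is
    passed through to :func:`extract_xic`; flank correction is the
    recommended setting when profiles feed the solubility classifier,
    since an uncorrected noise floor inflates the late-time tail.
    """
    pixel_list = image.pixel_list()
    if not pixel_list:
        raise ValueError("image has no pixels")
    counts = {px.n_scans for px in pixel_list}
    m = min(counts)
    if m < 2:
        raise ValueError("need at least 2 scans per pixel")
    if len(counts) > 1:
        warnings.warn(f"pixels have differing scan counts {sorted(counts)}; "
                      f"aligning on {m} slots")
    rows = np.empty((len(pixel_list), m))
    for i, px in enumerate(pixel_list):
        _, xic = extract_xic(px.spectra[:m], target, background=background)
        if normalize:
            peak = xic.max()
            if peak > 0:
                xic = xic / peak
        rows[i] = xic
    # Background-corrected XICs are zero-mean on noise, so slot means can
    # dip fractionally below zero; clamp the aggregate, not the per-pixel
    # traces, to keep the mean unbiased.
    return ElutionProfile(target=target, time_s=image.time_axis[:m],
                          mean_intensity=np.maximum(rows.mean(axis=0), 0.0),
                          sd=rows.std(axis=0, ddof=0),
                          n_pixels=len(pixel_list), normalized=normalize)


def profile_features(profile: ElutionProfile) -> ProfileFeatures:
    """Deterministic features of a profile; all-zero profiles are undefined."""
    y = profile.mean_intensity
    t = profile.time_s
    total = y.sum()
    if total <= 0:
        raise ValueError("features are undefined for an all-zero profile")
    smoothed = uniform_filter1d(y, size=3, mode="nearest")
    return ProfileFeatures(
        t_peak_s=float(t[int(np.argmax(y))]),
        frac_first_30s=float(y[t < 30.0].sum() / total),
        flatness=float(smoothed.min() / smoothed.max()),
        t_half_s=float(t[int(np.searchsorted(np.cumsum(y), total / 2.0))]),
    )


def classify_solubility(features: ProfileFeatures,
                        thresholds: tuple[float, float] = (0.8, 0.5)) -> str:
    """Rule cascade mapping profile features to a solubility class.

    ``frac_first_30s >= thresholds[0]`` -> soluble; otherwise
    ``flatness >= thresholds[1]`` -> transmembrane; else
    membrane-associated.  The class reflects the observed elution, not any
    annotation: a soluble protein trapped in myelin classifies with the
    membrane species, as its extraction kinetics dictate.
    """
    frac_thresh, flat_thresh = thresholds
    if features.frac_first_30s >= frac_thresh:
        return "soluble"
    if features.flatness >= flat_thresh:
        return "transmembrane"
    return "membrane_associated"


def neutral_mass_from_series(peaks: Sequence[tuple[float, int]]
                             ) -> tuple[float, float]:
    """Neutral mass (mean, SD in Da) from a charge-state series.

    Each (m/z, z) peak gives mass = z * (m/z - m_proton).  A series whose
    per-charge masses scatter with SD > 5 Da is flagged with a warning but
    still returned.
    """
    if not peaks:
        raise ValueError("need at least one (mz, charge) peak")
    masses = np.array([z * (mz - PROTON_MASS_DA) for mz, z in peaks])
    if np.any(np.array([z for _, z in peaks]) <= 0):
        raise ValueError("charges must be positive")
    mean = float(masses.mean())
    sd = float(masses.std(ddof=1)) if masses.size > 1 else 0.0
    if sd > 5.0:
        warnings.warn(f"inconsistent charge-state series: mass SD {sd:.1f} Da")
    return mean, sd


@dataclass
class PTMCatalog:
    """Monoisotopic mass shifts (Da) of candidate modifications."""

    entries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.entries.values()):
            raise ValueError("mass shifts must be positive")

    def shift(self, name: str) -> float:
        return self.entries[name]

    def combined_shift(self, names: Sequence[str]) -> float:
        """Total shift of a multiset of modifications (names may repeat)."""
        return float(sum(self.entries[n] for n in names))


def default_ptm_catalog() -> PTMCatalog:
    """Lipid anchors plus C-terminal methylation, monoisotopic."""
    C, H, O = _MONO["C"], _MONO["H"], _MONO["O"]
    return PTMCatalog({
        "S-geranylgeranylation": 20 * C + 32 * H,   # C20H32, +272.2504
        "S-farnesylation": 15 * C + 24 * H,         # C15H24, +204.1878
        "N-myristoylation": 14 * C + 26 * H + O,    # C14H26O, +210.1984
        "C-terminal methylation": C + 2 * H,        # CH2, +14.0157
    })


def match_mass_shift(delta_da: float, catalog: Optional[PTMCatalog] = None,
                     max_copies: int = 3, tol_da: float = 1.0
                     ) -> list[tuple[dict, float, float]]:
    """PTM multisets whose summed shift matches an observed mass difference.

    Exhaustively enumerates combinations with up to ``max_copies`` of each
    catalog entry; returns ``(counts, total_shift, error)`` tuples sorted
    by absolute error (ties by name).  An empty list is a valid result.
    """
    if delta_da <= 0:
        raise ValueError("delta_da must be positive")
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    if catalog is None:
        catalog = default_ptm_catalog()
    names = sorted(catalog.entries)
    results = []
    for counts in itertools.product(range(max_copies + 1), repeat=len(names)):
        if not any(counts):
            continue
        total = sum(n * catalog.entries[name] for name, n in zip(names, counts))
        err = total - delta_da
        if abs(err) <= tol_da:
            combo = {name: n for name, n in zip(names, counts) if n}
            results.append((combo, float(total), float(err)))
    results.sort(key=lambda item: (abs(item[2]), tuple(sorted(item[0]))))
    return results
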