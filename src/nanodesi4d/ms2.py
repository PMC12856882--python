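"""Simplify chimeric MS2 spectra using elution-time structure.

When two co-isolated precursors differ in solubility, their product ions
elute over different periods of a discrete-mode dwell: soluble-complex
fragments dominate the first ~0.5 min while membrane-complex fragments
persist.  Averaging scans over a late time window therefore yields a
clean single-precursor product spectrum, and correlating product-ion
elution profiles groups fragments by their precursor automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import MassSpectrum, NanoDesiError, XICTarget
from .profiles import extract_xic


class EmptyWindowError(NanoDesiError):
    """No scans fall inside the requested time window."""


@dataclass
class ProductIonSeries:
    """A product ion's elution profile, averaged over sampling locations."""

    label: str
    charge_states: Sequence[int]
    xic: tuple[np.ndarray, np.ndarray]  # (time_s, unit-normalized intensity)
    source_window: Optional[tuple[float, float]]
    sd: Optional[np.ndarray] = None
    n_locations: int = 1


def window_mean_spectrum(ms2_scans: Sequence[MassSpectrum],
                         t_window_s: tuple[float, float]) -> MassSpectrum:
    """Mean spectrum of the scans inside a half-open time window.

    Scans must share an m/z grid (true for simulator output and for SIM
    acquisitions resampled to a common axis).
    """
    start, end = t_window_s
    if start >= end:
        raise ValueError("window must satisfy start < end")
    members = [s for s in ms2_scans if start <= s.time_s < end]
    if not members:
        raise EmptyWindowError(f"no scans in window [{start}, {end})")
    mz = members[0].mz
    for s in members[1:]:
        if not np.array_equal(s.mz, mz):
            raise ValueError("scans must share a common m/z grid")
    mean = np.mean([s.intensity for s in members], axis=0)
    return MassSpectrum(members[0].scan_index, start, mz, mean,
                        ms_level=members[0].ms_level,
                        precursor_window=members[0].precursor_window)


def product_ion_profiles(ms2_locations: Sequence[Sequence[MassSpectrum]],
                         targets: Sequence[XICTarget],
                         background: str = "flank"
                         ) -> list[ProductIonSeries]:
    """Per-target elution profiles averaged over discrete sampling locations.

    Locations are aligned on the shortest common scan count; empty
    locations are skipped with a warning and the count recorded.  Each
    mean profile is unit-max normalized.  XICs are background-corrected
    by default (see :func:`nanodesi4d.profiles.extract_xic`): the profiles
    exist to be compared by shape, and an uncorrected noise floor both
    pads the integral and attenuates inter-profile correlations.
    """
    locations = [list(loc) for loc in ms2_locations if len(loc) > 0]
    if len(locations) < len(ms2_locations):
        warnings.warn(f"{len(ms2_locations) - len(locations)} empty "
                      "location(s) skipped")
    if not locations:
        raise ValueError("need at least one non-empty location")
    m = min(len(loc) for loc in locations)
    series = []
    for target in targets:
        rows = np.empty((len(locations), m))
        times = None
        for i, loc in enumerate(locations):
            t, xic = extract_xic(loc[:m], target, background=background)
            rows[i] = xic
            if times is None:
                times = t
        mean = np.maximum(rows.mean(axis=0), 0.0)  # clamp after averaging
        peak = mean.max()
        if peak > 0:
            sd = rows.std(axis=0, ddof=0) / peak
            mean = mean / peak
        else:
            sd = rows.std(axis=0, ddof=0)
        precursor = locations[0][0].precursor_window
        series.append(ProductIonSeries(label=target.label,
                                       charge_states=list(target.charges),
                                       xic=(times, mean),
                                       source_window=precursor,
                                       sd=sd, n_locations=len(locations)))
    return series


def group_by_profile(series: Sequence[ProductIonSeries],
                     r_threshold: float = 0.8) -> list[list[str]]:
    """Single-linkage groups of product ions by profile correlation.

    Pairs with Pearson r >= ``r_threshold`` are linked; constant
    (zero-variance) profiles get their own group with a warning.  Groups
    and members are ordered lexicographically by label, so the result is
    independent of input order.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 series to group")
    ordered = sorted(series, key=lambda s: s.label)
    labels = [s.label for s in ordered]
    profiles = [np.asarray(s.xic[1], dtype=float) for s in ordered]

    constant = [i for i, p in enumerate(profiles) if np.std(p) == 0]
    if constant:
        warnings.warn(f"{len(constant)} constant profile(s) assigned to "
                      "singleton groups")
    parent = list(range(len(ordered)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ordered)):
        if i in constant:
            continue
        for j in range(i + 1, len(ordered)):
            if j in constant:
                continue
            r = float(np.corrcoef(profiles[i], profiles[j])[0, 1])
            if r >= r_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[str]] = {}
    for i, label in enumerate(labels):
        groups.setdefault(find(i), []).append(label)
    return [sorted(members) for _, members in sorted(groups.items())]
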