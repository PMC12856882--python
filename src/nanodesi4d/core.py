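"""Shared data types and the scan-index/elution-time convention.

Discrete-mode nano-DESI parks the liquid-junction probe on one tissue
location ("pixel") for a dwell period, recording a time series of native
mass spectra while analytes dissolve into the solvent.  Every other module
builds on the types here and on one convention: scan indices are 0-based
and a scan window ``[first, last]`` maps to the half-open time interval
``[first*dt, (last+1)*dt)``, where ``dt`` is the scan period.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Mass of a proton in Da, used for charge-state <-> neutral-mass arithmetic.
PROTON_MASS_DA = 1.00728


class NanoDesiError(Exception):
    """Base class for errors raised by this package."""


class FormatError(NanoDesiError):
    """A scan stream or on-disk store violates its format contract."""


class NoContactError(NanoDesiError):
    """No scan in the stream ever exceeded the tissue-contact threshold."""


class TruncationError(NanoDesiError):
    """The scan stream ended before the acquisition schedule was satisfied."""

    def __init__(self, message: str, unfilled: Sequence = ()):  # noqa: D401
        super().__init__(message)
        self.unfilled = list(unfilled)


@dataclass
class MassSpectrum:
    """One scan: a time stamp plus parallel m/z and intensity arrays.

    ``time_s`` is seconds relative to a reference that depends on context:
    acquisition start for a raw stream, pixel contact once pixelated.
    Negative times mark pre-contact scans after contact alignment.
    """

    scan_index: int
    time_s: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    precursor_window: Optional[tuple[float, float]] = None  # (center, half-width)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.scan_index < 0:
            raise ValueError("scan_index must be non-negative")
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if not math.isfinite(self.time_s):
            raise ValueError("time_s must be finite")
        if self.ms_level not in (1, 2):
            raise ValueError("ms_level must be 1 or 2")

    def tic(self, window_mz: Optional[tuple[float, float]] = None) -> float:
        """Total ion current, optionally restricted to an m/z window."""
        if window_mz is None:
            return float(self.intensity.sum())
        lo, hi = window_mz
        i0 = np.searchsorted(self.mz, lo, side="left")
        i1 = np.searchsorted(self.mz, hi, side="right")
        return float(self.intensity[i0:i1].sum())

    def shifted(self, dt_s: float) -> "MassSpectrum":
        """Copy with ``time_s`` shifted by ``dt_s`` (arrays shared)."""
        return replace(self, time_s=self.time_s + dt_s)


@dataclass
class PixelRecord:
    """A pixel's ordered time-resolved spectra — the 4D cube's atom."""

    col: int
    row: int
    center_um: tuple[float, float]
    spectra: list[MassSpectrum]
    contact_scan: int = 0

    def __post_init__(self) -> None:
        times = [s.time_s for s in self.spectra]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("pixel spectra must have strictly increasing time_s")
        levels = {s.ms_level for s in self.spectra}
        if len(levels) > 1:
            raise ValueError("all spectra in a pixel must share ms_level")

    @property
    def n_scans(self) -> int:
        return len(self.spectra)


@dataclass
class AcquisitionSchedule:
    """Geometry and timing of a nano-DESI acquisition.

    Discrete mode needs ``dwell_s`` (per-pixel residence); continuous mode
    needs ``raster_speed_um_s``.  ``per_pixel_overhead_s`` is the dead time
    for probe lift, repositioning and liquid-junction stabilisation between
    pixels (discrete) or lines (continuous).
    """

    mode: str  # "discrete" | "continuous"
    pitch_x_um: float
    pitch_y_um: float
    scan_period_s: float
    dwell_s: Optional[float] = None
    raster_speed_um_s: Optional[float] = None
    junction_diameter_um: float = 100.0
    per_pixel_overhead_s: float = 12.9

    def __post_init__(self) -> None:
        if self.mode not in ("discrete", "continuous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("pitch_x_um", "pitch_y_um", "scan_period_s",
                     "junction_diameter_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.per_pixel_overhead_s < 0:
            raise ValueError("per_pixel_overhead_s must be non-negative")
        if self.mode == "discrete":
            if self.dwell_s is None or self.dwell_s <= 0:
                raise ValueError("discrete mode requires positive dwell_s")
        else:
            if self.raster_speed_um_s is None or self.raster_speed_um_s <= 0:
                raise ValueError("continuous mode requires positive raster_speed_um_s")

    @classmethod
    def discrete_default(cls) -> "AcquisitionSchedule":
        """1.5 min dwell, 100x200 um pitch, 2.6 s scan period."""
        return cls(mode="discrete", pitch_x_um=100.0, pitch_y_um=200.0,
                   scan_period_s=2.6, dwell_s=90.0)

    @classmethod
    def continuous_default(cls) -> "AcquisitionSchedule":
        """5 um/s linescans, 94x200 um pixels, 2.6 s scan period."""
        return cls(mode="continuous", pitch_x_um=94.0, pitch_y_um=200.0,
                   scan_period_s=2.6, raster_speed_um_s=5.0,
                   per_pixel_overhead_s=0.0)

    def scans_per_dwell(self) -> int:
        if self.mode != "discrete":
            raise ValueError("scans_per_dwell is defined for discrete mode")
        return int(math.floor(self.dwell_s / self.scan_period_s))

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSchedule":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AcquisitionSchedule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class XICTarget:
    """A species to extract: one m/z center per charge state plus a tolerance.

    ``tolerance`` is ``(value, unit)`` with unit ``"mz"`` (absolute Thomson
    half-width) or ``"ppm"`` (half-width = center * value * 1e-6).
    """

    label: str
    mz_centers: Sequence[float]
    charges: Sequence[int]
    tolerance: tuple[float, str] = (0.15, "mz")

    def __post_init__(self) -> None:
        self.mz_centers = [float(m) for m in self.mz_centers]
        self.charges = [int(z) for z in self.charges]
        if len(self.mz_centers) != len(self.charges):
            raise ValueError("mz_centers and charges must be parallel")
        value, unit = self.tolerance
        if value <= 0:
            raise ValueError("tolerance value must be positive")
        if unit not in ("mz", "ppm"):
            raise ValueError("tolerance unit must be 'mz' or 'ppm'")

    def half_width(self, mz_center: float) -> float:
        value, unit = self.tolerance
        return value if unit == "mz" else mz_center * value * 1e-6

    def to_dict(self) -> dict:
        return {"label": self.label, "mz_centers": list(self.mz_centers),
                "charges": list(self.charges),
                "tolerance": [self.tolerance[0], self.tolerance[1]]}

    @classmethod
    def from_dict(cls, d: dict) -> "XICTarget":
        tol = d.get("tolerance", [0.15, "mz"])
        return cls(label=d["label"], mz_centers=d["mz_centers"],
                   charges=d["charges"], tolerance=(float(tol[0]), tol[1]))


def scan_window_to_time(first_scan: int, last_scan: int,
                        scan_period_s: float) -> tuple[float, float]:
    """Map a 0-based inclusive scan window to its half-open time window.

    ``[first, last]`` -> ``[first*dt, (last+1)*dt)``.  With dt = 2.6 s this
    sends scans 2-4 to (5.2, 13.0) and scans 19-21 to (49.4, 57.2).
    """
    if first_scan < 0:
        raise ValueError("first_scan must be non-negative")
    if first_scan > last_scan:
        raise ValueError("first_scan must not exceed last_scan")
    if scan_period_s <= 0:
        raise ValueError("scan_period_s must be positive")
    return (first_scan * scan_period_s, (last_scan + 1) * scan_period_s)


def window_width(n_scans: int, scan_period_s: float) -> float:
    """Duration of an n-scan elution window (3 scans at 2.6 s -> 7.8 s)."""
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if scan_period_s <= 0:
        raise ValueError("scan_period_s must be positive")
    return n_scans * scan_period_s
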