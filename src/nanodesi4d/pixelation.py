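"""Turn ordered scan streams into pixels; plan and audit acquisitions.

Discrete mode ("spot sampling"): pixel p occupies the half-open interval
[p*(dwell+overhead), p*(dwell+overhead)+dwell) and receives the scans whose
start time falls inside it, re-zeroed to the pixel start.  Continuous mode
("time binning"): linescan scans are binned by stage position at the scan
midpoint.  Every scan ends up assigned to exactly one pixel or explicitly
flagged (overhead / pre-contact), so counts always reconcile.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .core import (AcquisitionSchedule, MassSpectrum, NoContactError,
                   PixelRecord, TruncationError)
from .io import Image4D

_EPS = 1e-9


def detect_contact(scans: Sequence[MassSpectrum],
                   tic_window_mz: Optional[tuple[float, float]] = None,
                   threshold_factor: float = 5.0) -> int:
    """Index of the first scan whose windowed TIC signals tissue contact.

    A scan establishes contact when its TIC exceeds ``threshold_factor``
    times the median TIC of all earlier (pre-signal) scans.  With
    ``threshold_factor <= 0`` everything qualifies and index 0 is
    returned.  Raises :class:`NoContactError` for an all-baseline stream.
    """
    if len(scans) < 3:
        raise ValueError("need at least 3 scans to detect contact")
    if threshold_factor <= 0:
        return 0
    tics = np.array([s.tic(tic_window_mz) for s in scans])
    for i in range(1, len(tics)):
        baseline = float(np.median(tics[:i]))
        if tics[i] > threshold_factor * baseline:
            return i
    raise NoContactError("no scan exceeded the contact threshold")


def align_to_contact(scans: Sequence[MassSpectrum],
                     contact_index: int) -> list[MassSpectrum]:
    """Re-zero all scan times to the contact scan's start.

    Pre-contact scans keep negative times so audits can still count them.
    """
    t0 = scans[contact_index].time_s
    return [s.shifted(-t0) for s in scans]


def spot_sample(scans: Sequence[MassSpectrum],
                schedule: AcquisitionSchedule,
                pixel_order: Sequence[tuple[int, int]]) -> Image4D:
    """Assemble a discrete-mode stream into a 4D image.

    Scans are assigned by start time; those in overhead gaps or before the
    first pixel are discarded but counted in ``image.metadata['audit']``.
    A stream too short to fill every pixel raises :class:`TruncationError`
    listing the unfilled pixels.
    """
    if schedule.mode != "discrete":
        raise ValueError("schedule.mode must be 'discrete'")
    dt = schedule.scan_period_s
    dwell = schedule.dwell_s
    period = dwell + schedule.per_pixel_overhead_s
    n_slots = schedule.scans_per_dwell()
    time_axis = np.arange(n_slots) * dt

    assigned: dict[int, list[MassSpectrum]] = {p: [] for p in range(len(pixel_order))}
    n_overhead = n_precontact = n_beyond = 0
    for s in scans:
        if s.time_s < -_EPS:
            n_precontact += 1
            continue
        p = int(math.floor(s.time_s / period + _EPS))
        offset = s.time_s - p * period
        if p >= len(pixel_order):
            n_beyond += 1
        elif offset < dwell - _EPS:
            assigned[p].append(s.shifted(-p * period))
        else:
            n_overhead += 1

    pixels = {}
    unfilled = []
    for p, (c, r) in enumerate(pixel_order):
        if not assigned[p]:
            unfilled.append((c, r))
            continue
        center = ((c + 0.5) * schedule.pitch_x_um, (r + 0.5) * schedule.pitch_y_um)
        pixels[(c, r)] = PixelRecord(c, r, center, assigned[p])
    if unfilled:
        raise TruncationError(
            f"stream too short: {len(unfilled)} unfilled pixels", unfilled)

    n_cols = max((c for c, _ in pixel_order), default=-1) + 1
    n_rows = max((r for _, r in pixel_order), default=-1) + 1
    audit = {"assigned": sum(len(v) for v in assigned.values()),
             "overhead": n_overhead, "precontact": n_precontact,
             "beyond_schedule": n_beyond, "total": len(scans)}
    return Image4D(pixels, n_cols, n_rows, schedule, time_axis,
                   metadata={"audit": audit})


def time_bin(scans: Sequence[MassSpectrum],
             schedule: AcquisitionSchedule,
             line_geometry: tuple[int, int]) -> Image4D:
    """Bin a continuous-mode linescan stream into a 2D image.

    ``line_geometry`` is (n_cols, n_rows).  Each line spans
    ``n_cols * pitch_x / speed`` seconds (plus the inter-line overhead);
    a scan joins the pixel under the stage at its midpoint.  Pixels are
    single-spectrum (scans averaged); a line too short to cover every
    column raises :class:`TruncationError`.
    """
    if schedule.mode != "continuous":
        raise ValueError("schedule.mode must be 'continuous'")
    n_cols, n_rows = line_geometry
    if n_cols < 1 or n_rows < 1:
        raise ValueError("line_geometry must be positive")
    speed = schedule.raster_speed_um_s
    dt = schedule.scan_period_s
    line_time = n_cols * schedule.pitch_x_um / speed
    line_period = line_time + schedule.per_pixel_overhead_s

    buckets: dict[tuple[int, int], list[MassSpectrum]] = {}
    n_overhead = n_precontact = n_beyond = 0
    for s in scans:
        if s.time_s < -_EPS:
            n_precontact += 1
            continue
        r = int(math.floor(s.time_s / line_period + _EPS))
        offset = s.time_s - r * line_period
        if r >= n_rows:
            n_beyond += 1
            continue
        if offset >= line_time - _EPS:
            n_overhead += 1
            continue
        x_mid = speed * (offset + dt / 2.0)
        c = min(int(x_mid // schedule.pitch_x_um), n_cols - 1)
        buckets.setdefault((c, r), []).append(s)

    unfilled = [(c, r) for r in range(n_rows) for c in range(n_cols)
                if (c, r) not in buckets]
    if unfilled:
        raise TruncationError(
            f"short line(s): {len(unfilled)} empty pixels", unfilled)

    pixels = {}
    for (c, r), members in buckets.items():
        mz = members[0].mz
        inten = np.mean([m.intensity for m in members], axis=0)
        center = ((c + 0.5) * schedule.pitch_x_um, (r + 0.5) * schedule.pitch_y_um)
        spec = MassSpectrum(members[0].scan_index, 0.0, mz, inten,
                            ms_level=members[0].ms_level)
        pixels[(c, r)] = PixelRecord(c, r, center, [spec])
    audit = {"assigned": sum(len(v) for v in buckets.values()),
             "overhead": n_overhead, "precontact": n_precontact,
             "beyond_schedule": n_beyond, "total": len(scans)}
    return Image4D(pixels, n_cols, n_rows, schedule, np.array([0.0]),
                   metadata={"audit": audit})


def plan_acquisition(n_cols: int, n_rows: int,
                     schedule: AcquisitionSchedule
                     ) -> tuple[int, float, float, float]:
    """(n_pixels, raster_time_s, dead_time_s, total_time_s) for a grid.

    Discrete mode: raster = pixels * dwell, dead = pixels * overhead —
    390 pixels at 90 s dwell + 12.9 s overhead comes to ~11.2 h, matching
    the roughly half-day scale of a discrete-mode image.
    """
    if n_cols < 1 or n_rows < 1:
        raise ValueError("grid dimensions must be positive")
    n_pixels = n_cols * n_rows
    if schedule.mode == "discrete":
        raster = n_pixels * schedule.dwell_s
        dead = n_pixels * schedule.per_pixel_overhead_s
    else:
        line_time = n_cols * schedule.pitch_x_um / schedule.raster_speed_um_s
        raster = n_rows * line_time
        dead = n_rows * schedule.per_pixel_overhead_s
    return n_pixels, raster, dead, raster + dead


def transit_time(schedule: AcquisitionSchedule) -> float:
    """Continuous-mode junction transit time: diameter / raster speed."""
    if schedule.mode != "continuous":
        raise ValueError("transit_time is defined for continuous mode")
    if not schedule.raster_speed_um_s or schedule.raster_speed_um_s <= 0:
        raise ValueError("raster speed must be positive")
    return schedule.junction_diameter_um / schedule.raster_speed_um_s
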