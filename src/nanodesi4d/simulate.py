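"""Forward simulator for discrete- and continuous-mode nano-DESI runs.

A tissue phantom (a labelled pixel grid, e.g. gray vs white matter) is
sampled by a virtual probe.  Each species carries a solubility class with a
parametric dissolution-kinetics curve:

* soluble:               ``exp(-t / tau_fast)``
* membrane-associated:   ``(t / tau_rise) * exp(-t / tau_rise)``, unit peak
* transmembrane:         ``(1 - exp(-t / tau_rise)) * exp(-t / tau_slow)``,
  unit peak

Spectra are sums of Gaussian charge-state peaks at ``(M + z*mp) / z`` with
an Orbitrap-like resolving power falling as ``sqrt(1/(m/z))``, plus optional
additive Gaussian baseline noise.  Every run returns the scan stream and a
ground-truth table (noiseless per-scan amplitudes plus the scan -> pixel
map) so downstream stages can be tested without instrument data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AcquisitionSchedule, MassSpectrum, PROTON_MASS_DA

SOLUBILITY_CLASSES = ("soluble", "membrane_associated", "transmembrane")


@dataclass
class SpeciesDefinition:
    """Simulator ground truth for one protein or complex.

    ``kinetics_params`` is ``(tau_fast, tau_rise, tau_slow)`` in seconds;
    each solubility class reads the parameters it needs.  ``abundance_map``
    maps phantom region label -> relative abundance.
    """

    name: str
    neutral_mass_da: float
    charges: Sequence[int]
    charge_weights: Sequence[float]
    solubility_class: str
    kinetics_params: tuple[float, float, float] = (10.0, 30.0, 120.0)
    abundance_map: dict = field(default_factory=lambda: {0: 1.0})

    def __post_init__(self) -> None:
        if self.neutral_mass_da <= 0:
            raise ValueError("neutral_mass_da must be positive")
        if self.solubility_class not in SOLUBILITY_CLASSES:
            raise ValueError(f"unknown solubility_class {self.solubility_class!r}")
        if len(self.charges) != len(self.charge_weights):
            raise ValueError("charges and charge_weights must be parallel")
        w = np.asarray(self.charge_weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("charge_weights must be non-negative, not all zero")
        self.charge_weights = tuple(w / w.sum())
        if any(p <= 0 for p in self.kinetics_params):
            raise ValueError("kinetics_params must be positive")

    def mz_centers(self) -> list[float]:
        """Charge-state envelope centers (M + z*mp)/z for each charge z."""
        return [(self.neutral_mass_da + z * PROTON_MASS_DA) / z for z in self.charges]

    def to_dict(self) -> dict:
        return {"name": self.name, "neutral_mass_da": self.neutral_mass_da,
                "charges": list(self.charges),
                "charge_weights": list(self.charge_weights),
                "solubility_class": self.solubility_class,
                "kinetics_params": list(self.kinetics_params),
                "abundance_map": {str(k): v for k, v in self.abundance_map.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesDefinition":
        d = dict(d)
        d["kinetics_params"] = tuple(d.get("kinetics_params", (10.0, 30.0, 120.0)))
        d["abundance_map"] = {int(k): float(v)
                              for k, v in d.get("abundance_map", {0: 1.0}).items()}
        return cls(**d)


@dataclass
class Phantom:
    """A labelled pixel grid standing in for a tissue section."""

    n_cols: int
    n_rows: int
    region_labels: np.ndarray  # shape (n_rows, n_cols), integer labels

    def __post_init__(self) -> None:
        self.region_labels = np.asarray(self.region_labels, dtype=int)
        if self.region_labels.shape != (self.n_rows, self.n_cols):
            raise ValueError("region_labels shape must be (n_rows, n_cols)")

    @property
    def n_pixels(self) -> int:
        return self.n_cols * self.n_rows

    def pixel_order(self) -> list[tuple[int, int]]:
        """Row-major (col, row) acquisition order."""
        return [(c, r) for r in range(self.n_rows) for c in range(self.n_cols)]

    @classmethod
    def two_region_default(cls) -> "Phantom":
        """30 x 14 grid (420 px) with a 51-pixel band of region 1.

        Emulates a brain section where a white-matter tract (e.g. the
        corpus callosum) crosses predominantly gray matter; the 369/51
        split matches the class sizes the segmentation stage recovers.
        """
        labels = np.zeros((14, 30), dtype=int)
        labels[5:8, 5:22] = 1  # 3 rows x 17 cols = 51 pixels
        return cls(n_cols=30, n_rows=14, region_labels=labels)

    def to_dict(self) -> dict:
        return {"n_cols": self.n_cols, "n_rows": self.n_rows,
                "region_labels": self.region_labels.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Phantom":
        return cls(n_cols=d["n_cols"], n_rows=d["n_rows"],
                   region_labels=np.asarray(d["region_labels"]))


def elution_kinetics(species: SpeciesDefinition, t) -> np.ndarray | float:
    """Relative dissolution signal in [0, 1] at time t seconds after contact."""
    scalar = np.isscalar(t)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    tau_fast, tau_rise, tau_slow = species.kinetics_params
    if species.solubility_class == "soluble":
        out = np.exp(-t / tau_fast)
    elif species.solubility_class == "membrane_associated":
        # unit peak at t = tau_rise
        out = (t / tau_rise) * np.exp(1.0 - t / tau_rise)
    else:  # transmembrane, unit peak at t* = tau_rise * ln((a+b)/a)
        a, b = tau_rise, tau_slow
        t_star = a * math.log((a + b) / a)
        peak = (1.0 - math.exp(-t_star / a)) * math.exp(-t_star / b)
        out = (1.0 - np.exp(-t / a)) * np.exp(-t / b) / peak
    return float(out) if scalar else out


def _envelope(species: SpeciesDefinition, mz_grid: np.ndarray,
              resolving_power_ref: float) -> np.ndarray:
    """Unit-abundance charge-state envelope of a species on the m/z grid."""
    out = np.zeros_like(mz_grid)
    for center, w in zip(species.mz_centers(), species.charge_weights):
        if w == 0:
            continue
        r_eff = resolving_power_ref * math.sqrt(200.0 / center)
        fwhm = center / r_eff
        sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        lo = np.searchsorted(mz_grid, center - 6 * sigma)
        hi = np.searchsorted(mz_grid, center + 6 * sigma)
        if hi > lo:
            x = mz_grid[lo:hi]
            out[lo:hi] += w * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    return out


def synth_spectrum(species_mix: Sequence[tuple[SpeciesDefinition, float]],
                   mz_grid: np.ndarray,
                   resolving_power_ref: float = 7500.0,
                   noise: tuple[float, float] = (0.0, 0.0),
                   seed: int = 0) -> MassSpectrum:
    """One synthetic SIM scan for a mixture of (species, abundance) pairs."""
    mz_grid = np.asarray(mz_grid, dtype=float)
    if mz_grid.size > 1 and not np.all(np.diff(mz_grid) > 0):
        raise ValueError("mz_grid must be strictly ascending")
    baseline, sd = noise
    intensity = np.full_like(mz_grid, float(baseline))
    for sp, abundance in species_mix:
        if abundance < 0:
            raise ValueError("abundances must be non-negative")
        if abundance > 0:
            intensity += abundance * _envelope(sp, mz_grid, resolving_power_ref)
    if sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, sd, size=mz_grid.size)
    np.clip(intensity, 0.0, None, out=intensity)
    return MassSpectrum(scan_index=0, time_s=0.0, mz=mz_grid, intensity=intensity)


@dataclass
class SimulationTruth:
    """Noiseless ground truth emitted alongside a simulated scan stream.

    ``amplitudes``: one row per (pixel, species, scan slot) with the
    noiseless envelope amplitude; ``scan_map``: one row per emitted scan
    with its global index, time, owning pixel (-1 for overhead scans) and
    slot.  ``noise_sd`` is the Gaussian noise actually applied.
    """

    amplitudes: pd.DataFrame
    scan_map: pd.DataFrame
    phantom: Phantom
    schedule: AcquisitionSchedule
    species: list[SpeciesDefinition]
    mz_grid: np.ndarray
    noise_sd: float
    baseline: float


def _resolve_noise_sd(noise_sd: Optional[float], snr: Optional[float],
                      peak_amplitude: float) -> float:
    if noise_sd is not None and snr is not None:
        raise ValueError("give noise_sd or snr, not both")
    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        return peak_amplitude / snr
    return float(noise_sd or 0.0)


def simulate_discrete_run(phantom: Phantom,
                          species: Sequence[SpeciesDefinition],
                          schedule: AcquisitionSchedule,
                          seed: int = 0,
                          mz_range: tuple[float, float] = (2400.0, 4000.0),
                          grid_step_mz: float = 0.25,
                          resolving_power_ref: float = 7500.0,
                          baseline: float = 0.0,
                          noise_sd: Optional[float] = None,
                          snr: Optional[float] = None,
                          emit_overhead_scans: bool = True,
                          ) -> tuple[list[MassSpectrum], SimulationTruth]:
    """Simulate a discrete-mode ("spot sampling") imaging run.

    Pixel ``p`` (row-major) occupies ``[p*(dwell+overhead), ... + dwell)``;
    within it, ``floor(dwell/dt)`` tissue scans start at offsets ``k*dt``
    and species amplitudes follow ``elution_kinetics`` at scan mid-times
    scaled by the pixel region's abundance.  Probe-lifted overhead scans
    (baseline only) start at offsets ``dwell + k*dt``.
    """
    if schedule.mode != "discrete":
        raise ValueError("schedule.mode must be 'discrete'")
    dt = schedule.scan_period_s
    n_d = schedule.scans_per_dwell()
    if n_d < 1:
        raise ValueError("dwell_s shorter than one scan period: no-scan pixels")
    n_o = int(math.floor(schedule.per_pixel_overhead_s / dt)) if emit_overhead_scans else 0
    period = schedule.dwell_s + schedule.per_pixel_overhead_s
    order = phantom.pixel_order()

    mz_grid = np.arange(mz_range[0], mz_range[1], grid_step_mz, dtype=float)
    envelopes = [_envelope(sp, mz_grid, resolving_power_ref) for sp in species]
    mid_t = (np.arange(n_d) + 0.5) * dt
    kin = {sp.name: elution_kinetics(sp, mid_t) for sp in species}

    # Noiseless amplitude table (pixel x species x slot), built first so
    # snr-based noise can be scaled from the true peak amplitude.
    amp_rows = []
    for p, (c, r) in enumerate(order):
        region = int(phantom.region_labels[r, c])
        for sp in species:
            ab = float(sp.abundance_map.get(region, 0.0))
            amps = ab * kin[sp.name]
            for k in range(n_d):
                amp_rows.append((p, c, r, region, sp.name, k,
                                 float(mid_t[k]), float(amps[k])))
    amplitudes = pd.DataFrame(amp_rows, columns=[
        "pixel", "col", "row", "region", "species", "scan_slot",
        "time_mid_s", "amplitude"])

    peak = 0.0
    for sp, env in zip(species, envelopes):
        max_ab = max((float(v) for v in sp.abundance_map.values()), default=0.0)
        peak = max(peak, max_ab * float(kin[sp.name].max(initial=0.0)) * float(env.max(initial=0.0)))
    sd = _resolve_noise_sd(noise_sd, snr, peak)

    rng = np.random.default_rng(seed)
    scans: list[MassSpectrum] = []
    map_rows = []
    amp_by_pixel = amplitudes.pivot_table(index=["pixel", "scan_slot"],
                                          columns="species", values="amplitude")
    names = [sp.name for sp in species]
    idx = 0
    for p, (c, r) in enumerate(order):
        t0 = p * period
        for k in range(n_d):
            intensity = np.full_like(mz_grid, baseline)
            row = amp_by_pixel.loc[(p, k)]
            for name, env in zip(names, envelopes):
                a = float(row[name])
                if a > 0:
                    intensity += a * env
            if sd > 0:
                intensity = intensity + rng.normal(0.0, sd, size=mz_grid.size)
            np.clip(intensity, 0.0, None, out=intensity)
            scans.append(MassSpectrum(idx, t0 + k * dt, mz_grid, intensity))
            map_rows.append((idx, t0 + k * dt, p, k))
            idx += 1
        for k in range(n_o):
            intensity = np.full_like(mz_grid, baseline)
            if sd > 0:
                intensity = intensity + rng.normal(0.0, sd, size=mz_grid.size)
            np.clip(intensity, 0.0, None, out=intensity)
            t = t0 + schedule.dwell_s + k * dt
            scans.append(MassSpectrum(idx, t, mz_grid, intensity))
            map_rows.append((idx, t, -1, -1))
            idx += 1
    scan_map = pd.DataFrame(map_rows, columns=["scan", "time_s", "pixel", "scan_slot"])
    truth = SimulationTruth(amplitudes, scan_map, phantom, schedule,
                            list(species), mz_grid, sd, baseline)
    return scans, truth


def simulate_continuous_run(phantom: Phantom,
                            species: Sequence[SpeciesDefinition],
                            schedule: AcquisitionSchedule,
                            seed: int = 0,
                            mz_range: tuple[float, float] = (2400.0, 4000.0),
                            grid_step_mz: float = 0.25,
                            resolving_power_ref: float = 7500.0,
                            baseline: float = 0.0,
                            noise_sd: Optional[float] = None,
                            snr: Optional[float] = None,
                            ) -> tuple[list[MassSpectrum], SimulationTruth]:
    """Simulate a continuous-mode (rastered linescan) run.

    The junction transits any location in ``diameter / speed`` seconds, so
    every species is seen at a single effective exposure: its amplitude is
    ``abundance * elution_kinetics(transit_time)``, constant along a line
    except for the region label under the probe.  Lines are row-major; an
    overhead gap of ``per_pixel_overhead_s`` separates lines.
    """
    if schedule.mode != "continuous":
        raise ValueError("schedule.mode must be 'continuous'")
    speed = schedule.raster_speed_um_s
    dt = schedule.scan_period_s
    transit = schedule.junction_diameter_um / speed
    line_len = phantom.n_cols * schedule.pitch_x_um
    line_time = line_len / speed
    n_line = int(math.floor(line_time / dt))
    if n_line < 1:
        raise ValueError("line shorter than one scan period")

    mz_grid = np.arange(mz_range[0], mz_range[1], grid_step_mz, dtype=float)
    envelopes = [_envelope(sp, mz_grid, resolving_power_ref) for sp in species]
    kin_at_transit = {sp.name: float(elution_kinetics(sp, transit)) for sp in species}

    peak = max((max((float(v) for v in sp.abundance_map.values()), default=0.0)
                * kin_at_transit[sp.name] * float(env.max(initial=0.0))
                for sp, env in zip(species, envelopes)), default=0.0)
    sd = _resolve_noise_sd(noise_sd, snr, peak)

    rng = np.random.default_rng(seed)
    scans: list[MassSpectrum] = []
    amp_rows, map_rows = [], []
    idx = 0
    for r in range(phantom.n_rows):
        t_line = r * (line_time + schedule.per_pixel_overhead_s)
        for k in range(n_line):
            x_mid = speed * (k * dt + dt / 2.0)
            c = min(int(x_mid // schedule.pitch_x_um), phantom.n_cols - 1)
            region = int(phantom.region_labels[r, c])
            intensity = np.full_like(mz_grid, baseline)
            for sp, env in zip(species, envelopes):
                a = float(sp.abundance_map.get(region, 0.0)) * kin_at_transit[sp.name]
                if a > 0:
                    intensity += a * env
                amp_rows.append((idx, r, c, region, sp.name, a))
            if sd > 0:
                intensity = intensity + rng.normal(0.0, sd, size=mz_grid.size)
            np.clip(intensity, 0.0, None, out=intensity)
            scans.append(MassSpectrum(idx, t_line + k * dt, mz_grid, intensity))
            map_rows.append((idx, t_line + k * dt, r, k))
            idx += 1
    amplitudes = pd.DataFrame(amp_rows, columns=["scan", "row", "col", "region",
                                                 "species", "amplitude"])
    scan_map = pd.DataFrame(map_rows, columns=["scan", "time_s", "line", "slot"])
    truth = SimulationTruth(amplitudes, scan_map, phantom, schedule,
                            list(species), mz_grid, sd, baseline)
    return scans, truth


def default_species_panel() -> list[SpeciesDefinition]:
    """Five brain-like species spanning the three solubility classes.

    Neutral masses are taken from the printed charge-state series of the
    archetype proteins (Arf3+GDP, CAH2+Zn, Rab3a+GDP, MAL, VDAC1) so every
    envelope falls inside the m/z 2400-4000 SIM window.  Region 0 plays
    gray matter, region 1 white matter.
    """
    return [
        SpeciesDefinition("Arf3_GDP", 21122.3, (6, 7, 8), (0.2, 0.45, 0.35),
                          "soluble", (10.0, 30.0, 120.0), {0: 1.0, 1: 0.2}),
        SpeciesDefinition("CAH2_Zn", 29090.0, (9, 10, 11), (0.3, 0.45, 0.25),
                          "soluble", (12.0, 30.0, 120.0), {0: 0.25, 1: 1.0}),
        SpeciesDefinition("Rab3a_GDP", 25882.9, (8, 9, 10), (0.3, 0.4, 0.3),
                          "membrane_associated", (10.0, 30.0, 120.0),
                          {0: 1.0, 1: 0.3}),
        SpeciesDefinition("MAL", 16700.0, (5, 6), (0.45, 0.55),
                          "transmembrane", (10.0, 2.5, 300.0), {0: 0.1, 1: 1.0}),
        SpeciesDefinition("VDAC1", 30668.0, (8, 9, 10, 11), (0.2, 0.3, 0.3, 0.2),
                          "transmembrane", (10.0, 2.5, 300.0), {0: 0.8, 1: 0.45}),
    ]


def default_chimera_products() -> tuple[list[SpeciesDefinition], list[SpeciesDefinition]]:
    """Product-ion species for a two-family chimeric MS2 fixture.

    Returns (fast, slow): crystallin-like subunits ejected from a soluble
    heterotetramer (fast, soluble kinetics) and Aqp0-like monomers/trimers
    from a membrane homotetramer (slow rise-decay kinetics), mimicking
    co-isolation of both inside one precursor window.
    """
    fast = [
        SpeciesDefinition("gammaCry", 21000.0, (10, 11, 12, 13),
                          (0.2, 0.3, 0.3, 0.2), "soluble", (10.0, 30.0, 120.0)),
        SpeciesDefinition("betaB2Cry", 23380.0, (9, 10, 11, 12),
                          (0.2, 0.3, 0.3, 0.2), "soluble", (8.0, 30.0, 120.0)),
        SpeciesDefinition("betaA4Cry", 22400.0, (10, 11, 12),
                          (0.3, 0.4, 0.3), "soluble", (12.0, 30.0, 120.0)),
    ]
    slow = [
        SpeciesDefinition("Aqp0_monomer", 28122.0, (6, 7, 8, 9, 10),
                          (0.15, 0.2, 0.3, 0.2, 0.15),
                          "transmembrane", (10.0, 30.0, 120.0)),
        SpeciesDefinition("Aqp0_trimer", 84366.0, (11, 12, 13),
                          (0.3, 0.4, 0.3), "transmembrane", (10.0, 30.0, 120.0)),
    ]
    return fast, slow


def simulate_ms2_locations(products: Sequence[SpeciesDefinition],
                           n_locations: int,
                           dwell_s: float,
                           scan_period_s: float = 2.6,
                           seed: int = 0,
                           precursor_window: tuple[float, float] = (6281.0, 15.0),
                           mz_range: tuple[float, float] = (1500.0, 8000.0),
                           grid_step_mz: float = 0.25,
                           resolving_power_ref: float = 7500.0,
                           baseline: float = 0.0,
                           noise_sd: Optional[float] = None,
                           snr: Optional[float] = None,
                           ) -> list[list[MassSpectrum]]:
    """MS2 product-ion scan streams from several discrete sampling locations.

    Precursor isolation is modelled only as a recorded (center, half-width)
    window; each product ion inherits its precursor's dissolution kinetics,
    so product elution profiles mirror precursor solubility.  Times are
    relative to tissue contact at each location.
    """
    if n_locations < 1 or dwell_s <= 0 or scan_period_s <= 0:
        raise ValueError("n_locations, dwell_s and scan_period_s must be positive")
    n_scans = int(math.floor(dwell_s / scan_period_s))
    mz_grid = np.arange(mz_range[0], mz_range[1], grid_step_mz, dtype=float)
    envelopes = [_envelope(sp, mz_grid, resolving_power_ref) for sp in products]
    mid_t = (np.arange(n_scans) + 0.5) * scan_period_s
    kin = [elution_kinetics(sp, mid_t) for sp in products]

    peak = max((float(sp.abundance_map.get(0, 1.0)) * float(k.max(initial=0.0))
                * float(env.max(initial=0.0))
                for sp, k, env in zip(products, kin, envelopes)), default=0.0)
    sd = _resolve_noise_sd(noise_sd, snr, peak)

    rng = np.random.default_rng(seed)
    locations = []
    for loc in range(n_locations):
        scans = []
        for k in range(n_scans):
            intensity = np.full_like(mz_grid, baseline)
            for sp, kcurve, env in zip(products, kin, envelopes):
                a = float(sp.abundance_map.get(0, 1.0)) * float(kcurve[k])
                if a > 0:
                    intensity += a * env
            if sd > 0:
                intensity = intensity + rng.normal(0.0, sd, size=mz_grid.size)
            np.clip(intensity, 0.0, None, out=intensity)
            scans.append(MassSpectrum(k, k * scan_period_s, mz_grid, intensity,
                                      ms_level=2, precursor_window=precursor_window))
        locations.append(scans)
    return locations
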