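"""Elution-time-filtered ion images and multivariate tissue segmentation.

Ion images integrate a target's XIC per pixel, optionally restricted to a
half-open elution-time window — the elution-time analogue of ion-mobility
filtering, trading total signal for specificity.  Segmentation follows
standard MSI practice: 2-m/z binning, per-pixel TIC normalization, PCA to
5 components, and seeded k-means with k = 2 to split tissue classes such
as gray and white matter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import XICTarget
from .io import Image4D
from .profiles import ElutionProfile, average_profiles, extract_xic


@dataclass
class IonImage:
    """A 2D intensity grid for one target over one elution-time window."""

    grid: np.ndarray  # (n_rows, n_cols)
    target: XICTarget
    time_window_s: Optional[tuple[float, float]]
    normalization: str = "none"  # "none" | "max"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(self.grid < 0):
            raise ValueError("ion-image intensities must be non-negative")

    def normalized(self) -> "IonImage":
        peak = self.grid.max()
        grid = self.grid / peak if peak > 0 else self.grid
        return IonImage(grid, self.target, self.time_window_s, "max")


@dataclass
class SegmentationResult:
    """Pixel labels plus per-class summaries from PCA + k-means."""

    labels: np.ndarray
    n_components: int
    k: int
    class_sizes: tuple
    class_mean_spectra: np.ndarray  # (k, n_bins), mean of the raw binned rows
    seed: int

    def __post_init__(self) -> None:
        if int(self.labels.size) != int(sum(self.class_sizes)):
            raise ValueError("class sizes must sum to the pixel count")


def ion_image(image: Image4D, target: XICTarget,
              time_window_s: Optional[tuple[float, float]] = None) -> IonImage:
    """Per-pixel integrated XIC over an (optional) half-open time window."""
    if time_window_s is not None:
        start, end = time_window_s
        if start >= end:
            raise ValueError("time window must satisfy start < end")
    grid = np.zeros((image.n_rows, image.n_cols))
    for px in image.pixel_list():
        if time_window_s is None:
            members = [s for s in px.spectra if s.time_s >= 0]
        else:
            members = [s for s in px.spectra
                       if time_window_s[0] <= s.time_s < time_window_s[1]]
        if members:
            _, xic = extract_xic(members, target)
            grid[px.row, px.col] = xic.sum()
    return IonImage(grid, target, time_window_s)


def bin_spectra(image: Image4D, bin_width_mz: float = 2.0,
                mz_range: tuple[float, float] = (2400.0, 4000.0)
                ) -> tuple[np.ndarray, np.ndarray]:
    """Pixel x m/z-bin feature matrix (scans summed over the full dwell).

    Bins are half-open ``[lo + i*w, lo + (i+1)*w)``; a peak exactly on an
    edge goes to the right-hand bin.  Returns (matrix, bin_edges) with
    pixels in row-major order.  Total intensity inside the range is
    conserved exactly.
    """
    lo, hi = mz_range
    if bin_width_mz <= 0 or hi <= lo:
        raise ValueError("invalid bin width or m/z range")
    n_bins = int(math.ceil((hi - lo) / bin_width_mz))
    edges = lo + bin_width_mz * np.arange(n_bins + 1)
    pixel_list = image.pixel_list()
    matrix = np.zeros((len(pixel_list), n_bins))
    for i, px in enumerate(pixel_list):
        for s in px.spectra:
            sel = (s.mz >= lo) & (s.mz < hi)
            if not np.any(sel):
                continue
            idx = ((s.mz[sel] - lo) // bin_width_mz).astype(int)
            np.add.at(matrix[i], idx, s.intensity[sel])
        if matrix[i].sum() == 0:
            warnings.warn(f"pixel ({px.col},{px.row}) has no signal in "
                          f"m/z {lo}-{hi}")
    return matrix, edges


def segment(matrix: np.ndarray, n_components: int = 5, k: int = 2,
            seed: int = 0) -> SegmentationResult:
    """TIC-normalize, PCA, and k-means cluster a binned feature matrix.

    Rows are scaled to unit TIC (zero rows left as-is) and mean-centered
    by the PCA; labels are canonicalized so label 0 is the largest class,
    making results comparable across seeds.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    matrix = np.asarray(matrix, dtype=float)
    if np.any(matrix < 0):
        raise ValueError("feature matrix must be non-negative")
    n_pixels = matrix.shape[0]
    if n_pixels <= k:
        raise ValueError("need more pixels than clusters")
    tic = matrix.sum(axis=1, keepdims=True)
    tic[tic == 0] = 1.0
    norm = matrix / tic

    max_rank = min(norm.shape[0] - 1, norm.shape[1])
    n_comp = min(n_components, max_rank)
    if n_comp < n_components:
        warnings.warn(f"rank limits PCA to {n_comp} components")
    scores = PCA(n_components=n_comp, random_state=seed).fit_transform(norm)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scores)

    raw = km.labels_
    sizes = np.bincount(raw, minlength=k)
    order = sorted(range(k), key=lambda lab: (-sizes[lab], lab))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[lab] for lab in raw])
    class_sizes = tuple(int(n) for n in np.bincount(labels, minlength=k))
    class_means = np.vstack([
        matrix[labels == lab].mean(axis=0) if np.any(labels == lab)
        else np.zeros(matrix.shape[1]) for lab in range(k)])
    return SegmentationResult(labels=labels, n_components=n_comp, k=k,
                              class_sizes=class_sizes,
                              class_mean_spectra=class_means, seed=seed)


def class_mean_spectrum(image: Image4D, labels: np.ndarray,
                        targets: Sequence[XICTarget] = (),
                        bin_width_mz: float = 2.0,
                        mz_range: tuple[float, float] = (2400.0, 4000.0)
                        ) -> tuple[dict, dict]:
    """Per-class mean binned spectrum and per-class elution profiles.

    Returns ``(mean_spectra, profiles)``: label -> mean binned spectrum,
    and label -> {target label -> ElutionProfile} computed by
    :func:`average_profiles` restricted to the class's pixels.  Empty
    classes are excluded with a warning.
    """
    labels = np.asarray(labels)
    pixel_list = image.pixel_list()
    if labels.size != len(pixel_list):
        raise ValueError("labels must match the pixel count")
    matrix, _ = bin_spectra(image, bin_width_mz, mz_range)
    mean_spectra: dict[int, np.ndarray] = {}
    profiles: dict[int, dict[str, ElutionProfile]] = {}
    for lab in sorted(set(int(x) for x in labels)):
        members = [px for px, l in zip(pixel_list, labels) if l == lab]
        if not members:
            warnings.warn(f"class {lab} is empty; excluded")
            continue
        mean_spectra[lab] = matrix[labels == lab].mean(axis=0)
        sub = Image4D({(px.col, px.row): px for px in members},
                      image.n_cols, image.n_rows, image.schedule,
                      image.time_axis, metadata={"class": lab})
        profiles[lab] = {t.label: average_profiles(sub, t) for t in targets}
    return mean_spectra, profiles
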