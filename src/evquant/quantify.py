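"""Intensity statistics on detected particles.

Implements the population metrics used to compare staining chemistries:
background-subtracted integrated intensities per particle, normalized mean
intensity (integrated / area / acquisition time), distribution summaries
with dynamic range (max - min, optionally quantile-truncated), fold-change
ratios, counts per field of view, and photobleaching stability profiles
measured on the time-0 particle masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .detection import DetectionParams, Particle
from .stack import ImageStack

__all__ = [
    "IntensityDistribution",
    "StabilityProfile",
    "background_offset",
    "integrated_intensity",
    "measure_particles",
    "normalized_mean_intensity",
    "dynamic_range",
    "fold_change",
    "stability_profile",
    "counts_per_fov",
]


# ---------------------------------------------------------------------------
# background and per-particle intensities
# ---------------------------------------------------------------------------


def background_offset(image: np.ndarray, particles: list[Particle]) -> float:
    """Per-image background: median of non-particle pixels.

    Particle masks are dilated by 3 px before exclusion so PSF tails do not
    bias the estimate; robust to sparse fields where almost every pixel is
    background.
    """
    image = np.asarray(image, dtype=float)
    mask = np.zeros(image.shape, dtype=bool)
    for p in particles:
        mask[p.pixel_coords[:, 0], p.pixel_coords[:, 1]] = True
    if mask.any():
        mask = ndi.binary_dilation(mask, iterations=3)
    bg = image[~mask]
    if bg.size == 0:
        return float(np.median(image))
    return float(np.median(bg))


def _aperture_coords(
    particle: Particle, shape: tuple[int, int], dilation_px: int
) -> np.ndarray:
    if dilation_px <= 0:
        return particle.pixel_coords
    ys, xs = particle.pixel_coords[:, 0], particle.pixel_coords[:, 1]
    y0 = max(0, ys.min() - dilation_px - 1)
    x0 = max(0, xs.min() - dilation_px - 1)
    y1 = min(shape[0], ys.max() + dilation_px + 2)
    x1 = min(shape[1], xs.max() + dilation_px + 2)
    local = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    local[ys - y0, xs - x0] = True
    local = ndi.binary_dilation(local, iterations=dilation_px)
    cc = np.argwhere(local)
    cc[:, 0] += y0
    cc[:, 1] += x0
    return cc


def integrated_intensity(
    particle: Particle,
    image: np.ndarray,
    offset: float = 0.0,
    dilation_px: int = 0,
) -> float:
    """Background-subtracted integrated intensity of one particle (ADU).

    Sum of image values over the particle mask (optionally dilated into an
    aperture that captures the PSF tails) minus ``offset`` per pixel, where
    ``offset`` is typically :func:`background_offset` of the image.
    """
    image = np.asarray(image, dtype=float)
    coords = particle.pixel_coords
    if (
        coords[:, 0].min() < 0
        or coords[:, 1].min() < 0
        or coords[:, 0].max() >= image.shape[0]
        or coords[:, 1].max() >= image.shape[1]
    ):
        raise ValueError("particle mask lies outside the image bounds")
    ap = _aperture_coords(particle, image.shape, dilation_px)
    vals = image[ap[:, 0], ap[:, 1]]
    return float(vals.sum() - offset * len(ap))


def measure_particles(
    particles: list[Particle],
    image: np.ndarray,
    params: DetectionParams | None = None,
    channel: str = "ch0",
) -> pd.DataFrame:
    """Tidy per-particle intensity table for one channel.

    Columns: id, x, y, area_px, raw_sum, integrated (background-subtracted
    aperture sum), mean. The aperture dilation comes from
    ``params.intensity_dilation_px`` (default 3 px).
    """
    image = np.asarray(image, dtype=float)
    dil = params.intensity_dilation_px if params is not None else 3
    offset = background_offset(image, particles)
    rows = []
    for p in particles:
        raw = float(image[p.pixel_coords[:, 0], p.pixel_coords[:, 1]].sum())
        integ = integrated_intensity(p, image, offset=offset, dilation_px=dil)
        rows.append(
            {
                "id": p.id,
                "x": p.centroid[0],
                "y": p.centroid[1],
                "area_px": p.area_px,
                "raw_sum": raw,
                "integrated": integ,
                "mean": raw / p.area_px if p.area_px else 0.0,
                "channel": channel,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["id", "x", "y", "area_px", "raw_sum", "integrated", "mean", "channel"],
    )
    df.attrs["background_offset"] = offset
    return df


def normalized_mean_intensity(
    integrated: float, area_px2: float, acquisition_time_ms: float
) -> float:
    """Integrated intensity divided by 2D area and acquisition time.

    Units ADU / px^2 / ms; makes intensities comparable across objects of
    different size imaged with different exposures.
    """
    if area_px2 <= 0:
        raise ValueError("area must be positive")
    if acquisition_time_ms <= 0:
        raise ValueError("acquisition time must be positive")
    return float(integrated) / float(area_px2) / float(acquisition_time_ms)


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


@dataclass
class IntensityDistribution:
    """Summary of a per-particle (IntI) or per-pixel (PixI) intensity sample."""

    values: np.ndarray
    truncation: tuple[float, float] | None = None  # quantiles in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size == 0:
            raise ValueError("empty intensity distribution")
        self.values = v
        if self.truncation is not None:
            lo, hi = self.truncation
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError("truncation quantiles must satisfy 0 <= lo < hi <= 1")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def _retained(self) -> np.ndarray:
        if self.truncation is None:
            return self.values
        lo, hi = np.quantile(self.values, self.truncation)
        return self.values[(self.values >= lo) & (self.values <= hi)]

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def min(self) -> float:
        return float(self._retained().min())

    @property
    def max(self) -> float:
        return float(self._retained().max())

    @property
    def dynamic_range(self) -> float:
        return self.max - self.min

    def summary(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "median": self.median,
            "min": self.min,
            "max": self.max,
            "dynamic_range": self.dynamic_range,
        }


def dynamic_range(dist: IntensityDistribution | np.ndarray) -> float:
    """Difference between the highest and lowest intensity values
    (after the distribution's optional quantile truncation)."""
    if not isinstance(dist, IntensityDistribution):
        dist = IntensityDistribution(np.asarray(dist))
    return dist.dynamic_range


def fold_change(a: float, b: float, digits: int | None = 1) -> float:
    """Ratio a / b, reported to one decimal by default (``digits=None`` for
    the exact ratio)."""
    if b <= 0:
        raise ValueError("fold_change denominator must be positive")
    r = float(a) / float(b)
    return round(r, digits) if digits is not None else r


# ---------------------------------------------------------------------------
# stability over time
# ---------------------------------------------------------------------------


@dataclass
class StabilityProfile:
    """Photobleaching profile over the time-0 particle masks.

    ``retention[t] = mean_signal(t) / mean_signal(0)`` with background
    subtracted per frame; histograms of positive-pixel intensities share one
    set of bin edges across timepoints.
    """

    timepoints_min: tuple[float, ...]
    mean_signal: np.ndarray
    retention: np.ndarray
    bin_edges: np.ndarray
    histograms: np.ndarray  # (T, nbins)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timepoint_min": self.timepoints_min,
                "mean_signal": self.mean_signal,
                "retention": self.retention,
            }
        )


def stability_profile(
    timeseries: ImageStack,
    particles: list[Particle],
    channel: int | str = 0,
    n_bins: int = 64,
) -> StabilityProfile:
    """Signal stability across a 0/1/3/5-min style time series.

    Pixel intensities are collected over the union of the time-0 particle
    masks at every timepoint (no re-detection, so bleached particles are not
    silently dropped); per-frame background (median outside the masks) is
    subtracted from the mean signal.
    """
    if timeseries.n_timepoints < 2:
        raise ValueError("stability profile needs at least two timepoints")
    if not particles:
        raise ValueError("no particles detected at t=0")
    if isinstance(channel, str):
        channel = timeseries.channel_index(channel)
    shape = timeseries.shape_yx
    mask = np.zeros(shape, dtype=bool)
    for p in particles:
        mask[p.pixel_coords[:, 0], p.pixel_coords[:, 1]] = True

    frames = [timeseries.frame(t, channel) for t in range(timeseries.n_timepoints)]
    all_vals = np.concatenate([f[mask] for f in frames])
    edges = np.histogram_bin_edges(all_vals, bins=n_bins)
    hists, means = [], []
    for f in frames:
        vals = f[mask].astype(float)
        hists.append(np.histogram(vals, bins=edges)[0])
        bg = float(np.median(f[~mask])) if (~mask).any() else 0.0
        means.append(float(vals.mean()) - bg)
    means_arr = np.asarray(means)
    if means_arr[0] == 0:
        raise ValueError("zero mean signal at t=0; cannot normalise retention")
    return StabilityProfile(
        timepoints_min=timeseries.timepoints_min,
        mean_signal=means_arr,
        retention=means_arr / means_arr[0],
        bin_edges=edges,
        histograms=np.asarray(hists),
    )


# ---------------------------------------------------------------------------
# counts per field of view
# ---------------------------------------------------------------------------


def counts_per_fov(particle_lists: list) -> dict:
    """Per-FOV particle counts with mean and sample SD.

    Accepts lists of detected-particle lists or plain integer counts.
    """
    if len(particle_lists) == 0:
        raise ValueError("at least one FOV is required")
    counts = [
        int(len(pl)) if not isinstance(pl, (int, np.integer)) else int(pl)
        for pl in particle_lists
    ]
    arr = np.asarray(counts, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {"counts": counts, "mean": float(arr.mean()), "sd": sd, "n_fov": len(counts)}
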