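"""Quantification operators for multi-channel fluorescence images.

Implements the measurement conventions used throughout the pipeline: sum
projection of Z-stacks, summed-ROI quantification with a moved background ROI
of equal area, ratiometric reporter/control normalization, wide-line
intensity profiles between nuclei, the center:surround membrane-enrichment
ratio of the tGPH insulin-signalling reporter, lipid-droplet area fractions,
and per-frame GCaMP/tdTomato ratio time series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Roi",
    "RoiQuant",
    "LineProfile",
    "UndefinedRatioError",
    "sum_project",
    "roi_quant",
    "ratiometric",
    "extract_line_profile",
    "tgph_membrane_ratio",
    "droplet_area_fraction",
    "gcamp_ratio_series",
]

_EPS = 1e-9  # tolerance for normalized-position window membership


class UndefinedRatioError(ZeroDivisionError):
    """Reference signal is non-positive, so a ratio is undefined."""


@dataclass(frozen=True)
class Roi:
    """A region of interest: boolean mask over a 2-D image."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not m.any():
            raise ValueError("ROI mask is empty")
        object.__setattr__(self, "mask", m)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class RoiQuant:
    """Summed ROI intensity with a summed background subtracted."""

    raw_sum: float
    background_sum: float

    @property
    def corrected(self) -> float:
        return self.raw_sum - self.background_sum


@dataclass(frozen=True)
class LineProfile:
    """Width-averaged intensity along a line, positions normalized to [0, 1]."""

    positions: np.ndarray
    intensities: np.ndarray
    width_px: int

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        v = np.asarray(self.intensities, dtype=float)
        if p.size != v.size or p.size < 2:
            raise ValueError("positions and intensities must have equal length >= 2")
        if np.any(np.diff(p) <= 0):
            raise ValueError("positions must be strictly increasing")
        if abs(p[0]) > _EPS or abs(p[-1] - 1.0) > _EPS:
            raise ValueError("positions must span [0, 1]")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "intensities", v)


def sum_project(stack: np.ndarray) -> np.ndarray:
    """Sum-project a Z-stack (z, rows, cols) to a 2-D image; 2-D input is returned unchanged."""
    a = np.asarray(stack, dtype=float)
    if a.size == 0:
        raise ValueError("empty stack")
    if a.ndim == 2:
        return a
    if a.ndim == 3:
        return a.sum(axis=0)
    raise ValueError(f"expected 2-D or 3-D stack, got {a.ndim}-D")


def roi_quant(
    image: np.ndarray,
    roi: Roi,
    bg_roi: Roi,
    area_normalize: bool = False,
) -> RoiQuant:
    """Summed ROI intensity minus the summed intensity of a moved background ROI.

    The background ROI is the same region moved to an adjacent unstained
    area, so equal pixel counts are required (a constant offset then cancels
    exactly).  With ``area_normalize`` the background sum is rescaled to the
    signal ROI's area instead.  A negative corrected value is reported with a
    warning rather than clipped.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("roi_quant expects a 2-D image")
    raw = float(img[roi.mask].sum())
    bg = float(img[bg_roi.mask].sum())
    if roi.area != bg_roi.area:
        if not area_normalize:
            raise ValueError(
                f"ROI areas differ ({roi.area} vs {bg_roi.area}); "
                "pass area_normalize=True to rescale the background"
            )
        bg *= roi.area / bg_roi.area
    q = RoiQuant(raw_sum=raw, background_sum=bg)
    if q.corrected < 0:
        warnings.warn("background exceeds ROI signal; corrected value is negative", stacklevel=2)
    return q


def ratiometric(signal: RoiQuant, reference: RoiQuant) -> float:
    """Background-corrected signal/reference ratio (e.g. GCaMP over tdTomato)."""
    if reference.corrected <= 0:
        raise UndefinedRatioError("reference corrected intensity must be > 0")
    return signal.corrected / reference.corrected


def extract_line_profile(
    image: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    width_px: int = 15,
) -> LineProfile:
    """Intensity profile along the segment p0 -> p1, averaged over a 15-px-wide band.

    Points are (row, col).  The segment is sampled at <= 1-px spacing; at each
    position, ``width_px`` samples spaced 1 px apart along the perpendicular,
    symmetric about the segment, are averaged (bilinear interpolation).
    Positions are rescaled to [0, 1].
    """
    img = np.asarray(image, dtype=float)
    r0, c0 = map(float, p0)
    r1, c1 = map(float, p1)
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= img.shape[0] - 1 and 0 <= c <= img.shape[1] - 1):
            raise ValueError(f"endpoint ({r}, {c}) outside image")
    length = math.hypot(r1 - r0, c1 - c0)
    if length == 0:
        raise ValueError("zero-length line")
    if width_px < 1:
        raise ValueError("width_px must be >= 1")

    n = int(math.ceil(length)) + 1
    t = np.linspace(0.0, 1.0, n)
    rows = r0 + t * (r1 - r0)
    cols = c0 + t * (c1 - c0)
    # unit perpendicular
    ur, uc = (r1 - r0) / length, (c1 - c0) / length
    pr, pc = -uc, ur
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0

    sample_r = rows[None, :] + offsets[:, None] * pr
    sample_c = cols[None, :] + offsets[:, None] * pc
    vals = ndimage.map_coordinates(
        img, [sample_r.ravel(), sample_c.ravel()], order=1, mode="nearest"
    ).reshape(width_px, n)
    return LineProfile(positions=t, intensities=vals.mean(axis=0), width_px=width_px)


def tgph_membrane_ratio(profile: LineProfile) -> float:
    """Center:surround ratio of a nucleus-to-nucleus line profile.

    The center is the mean intensity over the middle tenth of the line
    (0.45 <= x <= 0.55, the membrane); the surround averages the flanking
    tenths (0.35 <= x < 0.45 and 0.55 < x <= 0.65, cytoplasm).  Window
    membership follows those inequalities exactly; samples outside
    [0.35, 0.65] are ignored.  The ratio reads out membrane enrichment of the
    reporter and hence insulin/PI3K activity.
    """
    x = profile.positions
    v = profile.intensities
    center = (x >= 0.45 - _EPS) & (x <= 0.55 + _EPS)
    surround = ((x >= 0.35 - _EPS) & (x < 0.45 - _EPS)) | ((x > 0.55 + _EPS) & (x <= 0.65 + _EPS))
    if not center.any() or not surround.any():
        raise ValueError("no samples in center or surround window")
    s = float(v[surround].mean())
    if s == 0:
        raise UndefinedRatioError("surround mean intensity is zero")
    return float(v[center].mean()) / s


def droplet_area_fraction(
    droplet_channel: np.ndarray,
    cell_mask: Roi | np.ndarray,
    threshold: float | None = None,
) -> float:
    """Fraction of the cell mask occupied by lipid droplets.

    Pixels above ``threshold`` within the mask count as droplet.  By default
    the threshold is Otsu's method computed on the within-mask intensities (a
    configurable choice); a contrast-free mask yields 0.0.
    """
    mask = cell_mask.mask if isinstance(cell_mask, Roi) else np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    vals = np.asarray(droplet_channel, dtype=float)[mask]
    if threshold is None:
        if np.ptp(vals) == 0:
            return 0.0
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(vals))
    frac = float((vals > threshold).sum() / vals.size)
    return frac


def gcamp_ratio_series(
    frames: Sequence[Mapping[str, np.ndarray]],
    soma_rois: Sequence[Roi],
    signal_channel: str = "gcamp",
    reference_channel: str = "tdtomato",
) -> np.ndarray:
    """Per-timepoint mean GCaMP/tdTomato ratio averaged over neurons.

    For each frame, the mean signal intensity within each soma ROI is divided
    by the mean reference intensity in the same ROI; the per-neuron ratios are
    then averaged (unweighted) into a single value per timepoint.  The same
    ROIs apply to every frame.
    """
    if not soma_rois:
        raise ValueError("at least one soma ROI required")
    shape = np.asarray(frames[0][signal_channel]).shape
    for roi in soma_rois:
        if roi.mask.shape != shape:
            raise ValueError("soma ROI shape does not match frame shape (ROI left the field?)")
    series = np.empty(len(frames))
    for i, frame in enumerate(frames):
        sig = np.asarray(frame[signal_channel], dtype=float)
        ref = np.asarray(frame[reference_channel], dtype=float)
        ratios = []
        for roi in soma_rois:
            ref_mean = ref[roi.mask].mean()
            if ref_mean <= 0:
                raise UndefinedRatioError("reference channel mean is non-positive in a soma ROI")
            ratios.append(sig[roi.mask].mean() / ref_mean)
        series[i] = float(np.mean(ratios))
    return series
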