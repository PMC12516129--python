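"""Fluorescence intensity quantification.

Implements the intensity analyses used alongside the orientation metric:

* total-intensity time series from the sum-of-slices projection (the sum of
  every pixel over every confocal plane at each time point), normalized by
  the common maximum over all co-plotted series;
* thick line-scan profiles: the mean of bilinearly interpolated intensities
  across the width of a 15-pixel-wide scan line, at 1-pixel steps along it;
* temporal-drift (photobleaching) correction: a per-frame scalar baseline —
  here a low-percentile frame statistic, optionally smoothed in time — is
  subtracted from raw profile values so profiles from different time points
  become comparable, then profiles are normalized by the maximum among the
  time points selected for plotting;
* the fraction of total fluorescence inside labelled compartments, with the
  outside fraction defined as its complement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter1d

from .io_formats import ImageStack


@dataclass
class IntensitySeries:
    """Per-frame total intensity, arbitrary units."""

    times_s: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity values must be finite")
        if self.normalized and not np.isclose(self.values.max(), 1.0):
            raise ValueError("normalized series must have maximum 1")


@dataclass
class LineProfile:
    """Mean intensity across a thick scan line vs distance along it."""

    distances_um: np.ndarray
    values: np.ndarray
    width_px: int
    corrected: bool = False

    def __post_init__(self) -> None:
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.width_px < 1:
            raise ValueError("profile width must be >= 1 pixel")
        d = self.distances_um
        if d[0] != 0.0 or np.any(np.diff(d) <= 0):
            raise ValueError("distances must increase strictly from 0")


def total_intensity_series(stack: ImageStack) -> IntensitySeries:
    """Raw total intensity per time point: sum over all planes and pixels."""
    totals = stack.data.astype(np.float64).sum(axis=(1, 2, 3))
    return IntensitySeries(times_s=stack.times_s, values=totals)


def normalize_common_max(series_list: list[IntensitySeries]) -> list[IntensitySeries]:
    """Divide every co-plotted series by their single common maximum."""
    if not series_list:
        raise ValueError("need at least one series")
    common_max = max(float(s.values.max()) for s in series_list)
    if common_max <= 0:
        raise ValueError("common maximum must be positive to normalize")
    return [
        IntensitySeries(
            times_s=s.times_s, values=s.values / common_max, normalized=True
        )
        if s.values.max() == common_max
        else IntensitySeries(times_s=s.times_s, values=s.values / common_max)
        for s in series_list
    ]


def line_profile(
    image: np.ndarray,
    start_um: tuple[float, float],
    end_um: tuple[float, float],
    pixel_size_um: float,
    width_px: int = 15,
) -> LineProfile:
    """Thick line-scan profile between two points of a single frame.

    Samples every 1 pixel along the segment; at each sample the value is
    the mean of ``width_px`` bilinearly interpolated intensities spaced
    1 pixel apart across the segment, centred on it. Scan lines of equal
    declared length therefore always share the same distance axis. Raises if
    any sample falls outside the image.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("line_profile expects a 2D frame")
    if width_px < 1:
        raise ValueError("width must be >= 1 pixel")

    p0 = np.asarray(start_um, dtype=float) / pixel_size_um
    p1 = np.asarray(end_um, dtype=float) / pixel_size_um
    vec = p1 - p0
    length_px = float(np.linalg.norm(vec))
    if length_px == 0:
        raise ValueError("scan line has zero length")
    n_steps = int(np.floor(length_px)) + 1
    along = vec / length_px
    normal = np.array([-along[1], along[0]])

    s = np.arange(n_steps)[:, None]  # step index along the line
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0)[None, :]
    # sample positions: (n_steps, width_px, 2) in pixel (x, y)
    xy = p0[None, None, :] + s[..., None] * along + offsets[..., None] * normal

    ny, nx = image.shape
    if (
        xy[..., 0].min() < 0
        or xy[..., 1].min() < 0
        or xy[..., 0].max() > nx - 1
        or xy[..., 1].max() > ny - 1
    ):
        raise ValueError("scan line (including its width) leaves the image bounds")

    vals = map_coordinates(image, [xy[..., 1], xy[..., 0]], order=1, mode="nearest")
    return LineProfile(
        distances_um=np.arange(n_steps) * pixel_size_um,
        values=vals.mean(axis=1),
        width_px=width_px,
    )


def estimate_baseline(
    stack: ImageStack,
    percentile: float = 5.0,
    smooth_frames: int = 1,
    plane: int | None = None,
) -> np.ndarray:
    """Per-frame scalar background level subject to temporal drift.

    A robust low-percentile statistic of each frame (over all planes, or one
    plane if given), optionally smoothed with a moving average over
    ``smooth_frames`` frames. On a pure-background stack this returns the
    background exactly; sparse bright comets barely move a low percentile.
    """
    if stack.n_frames < 2:
        raise ValueError("baseline estimation needs at least 2 frames")
    data = stack.data if plane is None else stack.data[:, plane : plane + 1]
    base = np.percentile(
        data.reshape(stack.n_frames, -1).astype(np.float64), percentile, axis=1
    )
    if smooth_frames > 1:
        base = uniform_filter1d(base, smooth_frames, mode="nearest")
    return base


def correct_profile_drift(profile: LineProfile, baseline_value: float) -> LineProfile:
    """Subtract the frame's estimated baseline from a raw profile."""
    if not np.isfinite(baseline_value):
        raise ValueError("baseline value must be finite")
    return LineProfile(
        distances_um=profile.distances_um,
        values=profile.values - baseline_value,
        width_px=profile.width_px,
        corrected=True,
    )


def normalize_profiles(profiles: list[LineProfile]) -> list[LineProfile]:
    """Normalize co-plotted profiles by their common maximum value."""
    if not profiles:
        raise ValueError("need at least one profile")
    m = max(float(p.values.max()) for p in profiles)
    if m <= 0:
        raise ValueError("common maximum must be positive to normalize")
    return [
        LineProfile(
            distances_um=p.distances_um,
            values=p.values / m,
            width_px=p.width_px,
            corrected=p.corrected,
        )
        for p in profiles
    ]


def fraction_inside(
    image: np.ndarray, compartment_masks: np.ndarray
) -> tuple[float, float]:
    """Fraction of total image intensity inside labelled compartments.

    The inside fraction is the sum of pixel intensities within the union of
    all compartments divided by the sum over the whole image; the outside
    fraction is 1 minus the inside fraction, exactly.
    """
    image = np.asarray(image, dtype=np.float64)
    masks = np.asarray(compartment_masks)
    if masks.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    total = float(image.sum())
    if total == 0:
        raise ValueError("zero total intensity; fractions undefined")
    f_in = float(image[masks > 0].sum()) / total
    return f_in, 1.0 - f_in
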