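"""Reference-centre determination and the circular analysis region.

The orientation analysis scores comets relative to a reference centre: for
asters this is the geometric (area-weighted) centroid of a polygon outlining
the EB1-enriched focus; for fields with no aster it is a point near the
middle of the image, chosen so that the 22 µm analysis disk fits within the
image bounds. Membership of the disk is closed: a front tip at distance
exactly equal to the radius is inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .io_formats import ImageStack, PolygonROI

#: radius of the circular analysis region, µm
DEFAULT_REGION_RADIUS_UM = 22.0


@dataclass(frozen=True)
class AnalysisRegion:
    """Closed disk around the reference centre within which comets are scored."""

    center: tuple[float, float]
    radius: float = DEFAULT_REGION_RADIUS_UM

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("region radius must be positive")

    def contains(self, point: tuple[float, float]) -> bool:
        dx = point[0] - self.center[0]
        dy = point[1] - self.center[1]
        return dx * dx + dy * dy <= self.radius * self.radius


def polygon_centroid(roi: PolygonROI) -> tuple[float, float]:
    """Area-weighted centroid of a simple polygon (shoelace formulation).

    Independent of vertex winding direction and of the starting vertex.
    Raises on a degenerate (zero-area) polygon — such an outline carries no
    interior whose centre could be meaningful.
    """
    v = roi.as_array()
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area2 = cross.sum()  # twice the signed area
    if area2 == 0:
        raise ValueError("degenerate polygon: zero area")
    cx = ((x + xn) * cross).sum() / (3.0 * area2)
    cy = ((y + yn) * cross).sum() / (3.0 * area2)
    return float(cx), float(cy)


def segment_center(
    image: np.ndarray,
    threshold_quantile: float = 0.99,
    pixel_size_um: float = 1.0,
) -> PolygonROI:
    """Outline the brightest focus of a single-channel frame as a polygon.

    Thresholds the frame at the given intensity quantile, keeps the largest
    connected component, and returns its boundary contour as a polygon in µm.
    This automates the manual outlining of the EB1-enriched aster centre; the
    focus is assumed to be the brightest structure in the frame, hence the
    high default quantile.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("segment_center expects a single-channel 2D frame")
    thr = float(np.quantile(image, threshold_quantile))
    mask = image > thr
    if not mask.any():
        raise ValueError("no focus found: no pixel above the intensity threshold")

    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = int(sizes.argmax())
    component = labels == keep

    # contour of the component at the 0.5 level of its indicator image
    contours = measure.find_contours(component.astype(float), 0.5)
    contour = max(contours, key=len)
    # find_contours yields (row, col); convert to (x, y) µm and thin the
    # vertex chain so tiny pixel-step collinearities cannot degenerate it
    pts = contour[:: max(1, len(contour) // 256)]
    verts = tuple(
        (float(c * pixel_size_um), float(r * pixel_size_um)) for r, c in pts
    )
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    return PolygonROI(vertices=verts, label="focus")


def make_region(
    center: tuple[float, float],
    radius: float = DEFAULT_REGION_RADIUS_UM,
    image_bounds_um: tuple[float, float] | None = None,
) -> AnalysisRegion:
    """Construct the analysis region, optionally enforcing image containment.

    ``image_bounds_um`` is required for the no-aster mode, where the centre
    is an arbitrary mid-image point and the full disk must fall within the
    bounds of the image.
    """
    region = AnalysisRegion(center=tuple(map(float, center)), radius=float(radius))
    if image_bounds_um is not None:
        w, h = image_bounds_um
        cx, cy = region.center
        if (
            cx - radius < 0
            or cy - radius < 0
            or cx + radius > w
            or cy + radius > h
        ):
            raise ValueError(
                f"analysis region (centre {region.center}, radius {radius} um) "
                f"exceeds the image bounds {image_bounds_um}"
            )
    return region


def auto_center(
    stack: ImageStack,
    frame: int = 0,
    plane: int = 0,
    threshold_quantile: float = 0.99,
) -> tuple[float, float]:
    """Centre of the brightest focus in one frame of a stack, in µm."""
    roi = segment_center(
        stack.data[frame, plane],
        threshold_quantile=threshold_quantile,
        pixel_size_um=stack.pixel_size_um,
    )
    return polygon_centroid(roi)
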