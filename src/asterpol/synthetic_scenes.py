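"""Synthetic EB1-comet scenes with known ground truth.

This module generates the three study geometries used to exercise the
polarity analysis: a centripetal aster (plus ends grow toward the focus, the
inverted polarity of the acentrosomal aster), a centrifugal aster (the
classic centrosome-nucleated case, plus ends grow outward), and a spatially
random comet field (the no-aster null, where the fraction of comets scored
centripetal is Binomial(n, 1/2) by symmetry).

Every comet is a short segment whose front tip marks the growing plus end
and leads the motion; aster comets sit on radial lines perturbed by
wrapped-normal angular jitter, so mixtures with a known centripetal fraction
``p`` are nondegenerate. The renderer draws each comet as an anisotropic
streak brightest at the front tip and can add an EB1-enriched focus at the
aster centre, Gaussian noise, and (via :func:`apply_drift`) an additive
temporal baseline emulating photobleaching.

All randomness flows from ``SceneSpec.seed`` through named
``numpy.random.Generator`` streams; identical specs give bit-identical
output.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import CometAnnotation, ImageStack

logger = logging.getLogger(__name__)


class Geometry(str, enum.Enum):
    CENTRIPETAL_ASTER = "centripetal_aster"
    CENTRIFUGAL_ASTER = "centrifugal_aster"
    RANDOM_FIELD = "random_field"


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic comet scene.

    Defaults describe a desk-scale stand-in for a single-plane confocal view
    of an aster: a 60×60 µm field whose centre carries the focus, 0.22 µm
    pixels, 5 s between frames and a 150 s movie. Comet length and speed are
    plausible for EB1 comets on growing microtubules in egg extract
    (~2 µm comets, ~0.25 µm/s growth); neither is a measured quantity here,
    both are configurable.
    """

    geometry: Geometry | str = Geometry.RANDOM_FIELD
    n_comets: int = 100
    center: tuple[float, float] = (30.0, 30.0)
    mixing_fraction_p: float = 0.5
    comet_length_um: float = 2.0
    speed_um_s: float = 0.25
    frame_interval_s: float = 5.0
    n_frames: int = 30
    field_size_um: tuple[float, float] = (60.0, 60.0)
    noise_sd: float = 2.0
    background: float = 10.0
    comet_amplitude: float = 120.0
    focus_amplitude: float = 400.0
    focus_sigma_um: float = 1.5
    jitter_sd_deg: float = 10.0
    min_radius_um: float = 2.0
    max_radius_um: float = 20.0
    pixel_size_um: float = 0.22
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "geometry", Geometry(self.geometry))
        if not 0.0 <= self.mixing_fraction_p <= 1.0:
            raise ValueError("mixing_fraction_p must lie in [0, 1]")
        if self.comet_length_um <= 0:
            raise ValueError("comet_length_um must be positive (degenerate comet)")
        if self.n_comets < 0:
            raise ValueError("n_comets must be non-negative")
        w, h = self.field_size_um
        cx, cy = self.center
        if min(cx, cy, w - cx, h - cy) < 22.0:
            raise ValueError(
                "field must contain a 22 um-radius analysis disk around the centre"
            )

    def rng(self, stream: int) -> np.random.Generator:
        """Named random stream derived from the scene seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


class DriftKind(str, enum.Enum):
    NONE = "none"
    CONSTANT_OFFSET = "constant_offset"
    EXPONENTIAL_DECAY = "exponential_decay"


@dataclass(frozen=True)
class DriftModel:
    """Additive temporal baseline b(t) applied uniformly to each frame.

    ``exponential_decay`` uses b(t) = amplitude * exp(-rate * t) with t in
    frames, the usual first-order photobleaching form.
    """

    kind: DriftKind | str = DriftKind.NONE
    offset: float = 0.0
    amplitude: float = 0.0
    rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", DriftKind(self.kind))
        for name in ("offset", "amplitude", "rate"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.kind == DriftKind.CONSTANT_OFFSET and self.offset < 0:
            raise ValueError("baseline offset must be non-negative")
        if self.kind == DriftKind.EXPONENTIAL_DECAY and self.amplitude < 0:
            raise ValueError("baseline amplitude must be non-negative")

    def baseline(self, frames: np.ndarray | int) -> np.ndarray:
        """Baseline value per frame index."""
        t = np.asarray(frames, dtype=float)
        if self.kind == DriftKind.NONE:
            return np.zeros_like(t)
        if self.kind == DriftKind.CONSTANT_OFFSET:
            return np.full_like(t, float(self.offset))
        return self.amplitude * np.exp(-self.rate * t)


@dataclass
class GroundTruth:
    """Per-comet truth recorded at generation time."""

    tracks: list  # list[Track]; typed loosely to avoid an import cycle at runtime
    orientation_class: dict[int, str]
    center_class: dict[int, str]


def _unit(theta: np.ndarray) -> np.ndarray:
    return np.stack([np.cos(theta), np.sin(theta)], axis=-1)


def make_comet_field(spec: SceneSpec) -> tuple[list[CometAnnotation], GroundTruth]:
    """Draw comet positions, orientations and motion for one scene.

    Returns the per-frame annotations together with ground truth: one track
    per comet (front-tip position per frame), its true orientation class
    (centripetal iff the plus end grows toward the scene centre), and its
    true centre-interaction class under the 10 µm capture radius.
    """
    from .comet_tracking import Track  # local import: tracking also imports types

    if spec.n_comets == 0:
        return [], GroundTruth([], {}, {})

    rng = spec.rng(1)
    n = spec.n_comets
    cx, cy = spec.center
    w, h = spec.field_size_um

    if spec.geometry == Geometry.RANDOM_FIELD:
        front0 = rng.uniform([0.0, 0.0], [w, h], size=(n, 2))
        motion_angle = rng.uniform(0.0, 2.0 * np.pi, size=n)
        u = _unit(motion_angle)
    else:
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        r = rng.uniform(spec.min_radius_um, spec.max_radius_um, size=n)
        front0 = np.stack([cx + r * np.cos(phi), cy + r * np.sin(phi)], axis=1)
        inward = rng.random(n) < spec.mixing_fraction_p
        if spec.geometry == Geometry.CENTRIFUGAL_ASTER:
            inward = ~inward  # mirror case: fraction p points outward
        jitter = np.deg2rad(rng.normal(0.0, spec.jitter_sd_deg, size=n))
        base = np.where(inward, phi + np.pi, phi)  # toward vs away from centre
        u = _unit(base + jitter)

    step = spec.speed_um_s * spec.frame_interval_s
    annotations: list[CometAnnotation] = []
    tracks: list[Track] = []
    orientation: dict[int, str] = {}
    center_cls: dict[int, str] = {}
    center = np.array([cx, cy])

    for i in range(n):
        pts = []
        for t in range(spec.n_frames):
            front = front0[i] + u[i] * step * t
            rear = front - u[i] * spec.comet_length_um
            annotations.append(
                CometAnnotation(
                    comet_id=i,
                    frame=t,
                    front_tip=(float(front[0]), float(front[1])),
                    rear_tip=(float(rear[0]), float(rear[1])),
                )
            )
            pts.append((t, (float(front[0]), float(front[1]))))
        tracks.append(Track(track_id=i, points=pts))

        # true orientation: the unsigned angle between the growth direction u
        # and the radial direction (front tip - centre) at the first frame
        radial = front0[i] - center
        if np.allclose(radial, 0.0):
            orientation[i] = "centripetal"  # at the focus itself; measure-zero
        else:
            cosang = float(np.dot(u[i], radial) / np.linalg.norm(radial))
            orientation[i] = "centripetal" if cosang < 0.0 else "centrifugal"

        d_first = float(np.linalg.norm(front0[i] - center))
        d_last = float(np.linalg.norm(np.asarray(pts[-1][1]) - center))
        if d_last <= 10.0 and d_last < d_first:
            center_cls[i] = "incoming_terminating"
        elif d_first <= 10.0 and d_last > d_first:
            center_cls[i] = "outgoing"
        else:
            center_cls[i] = "other"

    return annotations, GroundTruth(tracks, orientation, center_cls)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_STREAK_SIGMA_UM = 0.35  # width of the rendered comet streak


def _splat(canvas: np.ndarray, x_px: float, y_px: float, weight: float) -> None:
    """Deposit a point mass with bilinear weights."""
    ny, nx = canvas.shape
    x0, y0 = int(np.floor(x_px)), int(np.floor(y_px))
    fx, fy = x_px - x0, y_px - y0
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            xi, yi = x0 + dx, y0 + dy
            if 0 <= xi < nx and 0 <= yi < ny:
                canvas[yi, xi] += weight * wx * wy


def render_scene(
    annotations: Sequence[CometAnnotation], spec: SceneSpec
) -> ImageStack:
    """Rasterize comet annotations into a noisy T×1×Y×X image stack.

    Each comet becomes a streak of Gaussian-blurred mass whose density ramps
    up toward, and peaks at, the front tip. Aster geometries additionally get
    a bright Gaussian focus at the scene centre (the EB1-enriched aster
    centre). Comets with either tip outside the field are skipped with a
    logged warning. With ``noise_sd=0`` the output is deterministic.
    """
    ps = spec.pixel_size_um
    w, h = spec.field_size_um
    nx, ny = int(round(w / ps)), int(round(h / ps))
    sigma_px = _STREAK_SIGMA_UM / ps

    by_frame: dict[int, list[CometAnnotation]] = {}
    for a in annotations:
        by_frame.setdefault(a.frame, []).append(a)
    n_frames = max(by_frame, default=spec.n_frames - 1) + 1

    noise_rng = spec.rng(2)
    frames = np.empty((n_frames, 1, ny, nx), dtype=np.float64)
    yy, xx = np.mgrid[0:ny, 0:nx]

    focus = 0.0
    if spec.geometry != Geometry.RANDOM_FIELD and spec.focus_amplitude > 0:
        cx_px, cy_px = spec.center[0] / ps, spec.center[1] / ps
        s = spec.focus_sigma_um / ps
        focus = spec.focus_amplitude * np.exp(
            -((xx - cx_px) ** 2 + (yy - cy_px) ** 2) / (2.0 * s * s)
        )

    for t in range(n_frames):
        canvas = np.zeros((ny, nx), dtype=np.float64)
        for a in by_frame.get(t, []):
            tips = np.array([a.front_tip, a.rear_tip])
            if np.any(tips < 0) or np.any(tips[:, 0] > w) or np.any(tips[:, 1] > h):
                logger.warning(
                    "comet %d frame %d outside field, skipped", a.comet_id, a.frame
                )
                continue
            front = np.asarray(a.front_tip) / ps
            rear = np.asarray(a.rear_tip) / ps
            length_px = float(np.linalg.norm(front - rear))
            n_samples = max(3, int(np.ceil(length_px)) + 1)
            s_vals = np.linspace(0.0, 1.0, n_samples)  # 0 = rear, 1 = front
            for s_val in s_vals:
                pos = rear + (front - rear) * s_val
                wgt = 0.15 + 0.85 * s_val**2
                if s_val == 1.0:
                    wgt = 2.5  # bright comet head dominates the streak
                _splat(canvas, pos[0], pos[1], wgt)
        # scale so an isolated comet head peaks near comet_amplitude:
        # a unit splat smoothed by a Gaussian peaks at 1 / (2 pi sigma^2)
        scale = spec.comet_amplitude * 2.0 * np.pi * sigma_px**2 / 2.5
        img = gaussian_filter(canvas, sigma_px) * scale
        img += spec.background + focus
        if spec.noise_sd > 0:
            img = img + noise_rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames[t, 0] = img

    return ImageStack(
        data=frames,
        pixel_size_um=ps,
        frame_interval_s=spec.frame_interval_s,
        z_step_um=1.0,
    )


# ---------------------------------------------------------------------------
# compartment fixtures
# ---------------------------------------------------------------------------


def disk_compartment_masks(
    shape: tuple[int, int] = (128, 128),
    centers: Sequence[tuple[int, int]] = ((36, 36), (36, 92), (92, 64)),
    radius: int = 22,
) -> np.ndarray:
    """A simple label mask of disk-shaped cell-like compartments."""
    from skimage.draw import disk

    masks = np.zeros(shape, dtype=np.int32)
    for lbl, (r0, c0) in enumerate(centers, start=1):
        rr, cc = disk((r0, c0), radius, shape=shape)
        masks[rr, cc] = lbl
    return masks


def make_compartment_image(
    fraction_inside: float,
    masks: np.ndarray,
    total_intensity: float = 1.0e6,
) -> tuple[np.ndarray, np.ndarray]:
    """Build an image whose in-compartment signal fraction is exact.

    The requested fraction of ``total_intensity`` is spread uniformly over
    the pixels inside the union of labelled compartments and the remainder
    uniformly outside, so the measured fraction equals ``fraction_inside``
    to machine precision before any noise is added.
    """
    if not 0.0 <= fraction_inside <= 1.0:
        raise ValueError("fraction_inside must lie in [0, 1]")
    masks = np.asarray(masks)
    inside = masks > 0
    n_in = int(inside.sum())
    n_out = int(inside.size - n_in)
    if n_in == 0 and fraction_inside > 0:
        raise ValueError("empty compartment mask cannot hold signal")
    if n_out == 0 and fraction_inside < 1:
        raise ValueError("mask covers the whole image; no outside pixels")

    image = np.zeros(masks.shape, dtype=np.float64)
    if n_in:
        image[inside] = fraction_inside * total_intensity / n_in
    if n_out:
        image[~inside] = (1.0 - fraction_inside) * total_intensity / n_out
    return image, masks


def apply_drift(stack: ImageStack, model: DriftModel) -> ImageStack:
    """Shift every pixel of frame t by the model baseline b(t)."""
    b = model.baseline(np.arange(stack.n_frames))
    data = stack.data.astype(np.float64, copy=True)
    data += b[:, np.newaxis, np.newaxis, np.newaxis]
    return replace_stack(stack, data)


def replace_stack(stack: ImageStack, data: np.ndarray) -> ImageStack:
    return ImageStack(
        data=data,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        z_step_um=stack.z_step_um,
    )
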