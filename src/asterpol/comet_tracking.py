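"""Comet detection, frame-to-frame linking, and track direction statistics.

Detection finds local intensity maxima (comet heads) above a quantile
threshold and attaches an orientation axis from local intensity second
moments; head/tail polarity is resolved later from motion, since a single
frame cannot distinguish them. Linking is a deterministic greedy
nearest-neighbour pass between consecutive frames with a hard displacement
cap and no gap closing — deliberately simple, with an exhaustive minimal
total-distance matching available as a small-case oracle in the tests.

A track's average direction is the circular mean of its segment angles
(resultant of the segment unit vectors); tracks are classed by how they
interact with the aster centre: ``incoming_terminating`` if they end inside
the capture radius having moved net inward, ``outgoing`` if they start
inside it and move net outward, otherwise ``other``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from matplotlib import colormaps
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

INCOMING = "incoming_terminating"
OUTGOING = "outgoing"
OTHER = "other"


@dataclass(frozen=True)
class Detection:
    """One comet candidate in one frame: position (µm) + orientation axis."""

    position: tuple[float, float]
    axis_deg: float  # orientation axis in [0, 180); head/tail unresolved
    intensity: float = 0.0


@dataclass
class Track:
    """Linked comet positions across frames."""

    track_id: int
    points: list[tuple[int, tuple[float, float]]]
    center_class: str | None = None

    def __post_init__(self) -> None:
        frames = [f for f, _ in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def positions(self) -> np.ndarray:
        return np.array([p for _, p in self.points], dtype=float)


@dataclass(frozen=True)
class TrackClassifierParams:
    """Centre-interaction rule parameters.

    ``capture_radius_um`` is the distance from the aster centre within which
    a track may be said to terminate at or emanate from the centre;
    ``time_window_s`` is the observation window over which tracks are
    counted.
    """

    center: tuple[float, float]
    capture_radius_um: float = 10.0
    time_window_s: float = 180.0

    def __post_init__(self) -> None:
        if self.capture_radius_um <= 0:
            raise ValueError("capture_radius_um must be positive")
        if self.time_window_s <= 0:
            raise ValueError("time_window_s must be positive")


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_comets(
    frame: np.ndarray,
    pixel_size_um: float,
    min_intensity_quantile: float = 0.995,
    min_separation_um: float = 1.5,
    smooth_sigma_um: float = 0.15,
) -> list[Detection]:
    """Comet-head candidates in one single-channel frame.

    Local maxima of the lightly smoothed frame above the intensity quantile,
    separated by at least ``min_separation_um``. The orientation axis of each
    detection comes from the second moments of the background-subtracted
    intensity in a small window around the peak.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("detect_comets expects a 2D frame")
    if frame.max() == frame.min():
        return []
    smoothed = gaussian_filter(frame, smooth_sigma_um / pixel_size_um)
    # threshold: the intensity quantile, but never below the noise floor
    # (median + 6 robust SDs) so near-empty noisy frames yield no peaks
    med = float(np.median(smoothed))
    mad = float(np.median(np.abs(smoothed - med)))
    thr = max(
        float(np.quantile(smoothed, min_intensity_quantile)),
        med + 6.0 * 1.4826 * mad,
    )
    min_dist = max(1, int(round(min_separation_um / pixel_size_um)))
    peaks = peak_local_max(
        smoothed, min_distance=min_dist, threshold_abs=thr, exclude_border=False
    )
    bg = float(np.median(smoothed))
    win = max(2, int(round(1.5 / pixel_size_um)))  # ~1.5 µm moment window
    out = []
    for r, c in peaks:
        axis = _moment_axis(smoothed, int(r), int(c), win, bg)
        out.append(
            Detection(
                position=(c * pixel_size_um, r * pixel_size_um),
                axis_deg=axis,
                intensity=float(smoothed[r, c]),
            )
        )
    # canonical order: by position, so detection order never affects linking
    out.sort(key=lambda d: d.position)
    return out


def _moment_axis(img: np.ndarray, r: int, c: int, win: int, bg: float) -> float:
    ny, nx = img.shape
    r0, r1 = max(0, r - win), min(ny, r + win + 1)
    c0, c1 = max(0, c - win), min(nx, c + win + 1)
    patch = np.clip(img[r0:r1, c0:c1] - bg, 0.0, None)
    total = patch.sum()
    if total == 0:
        return 0.0
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mx = (patch * xx).sum() / total
    my = (patch * yy).sum() / total
    mxx = (patch * (xx - mx) ** 2).sum() / total
    myy = (patch * (yy - my) ** 2).sum() / total
    mxy = (patch * (xx - mx) * (yy - my)).sum() / total
    ang = 0.5 * math.atan2(2.0 * mxy, mxx - myy)
    return math.degrees(ang) % 180.0


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------


def link_tracks(
    detections_by_frame: Sequence[Sequence[Detection]],
    max_displacement_um: float,
) -> list[Track]:
    """Greedy nearest-neighbour linking of detections across frames.

    Candidate pairs between consecutive frames are sorted by distance (ties
    broken by the canonical position order) and matched one-to-one; links
    longer than ``max_displacement_um`` are forbidden. Unmatched detections
    start new tracks. No gap closing: a comet missed in one frame ends its
    track.
    """
    if max_displacement_um <= 0:
        raise ValueError("max_displacement_um must be positive")

    open_tracks: dict[int, list[tuple[int, tuple[float, float]]]] = {}
    track_of_det: dict[int, int] = {}  # index in current frame -> track id
    next_id = 0
    finished: list[Track] = []

    prev: list[Detection] = []
    for t, dets in enumerate(detections_by_frame):
        dets = sorted(dets, key=lambda d: d.position)
        new_track_of_det: dict[int, int] = {}
        if prev:
            pairs = []
            for i, dp in enumerate(prev):
                for j, dn in enumerate(dets):
                    dist = math.dist(dp.position, dn.position)
                    if dist <= max_displacement_um:
                        pairs.append((dist, i, j))
            pairs.sort()
            used_prev: set[int] = set()
            used_next: set[int] = set()
            for dist, i, j in pairs:
                if i in used_prev or j in used_next:
                    continue
                used_prev.add(i)
                used_next.add(j)
                tid = track_of_det[i]
                open_tracks[tid].append((t, dets[j].position))
                new_track_of_det[j] = tid
            # tracks whose comet found no continuation are closed
            for i in range(len(prev)):
                if i not in used_prev:
                    tid = track_of_det[i]
                    finished.append(Track(track_id=tid, points=open_tracks.pop(tid)))
        for j, d in enumerate(dets):
            if j not in new_track_of_det:
                open_tracks[next_id] = [(t, d.position)]
                new_track_of_det[j] = next_id
                next_id += 1
        track_of_det = new_track_of_det
        prev = dets

    for tid, pts in open_tracks.items():
        finished.append(Track(track_id=tid, points=pts))
    finished.sort(key=lambda tr: tr.track_id)
    return finished


# ---------------------------------------------------------------------------
# direction statistics
# ---------------------------------------------------------------------------


def average_direction(track: Track) -> float | None:
    """Circular mean of the track's segment angles, degrees in [0, 360).

    Each frame-to-frame segment contributes a unit vector; the direction is
    the angle of their resultant. Zero-length segments are skipped; if every
    segment is zero-length, or the resultant vanishes exactly, the direction
    is undefined and None is returned.
    """
    pos = track.positions()
    if len(pos) < 2:
        raise ValueError("a direction needs at least 2 track points")
    seg = np.diff(pos, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    seg = seg[norms > 0]
    if len(seg) == 0:
        return None
    units = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    resultant = units.sum(axis=0)
    if np.allclose(resultant, 0.0):
        return None
    return float(math.degrees(math.atan2(resultant[1], resultant[0])) % 360.0)


def direction_color(angle_deg: float) -> tuple[float, float, float]:
    """RGB colour for a direction on the periodic HSV colour wheel.

    The mapping is periodic (0° and 360° coincide) and injective on
    [0°, 360°): every direction gets a unique hue.
    """
    cmap = colormaps["hsv"]
    r, g, b, _ = cmap((angle_deg % 360.0) / 360.0)
    return (float(r), float(g), float(b))


def classify_track(track: Track, params: TrackClassifierParams) -> str:
    """Centre-interaction class of one track.

    ``incoming_terminating``: the track ends within the capture radius of
    the centre and its net displacement is toward the centre (final distance
    smaller than initial). ``outgoing``: it starts within the capture radius
    and moves net outward. Anything else is ``other``.
    """
    pos = track.positions()
    if len(pos) < 2:
        return OTHER
    c = np.asarray(params.center, dtype=float)
    d_first = float(np.linalg.norm(pos[0] - c))
    d_last = float(np.linalg.norm(pos[-1] - c))
    if d_last <= params.capture_radius_um and d_last < d_first:
        return INCOMING
    if d_first <= params.capture_radius_um and d_last > d_first:
        return OUTGOING
    return OTHER


def terminate_emanate_fractions(
    tracks: Sequence[Track], params: TrackClassifierParams
) -> tuple[float, float]:
    """Fractions of classifiable tracks terminating at vs emanating from centre.

    Tracks classed ``other`` are excluded from the denominator, so the two
    fractions sum to 1 exactly.
    """
    n_in = n_out = 0
    for tr in tracks:
        cls = classify_track(tr, params)
        tr.center_class = cls
        if cls == INCOMING:
            n_in += 1
        elif cls == OUTGOING:
            n_out += 1
    total = n_in + n_out
    if total == 0:
        raise ValueError("no tracks terminate at or emanate from the centre")
    return n_in / total, n_out / total
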