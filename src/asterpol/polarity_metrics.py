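"""The comet-orientation angle metric θ and its summaries.

For each EB1 comet, two vectors are formed: the *comet vector* from the rear
tip to the front tip (the direction of plus-end growth) and the *radial
vector* from the reference centre to the front tip. θ is the unsigned angle
between the two, obtained by applying the law of cosines to the triangle
they span, so θ ∈ [0°, 180°]. A comet with θ > 90° grows toward the centre
(centripetal, "incoming"); θ ≤ 90° grows away (centrifugal, "outgoing") —
the tie at exactly 90° is scored centrifugal.

Only comets whose front tip falls inside the closed 22 µm analysis disk are
scored. Summaries report the centripetal percentage (full precision
internally, rounded to the nearest integer for display), an angular
histogram over [0°, 180°], and across replicates the mean percentage with
its standard error (sample SD with the n−1 denominator over √n).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .center_detection import AnalysisRegion
from .io_formats import CometAnnotation

logger = logging.getLogger(__name__)

CENTRIPETAL = "centripetal"
CENTRIFUGAL = "centrifugal"


@dataclass(frozen=True)
class AngleMeasurement:
    """θ and orientation class for one comet."""

    comet_id: int
    theta_deg: float
    orientation_class: str
    distance_to_center_um: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_deg <= 180.0:
            raise ValueError("theta must lie in [0, 180] degrees")
        expected = CENTRIPETAL if self.theta_deg > 90.0 else CENTRIFUGAL
        if self.orientation_class != expected:
            raise ValueError("orientation_class inconsistent with theta")


@dataclass
class OrientationSummary:
    """Counts, percentages and the angular histogram for one set of comets."""

    n_comets: int
    n_centripetal: int
    percent_centripetal: float
    bin_edges_deg: np.ndarray
    histogram: np.ndarray
    per_replicate_percents: list[float] = field(default_factory=list)
    mean_percent: float | None = None
    sem_percent: float | None = None

    @property
    def percent_centripetal_display(self) -> int:
        """Centripetal percentage rounded to the nearest integer for reports."""
        return int(round(self.percent_centripetal))

    @property
    def percent_centrifugal_display(self) -> int:
        return int(round(100.0 - self.percent_centripetal))


def comet_vector(a: CometAnnotation) -> np.ndarray:
    """Vector from the comet rear tip to the front tip (µm)."""
    return np.asarray(a.front_tip, dtype=float) - np.asarray(a.rear_tip, dtype=float)


def radial_vector(center: tuple[float, float], a: CometAnnotation) -> np.ndarray | None:
    """Vector from the reference centre to the comet front tip (µm).

    Returns None when the front tip coincides with the centre — θ is
    undefined there and the comet is excluded from analysis.
    """
    v = np.asarray(a.front_tip, dtype=float) - np.asarray(center, dtype=float)
    if v[0] == 0.0 and v[1] == 0.0:
        logger.warning(
            "comet %d frame %d: front tip at the reference centre, excluded",
            a.comet_id,
            a.frame,
        )
        return None
    return v


def theta(comet_vec: np.ndarray, radial_vec: np.ndarray) -> float:
    """Unsigned angle in degrees between the comet and radial vectors.

    The angle of the triangle the two vectors span, via the law of cosines
    on the unit-vector triangle: with û, v̂ the normalized vectors, the chord
    opposite θ has |û − v̂|² = 2 − 2 cos θ and the complementary chord
    |û + v̂|² = 2 + 2 cos θ, so θ = 2·atan2(|û − v̂|, |û + v̂|). This evaluates
    the same cosine relation without the ill-conditioned arccosine near
    θ = 0°/180°, and is exact at both bounds: antiparallel input returns
    exactly 180.0.
    """
    u = np.asarray(comet_vec, dtype=float)
    v = np.asarray(radial_vec, dtype=float)
    nu = math.hypot(u[0], u[1])
    nv = math.hypot(v[0], v[1])
    if nu == 0.0 or nv == 0.0:
        raise ValueError("theta is undefined for a zero-length vector")
    un = u / nu
    vn = v / nv
    chord_opp = math.hypot(un[0] - vn[0], un[1] - vn[1])
    chord_adj = math.hypot(un[0] + vn[0], un[1] + vn[1])
    return math.degrees(2.0 * math.atan2(chord_opp, chord_adj))


def classify(theta_deg: float) -> str:
    """Orientation class from θ: centripetal iff θ > 90° (tie → centrifugal)."""
    if not 0.0 <= theta_deg <= 180.0:
        raise ValueError(f"theta {theta_deg} outside [0, 180]")
    return CENTRIPETAL if theta_deg > 90.0 else CENTRIFUGAL


def filter_region(
    annotations: Iterable[CometAnnotation], region: AnalysisRegion
) -> list[CometAnnotation]:
    """Comets whose front tip lies within the closed analysis disk.

    Only the front tip governs membership; the rear tip may lie outside.
    """
    return [a for a in annotations if region.contains(a.front_tip)]


def measure_orientations(
    annotations: Iterable[CometAnnotation],
    region: AnalysisRegion,
    frame: int | None = 0,
) -> list[AngleMeasurement]:
    """θ per comet for all in-region comets of one frame.

    The analysis scores one still frame (``frame=0`` by default); pass
    ``frame=None`` to aggregate over all frames, an explicitly multi-frame
    variant.
    """
    out: list[AngleMeasurement] = []
    for a in annotations:
        if frame is not None and a.frame != frame:
            continue
        if not region.contains(a.front_tip):
            continue
        rad = radial_vector(region.center, a)
        if rad is None:
            continue
        t = theta(comet_vector(a), rad)
        out.append(
            AngleMeasurement(
                comet_id=a.comet_id,
                theta_deg=t,
                orientation_class=classify(t),
                distance_to_center_um=float(np.hypot(*rad)),
            )
        )
    return out


def summarize(
    measurements: Sequence[AngleMeasurement], bin_width_deg: float = 10.0
) -> OrientationSummary:
    """Counts, centripetal percentage and the angular histogram.

    The histogram covers [0°, 180°] with the stated bin width (last bin
    closed so θ = 180° is counted). Percentages are kept at full precision;
    use the ``*_display`` properties for the integer-rounded report values.
    """
    if not measurements:
        raise ValueError("cannot summarize an empty measurement set")
    thetas = np.array([m.theta_deg for m in measurements])
    n = len(measurements)
    n_in = sum(1 for m in measurements if m.orientation_class == CENTRIPETAL)
    n_bins = int(round(180.0 / bin_width_deg))
    if not np.isclose(n_bins * bin_width_deg, 180.0):
        raise ValueError("bin width must divide 180 degrees evenly")
    hist, edges = np.histogram(thetas, bins=n_bins, range=(0.0, 180.0))
    return OrientationSummary(
        n_comets=n,
        n_centripetal=n_in,
        percent_centripetal=100.0 * n_in / n,
        bin_edges_deg=edges,
        histogram=hist,
    )


def summarize_counts(n_centripetal: int, n_comets: int) -> OrientationSummary:
    """Summary from bare counts (no angular histogram)."""
    if n_comets <= 0 or n_centripetal < 0 or n_centripetal > n_comets:
        raise ValueError("invalid counts")
    edges = np.linspace(0.0, 180.0, 19)
    return OrientationSummary(
        n_comets=n_comets,
        n_centripetal=n_centripetal,
        percent_centripetal=100.0 * n_centripetal / n_comets,
        bin_edges_deg=edges,
        histogram=np.zeros(18, dtype=int),
    )


def replicate_stats(
    per_replicate_percents: Sequence[float],
) -> tuple[float, float | None]:
    """Mean and s.e.m. of per-replicate percentages.

    s.e.m. uses the sample standard deviation (n−1 denominator) divided by
    √n. With a single replicate the s.e.m. is undefined and returned as None.
    """
    p = np.asarray(per_replicate_percents, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one replicate")
    mean = float(p.mean())
    if p.size == 1:
        return mean, None
    sem = float(p.std(ddof=1) / math.sqrt(p.size))
    return mean, sem
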