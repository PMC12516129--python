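"""Readers and writers for image stacks, comet annotations, ROIs, and tracks.

All on-disk positions are physical coordinates in micrometres unless a file
declares pixel units, in which case they are converted on read using the
pixel-size calibration. The in-memory convention throughout the package is:
continuous 2D positions in µm, origin at the centre of the top-left pixel,
x increasing rightward (columns), y increasing downward (rows). Frames are
indexed from 0.

Formats:
    images       multi-page TIFF + sidecar JSON metadata (``<stem>.json``)
    annotations  CSV, schema v1 (see ANNOTATION_COLUMNS)
    tracks       CSV, one row per (track, frame)
    ROIs         JSON list of labelled vertex polygons
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

logger = logging.getLogger(__name__)

#: columns of the v1 comet-annotation CSV dialect
ANNOTATION_COLUMNS = (
    "comet_id",
    "frame",
    "front_x",
    "front_y",
    "rear_x",
    "rear_y",
    "units",
)

TRACK_COLUMNS = ("track_id", "frame", "x_um", "y_um")

#: metadata fields the TIFF sidecar must provide
REQUIRED_METADATA = ("pixel_size_um", "frame_interval_s", "z_step_um")


class FormatError(ValueError):
    """Raised when an input file violates its documented schema."""


@dataclass
class ImageStack:
    """A T×Z×Y×X fluorescence stack with physical calibration.

    Attributes
    ----------
    data : ndarray, shape (T, Z, Y, X)
        Intensities; any numeric dtype, all values finite.
    pixel_size_um : float
        Lateral calibration, µm per pixel.
    frame_interval_s : float
        Time between consecutive frames, seconds.
    z_step_um : float
        Spacing between confocal planes, µm.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack must be 4-dimensional (T, Z, Y, X); got shape {self.data.shape}"
            )
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all stack dimensions must be >= 1; got {self.data.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.data.astype(np.float64, copy=False))):
            raise ValueError("stack intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, seconds from the first frame."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def field_size_um(self) -> tuple[float, float]:
        """(width, height) of the imaged field in µm."""
        t, z, ny, nx = self.data.shape
        return nx * self.pixel_size_um, ny * self.pixel_size_um


@dataclass(frozen=True)
class CometAnnotation:
    """Front/rear tip positions of one EB1 comet in one frame (µm).

    The front tip marks the growing microtubule plus end; the rear tip points
    back toward the minus end. The two tips must differ, otherwise the comet
    vector is undefined.
    """

    comet_id: int
    frame: int
    front_tip: tuple[float, float]
    rear_tip: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.front_tip) == tuple(self.rear_tip):
            raise ValueError(
                f"comet {self.comet_id} frame {self.frame}: "
                "front tip equals rear tip, comet vector undefined"
            )


@dataclass(frozen=True)
class PolygonROI:
    """A simple polygon region of interest with vertices in µm."""

    vertices: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        arr = np.asarray(verts)
        x, y = arr[:, 0], arr[:, 1]
        shoelace = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
        if shoelace == 0:
            raise ValueError(f"polygon {self.label!r} has zero area")
        if not _ShapelyPolygon(verts).is_valid:
            raise ValueError(f"polygon {self.label!r} is self-intersecting")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, metadata=None, photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "z_step_um": stack.z_step_um,
        "shape_tzyx": list(stack.data.shape),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF stack written by :func:`write_stack`.

    Raises
    ------
    FormatError
        If the sidecar metadata file is missing or lacks required fields.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(
            f"missing metadata sidecar {sidecar.name}: required fields "
            f"{', '.join(REQUIRED_METADATA)}"
        )
    meta = json.loads(sidecar.read_text())
    missing = [k for k in REQUIRED_METADATA if k not in meta]
    if missing:
        raise FormatError(f"sidecar {sidecar.name} missing fields: {', '.join(missing)}")
    data = tifffile.imread(path)
    if not np.issubdtype(np.asarray(data).dtype, np.number):
        raise FormatError(f"{path.name}: non-numeric pixel data")
    if "shape_tzyx" in meta:
        data = np.asarray(data).reshape(meta["shape_tzyx"])
    else:
        data = np.atleast_2d(np.asarray(data))
        while data.ndim < 4:
            data = data[np.newaxis]
    return ImageStack(
        data=data,
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        z_step_um=float(meta["z_step_um"]),
    )


# ---------------------------------------------------------------------------
# comet annotations
# ---------------------------------------------------------------------------


def write_annotations(
    annotations: Sequence[CometAnnotation],
    path: str | Path,
    extra: dict[int, str] | None = None,
) -> None:
    """Write annotations as a v1 CSV (µm units).

    ``extra`` optionally maps comet_id to a ``true_class`` string column,
    used by the synthetic generator to record ground truth.
    """
    rows = []
    for a in annotations:
        row = {
            "comet_id": a.comet_id,
            "frame": a.frame,
            "front_x": a.front_tip[0],
            "front_y": a.front_tip[1],
            "rear_x": a.rear_tip[0],
            "rear_y": a.rear_tip[1],
            "units": "um",
        }
        if extra is not None:
            row["true_class"] = extra.get(a.comet_id, "")
        rows.append(row)
    cols = list(ANNOTATION_COLUMNS) + (["true_class"] if extra is not None else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_annotations(
    path: str | Path, pixel_size_um: float | None = None
) -> list[CometAnnotation]:
    """Read comet annotations from a v1 CSV.

    Rows declaring pixel units are converted to µm via ``pixel_size_um``;
    rows whose front and rear tips coincide are rejected with a logged
    warning (the comet vector is undefined for them).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surfaces parser context
        raise FormatError(f"{path.name}: unreadable annotation CSV ({exc})") from exc
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {', '.join(missing)}")

    out: list[CometAnnotation] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        units = str(row["units"]).strip().lower()
        if units not in ("um", "px"):
            raise FormatError(f"{path.name} line {line_no}: units must be 'um' or 'px'")
        try:
            vals = [float(row[c]) for c in ("front_x", "front_y", "rear_x", "rear_y")]
            comet_id = int(row["comet_id"])
            frame = int(row["frame"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path.name} line {line_no}: malformed row ({exc})") from exc
        if units == "px":
            if pixel_size_um is None:
                raise FormatError(
                    f"{path.name} line {line_no}: pixel units require pixel_size_um"
                )
            vals = [v * pixel_size_um for v in vals]
        fx, fy, rx, ry = vals
        if (fx, fy) == (rx, ry):
            logger.warning(
                "%s line %d: front tip equals rear tip, row rejected", path.name, line_no
            )
            continue
        out.append(CometAnnotation(comet_id, frame, (fx, fy), (rx, ry)))
    return out


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def write_tracks(tracks: Sequence["TrackLike"], path: str | Path) -> None:
    """Write tracks as CSV, one row per point."""
    rows = [
        {"track_id": t.track_id, "frame": f, "x_um": x, "y_um": y}
        for t in tracks
        for f, (x, y) in t.points
    ]
    pd.DataFrame(rows, columns=list(TRACK_COLUMNS)).to_csv(path, index=False)


def read_tracks(path: str | Path) -> list["TrackLike"]:
    """Read tracks written by :func:`write_tracks`."""
    from .comet_tracking import Track  # deferred: avoids an import cycle

    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {', '.join(missing)}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        pts = [(int(r.frame), (float(r.x_um), float(r.y_um))) for r in grp.itertuples()]
        tracks.append(Track(track_id=int(tid), points=pts))
    return tracks


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------


def write_rois(rois: Sequence[PolygonROI], path: str | Path) -> None:
    payload = [{"label": r.label, "vertices": [list(v) for v in r.vertices]} for r in rois]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois(path: str | Path) -> list[PolygonROI]:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path.name}: invalid JSON ({exc})") from exc
    if not isinstance(payload, list):
        raise FormatError(f"{path.name}: expected a JSON list of ROIs")
    return [
        PolygonROI(
            vertices=tuple((float(x), float(y)) for x, y in item["vertices"]),
            label=str(item.get("label", "")),
        )
        for item in payload
    ]


class TrackLike:  # pragma: no cover - typing helper only
    track_id: int
    points: list[tuple[int, tuple[float, float]]]
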