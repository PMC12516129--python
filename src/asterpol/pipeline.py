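"""End-to-end orchestration: simulate → detect → track → polarity → intensity.

A :class:`RunConfig` fully determines a run; identical config + seed gives
bit-identical non-figure outputs. Each stage is timed and logged, and a
stage failure aborts the run with the stage name attached. Figures are side
effects only — no computed quantity ever depends on them.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io_formats, synthetic_scenes
from .center_detection import auto_center, make_region
from .comet_tracking import (
    TrackClassifierParams,
    detect_comets,
    link_tracks,
    terminate_emanate_fractions,
)
from .intensity_quant import fraction_inside, total_intensity_series
from .polarity_metrics import measure_orientations, replicate_stats, summarize
from .synthetic_scenes import SceneSpec, make_comet_field, render_scene

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    scene: SceneSpec = field(default_factory=SceneSpec)
    annotations_path: Path | None = None  # analyse a file instead of simulating
    center_um: tuple[float, float] | None = None
    n_replicates: int = 3
    region_radius_um: float = 22.0
    capture_radius_um: float = 10.0
    time_window_s: float = 180.0
    bin_width_deg: float = 10.0
    max_displacement_um: float = 2.5
    compartment_fraction: float = 0.82
    seed: int = 0
    output_dir: Path = Path("asterpol_run")
    render: bool = True
    figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scene = SceneSpec(**raw.pop("scene", {}))
        raw.pop("output_dir_", None)
        cfg = cls(scene=scene, **raw)
        cfg.output_dir = Path(cfg.output_dir)
        if cfg.annotations_path is not None:
            cfg.annotations_path = Path(cfg.annotations_path)
        if cfg.center_um is not None:
            cfg.center_um = tuple(cfg.center_um)
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError(name, exc) from exc
            logger.info("stage %-10s %.2f s", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis on synthetic scenes and write a report bundle.

    Returns the summary dictionary that is also written as ``summary.json``.
    Outputs: ``measurements.csv`` (per-comet θ), ``tracks.csv``,
    ``summary.json`` and, when enabled, polar-histogram / trajectory /
    profile figures.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.annotations_path is not None:
        return _run_on_annotations(config, out)

    percents: list[float] = []
    all_rows = []
    first_scene_artifacts: dict = {}

    for rep in range(config.n_replicates):
        spec = synthetic_scenes.SceneSpec(
            **{
                **asdict_scene(config.scene),
                "seed": int(config.seed) * 1000 + rep,
            }
        )
        annotations, truth = _simulate(spec)
        region_center = spec.center
        if config.render and rep == 0:
            stack = _render(annotations, spec)
            if spec.geometry != synthetic_scenes.Geometry.RANDOM_FIELD:
                region_center = _find_center(stack)
            first_scene_artifacts = _track_and_measure(
                stack, spec, truth, config, out
            )
        region = make_region(
            region_center,
            config.region_radius_um,
            image_bounds_um=spec.field_size_um,
        )
        measurements = measure_orientations(annotations, region, frame=0)
        if measurements:
            s = summarize(measurements, config.bin_width_deg)
            percents.append(s.percent_centripetal)
        for m in measurements:
            all_rows.append(
                {
                    "replicate": rep,
                    "comet_id": m.comet_id,
                    "theta_deg": m.theta_deg,
                    "orientation_class": m.orientation_class,
                    "distance_to_center_um": m.distance_to_center_um,
                    "true_class": truth.orientation_class.get(m.comet_id, ""),
                }
            )

    if not percents:
        raise StageError("polarity", ValueError("no comets inside any analysis region"))

    mean_pct, sem_pct = replicate_stats(percents)

    # compartment-fraction quantification on a constructed compartment image
    masks = synthetic_scenes.disk_compartment_masks()
    image, _ = synthetic_scenes.make_compartment_image(
        config.compartment_fraction, masks
    )
    f_in, f_out = fraction_inside(image, masks)

    summary = {
        "seed": int(config.seed),
        "geometry": str(config.scene.geometry.value),
        "n_replicates": config.n_replicates,
        "per_replicate_percent_centripetal": percents,
        "mean_percent_centripetal": mean_pct,
        "sem_percent_centripetal": sem_pct,
        "fraction_inside_compartments": f_in,
        "fraction_outside_compartments": f_out,
        **first_scene_artifacts,
    }

    import pandas as pd

    pd.DataFrame(all_rows).to_csv(out / "measurements.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    if config.figures:
        _make_figures(all_rows, config, out)
    return summary


@_stage("load")
def _load_annotations(path: Path):
    if not Path(path).exists():
        raise FileNotFoundError(f"annotations file not found: {path}")
    return io_formats.read_annotations(path)


def _run_on_annotations(config: RunConfig, out: Path) -> dict:
    annotations = _load_annotations(config.annotations_path)
    center = config.center_um or config.scene.center
    region = make_region(center, config.region_radius_um)
    measurements = measure_orientations(annotations, region, frame=0)
    if not measurements:
        raise StageError("polarity", ValueError("no comets inside the analysis region"))
    s = summarize(measurements, config.bin_width_deg)
    summary = {
        "seed": int(config.seed),
        "n_comets": s.n_comets,
        "n_centripetal": s.n_centripetal,
        "percent_centripetal": s.percent_centripetal,
        "percent_centripetal_display": s.percent_centripetal_display,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    if config.figures:
        from . import plots

        plots.polar_histogram(
            [m.theta_deg for m in measurements],
            config.bin_width_deg,
            out / "polar_histogram.png",
        )
    return summary


def asdict_scene(spec: SceneSpec) -> dict:
    d = asdict(spec)
    d["geometry"] = spec.geometry.value
    return d


@_stage("simulate")
def _simulate(spec: SceneSpec):
    return make_comet_field(spec)


@_stage("render")
def _render(annotations, spec):
    return render_scene(annotations, spec)


@_stage("center")
def _find_center(stack):
    return auto_center(stack)


@_stage("track")
def _track_and_measure(stack, spec, truth, config: RunConfig, out: Path) -> dict:
    dets = [
        detect_comets(stack.data[t, 0], stack.pixel_size_um)
        for t in range(stack.n_frames)
    ]
    tracks = link_tracks(dets, config.max_displacement_um)
    params = TrackClassifierParams(
        center=spec.center,
        capture_radius_um=config.capture_radius_um,
        time_window_s=config.time_window_s,
    )
    io_formats.write_tracks(tracks, out / "tracks.csv")
    artifacts: dict = {"n_tracks": len(tracks)}
    try:
        f_in, f_out = terminate_emanate_fractions(tracks, params)
        artifacts["fraction_incoming"] = f_in
        artifacts["fraction_outgoing"] = f_out
    except ValueError:
        artifacts["fraction_incoming"] = None
        artifacts["fraction_outgoing"] = None

    # intensity series of the rendered stack (sum-of-slices totals)
    series = total_intensity_series(stack)
    artifacts["total_intensity_first_frame"] = float(series.values[0])
    if config.figures:
        from . import plots

        plots.trajectory_figure(tracks, spec, out / "trajectories.png")
    return artifacts


def _make_figures(rows, config: RunConfig, out: Path) -> None:
    from . import plots

    thetas = [r["theta_deg"] for r in rows]
    if thetas:
        plots.polar_histogram(thetas, config.bin_width_deg, out / "polar_histogram.png")
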