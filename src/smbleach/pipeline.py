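"""End-to-end workflow: simulate -> detect -> link -> trace -> count -> correct.

Configuration is a JSON-compatible nested mapping, schema-validated before
any stage runs (unknown keys are rejected by name). Every intermediate
artifact is written as CSV/TIFF so stages can be re-run independently, and
the consolidated report is deterministic for a fixed config and seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detect import detect_movie, spot_density
from .io import MovieStack, read_movie, write_movie, write_table
from .simulate import SimulationConfig, render_movie
from .steps import aggregate_histogram, count_steps, estimate_unit_intensity, fit_steps_batch
from .stoichiometry import (
    LabelingModel,
    bootstrap_ci,
    forward_observe,
    group_fractions,
    particle_to_entity,
    receptors_per_cell,
    solve_corrected_fractions,
)
from .tracking import (
    FluorescenceTrace,
    TraceQCRules,
    extract_traces,
    flag_crowded_tracks,
    link,
    merge_stationary_tracks,
    qc_filter_traces,
)

__all__ = ["ConfigError", "RunConfig", "RunReport", "validate_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "detect", "link", "trace", "steps", "correct")


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


@dataclass
class DetectionParams:
    n_levels: int = 3
    k_sigma: float = 3.0
    detect_level: int = 2
    min_separation: float = 2.0
    half_window: int = 4
    expected_sigma: float = 1.3


@dataclass
class LinkingParams:
    max_displacement: float = 2.0
    max_gap: int = 0
    merge_radius: float = 1.5    # px; fragments of one fixed particle coincide


@dataclass
class TraceParams:
    aperture_radius: float = 3.0
    annulus_inner: float = 5.0
    annulus_outer: float = 7.0
    min_duration: int = 3
    tail_frames: int = 10


@dataclass
class StepParams:
    penalty: float | None = None            # default 2*log(n_frames)
    min_step_fraction: float = 0.5


@dataclass
class CorrectionParams:
    labeling_efficiency: float = 0.8
    n_max: int = 5
    visibility_conditioned: bool = True
    bootstrap_replicates: int = 0           # 0 disables bootstrap CIs
    cell_area: float = 1200.0               # um^2, COS-7-like surface area


@dataclass
class RunConfig:
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    input_movie: str | None = None          # path; None means simulate
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkingParams = field(default_factory=LinkingParams)
    trace: TraceParams = field(default_factory=TraceParams)
    steps: StepParams = field(default_factory=StepParams)
    correction: CorrectionParams = field(default_factory=CorrectionParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["simulation"]["true_fractions"] = list(self.simulation.true_fractions)
        d["simulation"]["image_shape"] = list(self.simulation.image_shape)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _build_section(cls, raw: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")
    coerced = dict(raw)
    if name == "simulation":
        if "true_fractions" in coerced:
            coerced["true_fractions"] = tuple(coerced["true_fractions"])
        if "image_shape" in coerced:
            coerced["image_shape"] = tuple(coerced["image_shape"])
    try:
        return cls(**coerced)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in '{name}': {exc}") from exc


def validate_config(raw) -> RunConfig:
    """Parse and validate a configuration (JSON text, path contents, or dict).

    Empty input yields the full default configuration. Out-of-range values
    raise :class:`ConfigError` naming the offending field.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, (str, bytes)):
        raw = json.loads(raw) if raw.strip() else {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a JSON object")
    sections = {
        "simulation": SimulationConfig,
        "detection": DetectionParams,
        "linking": LinkingParams,
        "trace": TraceParams,
        "steps": StepParams,
        "correction": CorrectionParams,
    }
    known_top = set(sections) | {"seed", "stages", "input_movie"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs: dict = {}
    for name, cls in sections.items():
        kwargs[name] = _build_section(cls, raw.get(name, {}), name)
    if not (0.0 < kwargs["correction"].labeling_efficiency <= 1.0):
        raise ConfigError("correction.labeling_efficiency must be in (0, 1]")
    if kwargs["simulation"].particle_density is not None and kwargs["simulation"].particle_density < 0:
        raise ConfigError("simulation.particle_density must be >= 0")
    stages = tuple(raw.get("stages", STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    return RunConfig(seed=int(raw.get("seed", 0)), stages=stages,
                     input_movie=raw.get("input_movie"), **kwargs)


@dataclass
class RunReport:
    """Consolidated per-stage counts, the observed histogram, and corrected results."""

    config_hash: str
    seed: int
    version: str
    n_particles_simulated: int = 0
    ground_truth_fractions: list = field(default_factory=list)
    realized_density: float = float("nan")
    n_detections: int = 0
    n_tracks: int = 0
    n_traces: int = 0
    n_traces_accepted: int = 0
    rejections: dict = field(default_factory=dict)
    estimated_unit_intensity: float = float("nan")
    spot_density: float = float("nan")
    receptors_per_cell: int | None = None
    observed_counts: list = field(default_factory=list)
    observed_fractions: list = field(default_factory=list)
    corrected_fractions: list = field(default_factory=list)
    corrected_ci: dict | None = None
    entity_fractions: list = field(default_factory=list)
    grouped_particle: dict = field(default_factory=dict)
    grouped_entity: dict = field(default_factory=dict)
    residual_norm: float = float("nan")
    condition_indicator: float = float("nan")
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def summary(self) -> str:
        lines = [
            f"smbleach run (seed={self.seed}, config {self.config_hash})",
            f"  particles simulated : {self.n_particles_simulated}"
            f" (realized density {self.realized_density:.3g} /um^2)",
            f"  detections / tracks : {self.n_detections} / {self.n_tracks}",
            f"  traces accepted     : {self.n_traces_accepted} of {self.n_traces}"
            f" (rejections: {self.rejections})",
            f"  spot density        : {self.spot_density:.3g} /um^2"
            + (f" -> ~{self.receptors_per_cell} receptors/cell" if self.receptors_per_cell else ""),
            f"  observed steps      : {self.observed_counts}",
        ]
        if self.corrected_fractions:
            cf = ", ".join(f"{x:.3f}" for x in self.corrected_fractions)
            ef = ", ".join(f"{x:.3f}" for x in self.entity_fractions)
            lines += [
                f"  corrected fractions : [{cf}]",
                f"  entity fractions    : [{ef}]",
                f"  grouped (particle)  : {self.grouped_particle}",
            ]
        return "\n".join(lines)


def _write(out_dir: Path | None, name: str, df: pd.DataFrame) -> None:
    if out_dir is not None:
        write_table(out_dir / name, df)


def run_pipeline(config: RunConfig, out_dir=None) -> RunReport:
    """Execute the enabled stages in order and return the consolidated report.

    Artifacts (TIFF movie, ground-truth/spot/track/trace/step CSVs, report
    JSON) are written under ``out_dir`` when given. The run is deterministic
    for a fixed config and seed.
    """
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    report = RunReport(config.config_hash(), config.seed, __version__)

    movie: MovieStack | None = None
    if config.input_movie is not None:
        movie = read_movie(config.input_movie)
    elif "simulate" in stages:
        movie, truth = render_movie(config.simulation, seed=config.seed)
        report.n_particles_simulated = len(truth)
        report.ground_truth_fractions = truth.summary.tolist()
        report.realized_density = truth.realized_density
        if out_dir is not None:
            write_movie(out_dir / "movie.tif", movie)
            write_table(out_dir / "ground_truth.csv", truth.to_dataframe())
    if movie is None or "detect" not in stages:
        if out_dir is not None:
            (out_dir / "report.json").write_text(report.to_json())
        return report

    det = config.detection
    spots = detect_movie(
        movie, fit_frames=(0,), n_levels=det.n_levels, k_sigma=det.k_sigma,
        detect_level=det.detect_level, min_separation=det.min_separation,
        half_window=det.half_window, expected_sigma=det.expected_sigma,
    )
    report.n_detections = len(spots)
    frame0 = spots[(spots["frame"] == 0)]
    report.spot_density = spot_density(frame0, movie.fov_area)
    report.receptors_per_cell = receptors_per_cell(
        report.spot_density, config.correction.cell_area)
    _write(out_dir, "spots.csv", spots)
    if "link" not in stages:
        if out_dir is not None:
            (out_dir / "report.json").write_text(report.to_json())
        return report

    tracks = link(spots, config.linking.max_displacement, config.linking.max_gap)
    tracks = merge_stationary_tracks(tracks, config.linking.merge_radius)
    report.n_tracks = len(tracks)
    _write(out_dir, "tracks.csv", pd.DataFrame(
        [{"track_id": t.track_id, "start_frame": t.start_frame,
          "end_frame": t.end_frame, "n_detections": len(t),
          "row": t.anchor[0], "col": t.anchor[1], "isolated": t.isolated}
         for t in tracks]))
    if "trace" not in stages:
        if out_dir is not None:
            (out_dir / "report.json").write_text(report.to_json())
        return report

    tp = config.trace
    traces = extract_traces(movie, tracks, tp.aperture_radius,
                            (tp.annulus_inner, tp.annulus_outer),
                            flag_isolation=False)
    # tracks shorter than the minimum visible duration are detection noise or
    # immediately-bleached spots; exclude them before the unit estimate, and
    # judge crowding only among the remaining (valid) tracks
    by_id = {t.track_id: t for t in tracks}
    valid = [t for t in tracks if len(t) >= tp.min_duration]
    crowded_ids = flag_crowded_tracks(valid, 3.0 * det.expected_sigma)
    for tr in traces:
        if len(by_id[tr.track_id]) < tp.min_duration:
            tr.qc_flags.append("short track")
        elif tr.track_id in crowded_ids:
            tr.qc_flags.append("crowded")
    # step counting operates on the full-excitation segment only
    pre = config.simulation.preacq_frames if config.input_movie is None else 0
    if pre:
        traces = [FluorescenceTrace(t.track_id, t.intensity[pre:], t.frame_interval,
                                    t.aperture_radius, list(t.qc_flags)) for t in traces]
    report.n_traces = len(traces)
    _write(out_dir, "traces.csv", pd.DataFrame(
        [{"track_id": t.track_id, "frame": f, "value": v}
         for t in traces for f, v in enumerate(t.intensity)]))
    if "steps" not in stages:
        if out_dir is not None:
            (out_dir / "report.json").write_text(report.to_json())
        return report

    clean = [t for t in traces if not t.qc_flags]
    first_pass = [count_steps(t, penalty=config.steps.penalty, min_step=0.0)
                  for t in clean]
    unit = estimate_unit_intensity(first_pass)
    report.estimated_unit_intensity = unit
    rules = TraceQCRules(unit_intensity=unit, min_duration=tp.min_duration,
                         tail_frames=tp.tail_frames)
    accepted, rejection_log = qc_filter_traces(traces, rules)
    report.n_traces_accepted = len(accepted)
    report.rejections = rejection_log["reason"].value_counts().to_dict() if len(rejection_log) else {}
    _write(out_dir, "rejections.csv", rejection_log)

    fits, _ = fit_steps_batch(accepted, penalty=config.steps.penalty,
                              min_step_fraction=config.steps.min_step_fraction,
                              unit_intensity=unit)
    hist = aggregate_histogram(fits, n_max=config.correction.n_max,
                               density_value=report.spot_density)
    report.observed_counts = hist.counts.tolist()
    if hist.total:
        report.observed_fractions = hist.fractions().tolist()
    _write(out_dir, "step_fits.csv", pd.DataFrame(
        [{"track_id": f.track_id, "n_steps": f.n_steps,
          "change_points": ";".join(map(str, f.change_points)),
          "accepted": f.accepted} for f in fits]))
    _write(out_dir, "histogram.csv", hist.to_dataframe())
    if "correct" not in stages or hist.total == 0:
        if out_dir is not None:
            (out_dir / "report.json").write_text(report.to_json())
        return report

    model = LabelingModel(config.correction.labeling_efficiency,
                          config.correction.n_max,
                          config.correction.visibility_conditioned)
    result = solve_corrected_fractions(hist, model)
    report.corrected_fractions = result.corrected.fractions.tolist()
    report.residual_norm = result.residual_norm
    report.condition_indicator = result.condition_indicator
    report.notes.extend(result.warnings)
    entity = particle_to_entity(result.corrected)
    report.entity_fractions = entity.fractions.tolist()
    report.grouped_particle = group_fractions(result.corrected)
    report.grouped_entity = group_fractions(entity)
    corrected_df = pd.DataFrame({
        "order": np.arange(1, model.n_max + 1),
        "fraction": result.corrected.fractions,
    })
    if config.correction.bootstrap_replicates >= 100:
        ci = bootstrap_ci(hist, model, b=config.correction.bootstrap_replicates,
                          seed=config.seed)
        report.corrected_ci = {"ci_low": ci["ci_low"].tolist(),
                               "ci_high": ci["ci_high"].tolist()}
        corrected_df["ci_low"] = ci["ci_low"]
        corrected_df["ci_high"] = ci["ci_high"]
    _write(out_dir, "corrected.csv", corrected_df)
    if out_dir is not None:
        (out_dir / "report.json").write_text(report.to_json())
        (out_dir / "diagnostics.json").write_text(json.dumps({
            "residual_norm": report.residual_norm,
            "condition_indicator": report.condition_indicator,
            "n_particles": hist.total,
        }, indent=2))
    return report
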