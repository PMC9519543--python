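"""End-to-end runs: simulate -> detect -> track -> quantify -> report.

Two entry points:

* :func:`run_pipeline` executes the file-based stages for a
  :class:`~spiris.io.RunConfig`, writing every artifact with provenance
  (config hash, seed, tool version). Identical config + seed gives
  byte-identical outputs.

* :func:`run_kinetic_calibration` is the in-memory workhorse: it renders
  single-spot movies over a concentration grid plus blank (zero-target)
  spots, pushes each through detection and tracking, extracts per-spot
  binding rates, and fits the kinetic calibration with its LOD.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import DetectionKernel, DetectionParams, detect_stack
from .io import RunConfig, read_stack, write_stack, write_table
from .quantify import (BlankStats, KineticCalibrationResults, estimate_rate,
                       lod_kinetic)
from .simulate import (SimulationConfig, default_spot, events_to_frame,
                       render_timelapse, render_zstack, sample_events)
from .track import TrackingParams, cumulative_binding, track_detections, tracks_to_frame

__all__ = [
    "simulate_stage",
    "detect_stage",
    "track_stage",
    "quantify_stage",
    "run_pipeline",
    "movie_binding_rate",
    "run_kinetic_calibration",
]

logger = logging.getLogger("spiris")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input provenance."""

    def __init__(self, stage: str, source: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {source}: {cause}")
        self.stage = stage
        self.source = source


def _prov(config: RunConfig) -> dict:
    return {"config_hash": config.hash, "seed": config.seed}


def movie_binding_rate(
    sim: SimulationConfig,
    concentration: float,
    det_params: DetectionParams,
    trk_params: TrackingParams,
    rng: np.random.Generator,
    kernel: DetectionKernel | None = None,
) -> tuple[float, int]:
    """Simulate one single-spot kinetic movie and measure its binding rate.

    Returns (rate in events/hour from the OLS fit of the cumulative curve,
    number of tracked events). The full image chain runs: event sampling,
    rendering, detection, tracking.
    """
    if kernel is None:
        kernel = DetectionKernel.gaussian(sim.psf_sigma)
    spot = default_spot(sim)
    events = sample_events(sim, spot, concentration, rng)
    stack = render_timelapse(sim, events, rng)
    dets = detect_stack(stack, kernel, det_params, mode="kinetic")
    tracks = track_detections(dets, trk_params)
    log = cumulative_binding(tracks, stack.axis_values)
    curve = sum(log.counts.values())
    rate = estimate_rate(stack.axis_values, curve, concentration=concentration)
    return rate.rate, len(tracks)


def run_kinetic_calibration(
    sim: SimulationConfig,
    concentrations,
    replicates: int = 3,
    blank_replicates: int = 12,
    det_params: DetectionParams | None = None,
    trk_params: TrackingParams | None = None,
    seed: int | None = None,
) -> tuple[KineticCalibrationResults, pd.DataFrame]:
    """Image-level kinetic calibration: movies -> rates -> LOD fit.

    Blank spots are movies at zero target concentration (nonspecific binding
    only). Returns the fitted calibration results and the per-movie rate
    table (concentration, replicate, rate_per_h, n_events).
    """
    det_params = det_params or DetectionParams()
    trk_params = trk_params or TrackingParams()
    rng = np.random.default_rng(sim.rng_seed if seed is None else seed)
    kernel = DetectionKernel.gaussian(sim.psf_sigma)
    rows = []
    for c in concentrations:
        for rep in range(replicates):
            rate, n = movie_binding_rate(sim, float(c), det_params, trk_params,
                                         rng, kernel)
            rows.append({"concentration": float(c), "replicate": rep,
                         "rate_per_h": rate, "n_events": n})
    blank_rates = []
    for rep in range(blank_replicates):
        rate, _ = movie_binding_rate(sim, 0.0, det_params, trk_params, rng, kernel)
        blank_rates.append(rate)
    blank = BlankStats.from_samples(blank_rates)
    table = pd.DataFrame(rows)
    means = table.groupby("concentration")["rate_per_h"].mean()
    results = lod_kinetic(means.index.to_numpy(), means.to_numpy(), blank)
    return results, table


# ---------------------------------------------------------------------------
# file-based stages

def simulate_stage(config: RunConfig, outdir: Path) -> dict:
    """Render a single-spot synthetic stack and write it with ground truth."""
    sim = config.simulation
    rng = np.random.default_rng(config.seed)
    spot = default_spot(sim)
    if config.mode == "kinetic":
        events = sample_events(sim, spot, config.concentrations_molar[0], rng)
        stack = render_timelapse(sim, events, rng)
    else:
        spot_rng = np.random.default_rng(config.seed)
        events = sample_events(sim, spot, config.concentrations_molar[0], spot_rng)
        particles = [(ev.x, ev.y) for ev in events]
        stack = render_zstack(sim, particles, rng)
    stack_path = write_stack(outdir / "stack.tif", stack, extra_meta=_prov(config))
    write_table(events_to_frame(events), outdir / "ground_truth_events.csv",
                _prov(config))
    (outdir / "simulation_config.json").write_text(
        json.dumps({**dataclasses.asdict(sim), **_prov(config)}, indent=1,
                   sort_keys=True, default=str))
    return {"stack": str(stack_path),
            "events": str(outdir / "ground_truth_events.csv")}


def detect_stage(config: RunConfig, outdir: Path, stack_path=None) -> dict:
    """Detect particles in a stack file; write a detections CSV + params JSON."""
    path = Path(stack_path or config.stack or outdir / "stack.tif")
    stack = read_stack(path)
    if config.kernel:
        import tifffile

        kernel = DetectionKernel(tifffile.imread(config.kernel).astype(float))
    else:
        kernel = DetectionKernel.gaussian(config.simulation.psf_sigma)
    dets = detect_stack(stack, kernel, config.detection, mode=config.mode)
    det_path = write_table(dets, outdir / "detections.csv", _prov(config))
    (outdir / "detection_params.json").write_text(
        json.dumps({**config.detection.to_dict(), **_prov(config)}, indent=1,
                   sort_keys=True, default=str))
    return {"detections": str(det_path)}


def track_stage(config: RunConfig, outdir: Path, detections_path=None,
                stack_path=None) -> dict:
    """Link detections into tracks and an event log; write both CSVs."""
    from .io import read_table
    from .spotgrid import SpotGrid, assign

    det_path = Path(detections_path or outdir / "detections.csv")
    dets = read_table(det_path)
    tracks = track_detections(dets, config.tracking)
    s_path = Path(stack_path or config.stack or outdir / "stack.tif")
    if s_path.exists():
        frame_times = read_stack(s_path).axis_values
    else:
        n = int(dets["frame_index"].max()) + 1 if len(dets) else 1
        frame_times = np.arange(n, dtype=float)
    assignment = None
    if config.grid:
        grid = SpotGrid.from_json(Path(config.grid).read_text())
        assignment = assign(tracks, grid, config.simulation.pixel_pitch)
    else:
        assignment = {t.track_id: "spot_0" for t in tracks}
    log = cumulative_binding(tracks, frame_times, assignment)
    t_path = write_table(tracks_to_frame(tracks), outdir / "tracks.csv",
                         _prov(config))
    e_path = write_table(log.to_frame(), outdir / "event_log.csv", _prov(config))
    return {"tracks": str(t_path), "event_log": str(e_path)}


def quantify_stage(config: RunConfig, outdir: Path) -> dict:
    """Image-level calibration over the configured concentration grid.

    Runs `run_kinetic_calibration` under the run's seed and writes the rate
    table plus a calibration report JSON (slopes, intercepts, LOD, interval,
    flags).
    """
    results, table = run_kinetic_calibration(
        config.simulation, config.concentrations_molar,
        replicates=config.replicates, blank_replicates=config.blank_replicates,
        det_params=config.detection, trk_params=config.tracking,
        seed=config.seed,
    )
    write_table(table, outdir / "rates.csv", _prov(config))
    report = {**results.to_dict(), **_prov(config)}
    (outdir / "calibration_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    return {"rates": str(outdir / "rates.csv"),
            "report": str(outdir / "calibration_report.json"),
            "lod_molar": results.lod.lod}


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute simulate -> detect -> track -> quantify; return artifact paths."""
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    stages = [
        ("simulate", simulate_stage),
        ("detect", detect_stage),
        ("track", track_stage),
        ("quantify", quantify_stage),
    ]
    for name, fn in stages:
        try:
            artifacts.update(fn(config, outdir))
        except Exception as exc:  # noqa: BLE001 - re-raised with provenance
            raise StageError(name, f"config {config.hash} seed {config.seed}",
                             exc) from exc
        logger.info("stage %s done", name)
    (outdir / "run_summary.json").write_text(
        json.dumps({k: v for k, v in artifacts.items()},
                   indent=1, sort_keys=True, default=str))
    return artifacts
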