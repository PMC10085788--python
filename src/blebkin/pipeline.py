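"""End-to-end desk-scale analysis: tracks -> rate -> trajectory -> budget.

`run_pipeline` chains the detachment-rate estimate, the age trajectory,
the expected-detachments integral and the chromatin-loss budget into a
single machine-readable report.  Every number in the report is
recomputable from the echoed configuration; formatted percent strings
are derived fields, never inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .budget import BudgetParams, budget_report
from .io import read_frequency_obs, read_tracks
from .kinetics import ValidationError, estimate_detachment_rate
from .synthetic import (
    BirthIntensity,
    SimConfig,
    StudyDesign,
    generate_study,
)
from .trajectory import (
    Trajectory,
    default_power_trajectory,
    expected_detachments,
    integrate_trajectory,
    trajectory_from_observations,
)

__all__ = ["run_pipeline", "PipelineError", "birth_intensity_from_dict", "sim_config_from_dict"]

logger = logging.getLogger("blebkin")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def birth_intensity_from_dict(d: dict) -> BirthIntensity:
    d = dict(d)
    if "target" in d:
        d["target"] = Trajectory.from_dict(d["target"])
    return BirthIntensity(**d)


def sim_config_from_dict(d: dict, seed: int | None = None) -> SimConfig:
    d = dict(d)
    d["birth_intensity"] = birth_intensity_from_dict(d["birth_intensity"])
    if seed is not None:
        d["seed"] = seed
    return SimConfig(**d)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # surfaced with stage context
            raise PipelineError(name, exc) from exc

    return wrap


def run_pipeline(config: dict) -> dict:
    """Run the full analysis described by a configuration dict.

    Configuration keys (all optional unless noted):

    * ``seed`` — root seed for any simulation (default 0);
    * ``ci_level`` — confidence level for the rate CI (default 0.95);
    * ``age_window`` — ``[t_start, t_end]`` in adult days (default [1, 14]);
    * ``simulate`` — if present, a study is generated first:
      ``{"config": <SimConfig dict>, "design": <StudyDesign dict>,
      "out_dir": path}``; its outputs become the default inputs;
    * ``tracks`` — path to a track TSV (required unless simulating);
    * ``frequency`` — path to a frequency TSV (required when
      ``trajectory`` is ``"from_observations"``);
    * ``trajectory`` — a trajectory dict, ``"from_observations"``, or
      absent for the default power-law reconstruction;
    * ``budget`` — overrides for :class:`BudgetParams` fields other than
      ``expected_detachments``.
    """
    seed = int(config.get("seed", 0))
    ci_level = float(config.get("ci_level", 0.95))
    t_start, t_end = config.get("age_window", [1.0, 14.0])
    warnings_out: list[str] = []

    tracks_path = config.get("tracks")
    frequency_path = config.get("frequency")

    if "simulate" in config:
        sim = config["simulate"]
        sim_config = _stage("simulate")(
            sim_config_from_dict, sim["config"], seed=seed
        )
        design = StudyDesign(**sim.get("design", {}))
        bundle = _stage("simulate")(generate_study, sim_config, design, sim["out_dir"])
        tracks_path = tracks_path or bundle.tracks_path
        frequency_path = frequency_path or bundle.frequency_path

    if tracks_path is None:
        raise PipelineError("estimate", ValidationError("no track table given or simulated"))

    tracks = _stage("read-tracks")(read_tracks, tracks_path)
    estimate = _stage("estimate")(estimate_detachment_rate, tracks, ci_level)
    logger.info(
        "detachment rate %.3g/h from %d events over %.1f bleb-hours",
        estimate.rate,
        estimate.n_events,
        estimate.exposure,
    )
    if estimate.n_events == 0:
        warnings_out.append(
            "no detachment events observed: rate 0, infinite lifetime, zero budget"
        )

    traj_spec = config.get("trajectory")
    if traj_spec == "from_observations":
        if frequency_path is None:
            raise PipelineError(
                "trajectory", ValidationError("'from_observations' needs a frequency table")
            )
        obs = _stage("read-frequency")(read_frequency_obs, frequency_path)
        traj = _stage("trajectory")(trajectory_from_observations, obs)
    elif isinstance(traj_spec, dict):
        traj = _stage("trajectory")(Trajectory.from_dict, traj_spec)
    elif traj_spec is None:
        traj = default_power_trajectory()
    else:
        raise PipelineError(
            "trajectory", ValidationError(f"invalid trajectory spec {traj_spec!r}")
        )

    integral = _stage("integrate")(integrate_trajectory, traj, t_start, t_end)
    n_detach = _stage("integrate")(expected_detachments, traj, estimate.rate, t_start, t_end)

    budget_overrides = dict(config.get("budget", {}))
    params = _stage("budget")(
        BudgetParams, expected_detachments=n_detach, **budget_overrides
    )
    result = _stage("budget")(budget_report, params)
    logger.info(
        "hyp7 DNA loss via blebbing %s; share of total %s",
        result.to_dict()["hyp7_loss_percent"],
        result.to_dict()["share_of_total_percent"],
    )

    config_blob = json.dumps(config, sort_keys=True, default=str).encode()
    report = {
        "provenance": {
            "blebkin_version": __version__,
            "config_sha256": hashlib.sha256(config_blob).hexdigest(),
            "seed": seed,
        },
        "config": config,
        "kinetics": estimate.to_dict(),
        "trajectory": traj.to_dict(),
        "age_window_days": [t_start, t_end],
        "trajectory_integral_bleb_days": integral,
        "expected_detachments_per_nucleus": n_detach,
        "budget": result.to_dict(),
        "warnings": warnings_out,
    }
    return report


def write_report(report: dict, path: str | Path | None) -> str:
    text = json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
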