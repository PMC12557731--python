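"""File formats: run-configuration YAML, XYZ trajectories, JSON sidecars, CSV metrics.

The run-configuration file is one YAML document with up to three mappings —
``parameters``, ``schedule`` and ``experiment`` — whose keys mirror the
dataclass fields of :class:`SimulationParameters`, :class:`PhaseSchedule`
and :class:`ExperimentPlan`.  Every key has a default; unknown keys are an
error (typo safety).  ``parameters.phi`` may be given instead of
``parameters.R_vesicle`` and is converted with the bead-volume formula.

Trajectories are written as extended XYZ: one frame per snapshot, the
element column carrying the chain label (A/B), the comment line carrying
the time stamp in tau.  Positions round-trip at full double precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import PhaseSchedule, RunResult, default_schedule
from .errors import ConfigFileError, InvalidParameterError
from .experiment import ExperimentPlan
from .metrics import EnsembleResult, MetricsSeries
from .model import (
    CHAIN_LABELS,
    Configuration,
    SimulationParameters,
    ring_bonds,
    vesicle_radius_from_volume_fraction,
)

_SECTIONS = ("parameters", "schedule", "experiment")


# ---------------------------------------------------------------------------
# run configuration


def load_and_validate_config(path):
    """Parse a YAML run configuration into validated, fully defaulted objects.

    Returns ``(SimulationParameters, PhaseSchedule, ExperimentPlan)``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigFileError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigFileError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigFileError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigFileError(f"{path}: unknown section(s) {sorted(unknown)}")

    params = _build_params(raw.get("parameters") or {})
    schedule = _build_schedule(raw.get("schedule") or {}, params)
    plan = _build_plan(raw.get("experiment") or {})
    return params, schedule, plan


def _check_keys(section: str, given: dict, allowed) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ConfigFileError(
            f"unknown key(s) {sorted(unknown)} in section '{section}' "
            f"(allowed: {sorted(allowed)})"
        )


def _build_params(section: dict) -> SimulationParameters:
    fields = {f.name for f in dataclasses.fields(SimulationParameters)}
    _check_keys("parameters", section, fields | {"phi"})
    section = dict(section)
    phi = section.pop("phi", None)
    try:
        if phi is not None:
            if "R_vesicle" in section:
                raise ConfigFileError("give either 'phi' or 'R_vesicle', not both")
            return SimulationParameters.for_volume_fraction(phi, **section)
        return SimulationParameters(**section)
    except InvalidParameterError as exc:
        raise ConfigFileError(f"invalid 'parameters' section: {exc}") from exc


def _build_schedule(section: dict, params: SimulationParameters) -> PhaseSchedule:
    fields = {f.name for f in dataclasses.fields(PhaseSchedule)}
    _check_keys("schedule", section, fields)
    try:
        if section.keys() <= {"compaction_mode"}:
            return default_schedule(
                section.get("compaction_mode", "fast"), params.n_beads_per_ring
            )
        return PhaseSchedule(**section)
    except InvalidParameterError as exc:
        raise ConfigFileError(f"invalid 'schedule' section: {exc}") from exc


def _build_plan(section: dict) -> ExperimentPlan:
    fields = {f.name for f in dataclasses.fields(ExperimentPlan)}
    _check_keys("experiment", section, fields)
    try:
        return ExperimentPlan(**section)
    except InvalidParameterError as exc:
        raise ConfigFileError(f"invalid 'experiment' section: {exc}") from exc


def effective_config_dict(params, schedule, plan) -> dict:
    return {
        "parameters": dataclasses.asdict(params),
        "schedule": dataclasses.asdict(schedule),
        "experiment": dataclasses.asdict(plan),
    }


def write_config(path, params, schedule, plan) -> None:
    """Echo the fully defaulted configuration back out (round-trips exactly)."""
    Path(path).write_text(
        yaml.safe_dump(effective_config_dict(params, schedule, plan), sort_keys=True)
    )


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory(result: RunResult, path) -> None:
    """Extended-XYZ trajectory, one frame per snapshot, chain in the element column."""
    if not result.snapshots:
        raise InvalidParameterError("refusing to write an empty trajectory")
    lines = []
    for snap in result.snapshots:
        lines.append(str(snap.n_beads))
        lines.append(f"time_tau={float(snap.time):.17g}")
        for label, row in zip(snap.chain_id, snap.positions):
            lines.append(
                f"{CHAIN_LABELS[int(label)]} "
                f"{float(row[0]):.17g} {float(row[1]):.17g} {float(row[2]):.17g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path):
    """Read an XYZ trajectory back: list of (time, positions, chain_id)."""
    lines = Path(path).read_text().splitlines()
    frames = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k])
        comment = lines[k + 1]
        time = 0.0
        for token in comment.split():
            if token.startswith("time_tau="):
                time = float(token.split("=", 1)[1])
        pos = np.empty((n, 3))
        chain = np.empty(n, dtype=np.int8)
        for i in range(n):
            parts = lines[k + 2 + i].split()
            chain[i] = CHAIN_LABELS.index(parts[0])
            pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append((time, pos, chain))
        k += 2 + n
    return frames


def trajectory_to_configurations(frames) -> list[Configuration]:
    """Rebuild Configurations from frames (rings assumed contiguous per chain)."""
    out = []
    for time, pos, chain in frames:
        n_a = int(np.sum(chain == 0))
        n_b = int(np.sum(chain == 1))
        out.append(Configuration(pos, chain, ring_bonds(n_a, n_b), time=time))
    return out


# ---------------------------------------------------------------------------
# sidecars and CSV


def write_metadata(path, params, schedule, seed: int, extra: dict | None = None) -> None:
    """JSON sidecar sufficient to reproduce the accompanying file exactly."""
    payload = {
        "ringseg_version": __version__,
        "seed": int(seed),
        "parameters": dataclasses.asdict(params),
        "schedule": dataclasses.asdict(schedule),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_metadata(path) -> dict:
    return json.loads(Path(path).read_text())


def metrics_to_frame(series: MetricsSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_tau": series.times,
            "efficiency": series.efficiency,
            "com_dist_norm": series.com_distance_norm,
            "rg_A": series.rg_a,
            "rg_B": series.rg_b,
        }
    )


def write_metrics_csv(series: MetricsSeries, path) -> None:
    metrics_to_frame(series).to_csv(path, index=False)


def read_metrics_csv(path, replica_seed: int = -1) -> MetricsSeries:
    df = pd.read_csv(path)
    return MetricsSeries(
        df["time_tau"].to_numpy(),
        df["efficiency"].to_numpy(),
        df["com_dist_norm"].to_numpy(),
        df["rg_A"].to_numpy(),
        df["rg_B"].to_numpy(),
        replica_seed=replica_seed,
    )


def summary_to_frame(summary: EnsembleResult, mode: str, phi: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mode": mode,
            "phi": phi,
            "time_tau": summary.times,
            "mean_efficiency": summary.mean_efficiency,
            "se_efficiency": summary.se_efficiency,
            "mean_dist": summary.mean_dist,
            "se_dist": summary.se_dist,
            "n": summary.n_replicas,
        }
    )
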