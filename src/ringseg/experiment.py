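"""Replica ensembles and the top-level experiment driver.

An :class:`ExperimentPlan` names a grid of (compaction mode, volume
fraction) cells; each cell runs ``n_replicas`` independent replicas with
seeds ``base_seed + i`` and is summarized as a mean +/- SE time series of
both segregation metrics.  The driver is restartable: per-replica metric
CSVs already on disk are loaded instead of recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from pathlib import Path

import pandas as pd

from .engine import COMPACTION_MODES, PhaseSchedule, RunResult, default_schedule, run_protocol
from .errors import InstabilityError, InvalidParameterError
from .fixtures import make_mixed_compact_init
from .metrics import (
    EnsembleResult,
    MetricsSeries,
    compute_metrics_series,
    ensemble_summary,
)
from .model import SimulationParameters

logger = logging.getLogger("ringseg")


@dataclass(frozen=True)
class ExperimentPlan:
    """Grid of (mode, phi) cells replicated over seeds."""

    name: str = "segregation"
    modes: tuple = ("none", "slow", "fast")
    phis: tuple = (0.10,)
    n_replicas: int = 10
    base_seed: int = 1000
    n_beads_per_ring: int = 200
    schedule_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise InvalidParameterError("n_replicas must be >= 1")
        if not self.modes:
            raise InvalidParameterError("modes must be nonempty")
        for mode in self.modes:
            if mode not in COMPACTION_MODES:
                raise InvalidParameterError(f"unknown compaction mode {mode!r}")
        for phi in self.phis:
            if not (0.0 < phi < 0.4):
                raise InvalidParameterError(f"phi={phi} outside (0, 0.4)")
        object.__setattr__(self, "modes", tuple(self.modes))
        object.__setattr__(self, "phis", tuple(float(p) for p in self.phis))
        object.__setattr__(self, "schedule_overrides", dict(self.schedule_overrides))


def run_replica(
    params: SimulationParameters,
    schedule: PhaseSchedule,
    phi: float,
    seed: int,
) -> tuple[RunResult, MetricsSeries]:
    """One replica: generate the mixed initial state, run the protocol, measure."""
    initial = make_mixed_compact_init(params, phi, seed)
    result = run_protocol(params, schedule, initial, seed)
    return result, compute_metrics_series(result)


def run_ensemble(
    mode: str,
    phi: float,
    n_replicas: int,
    base_seed: int,
    n_beads_per_ring: int = 200,
    schedule: PhaseSchedule | None = None,
    param_overrides: dict | None = None,
) -> tuple[list[MetricsSeries], EnsembleResult]:
    """n replicas of one (mode, phi) cell, seeds base_seed..base_seed+n-1."""
    params = SimulationParameters.for_volume_fraction(
        phi, n_beads_per_ring=n_beads_per_ring, **(param_overrides or {})
    )
    if schedule is None:
        schedule = default_schedule(mode, n_beads_per_ring)
    elif schedule.compaction_mode != mode:
        schedule = schedule.with_(compaction_mode=mode)
    series = []
    for i in range(n_replicas):
        seed = base_seed + i
        logger.info("replica %d/%d (mode=%s phi=%.2f seed=%d)", i + 1, n_replicas, mode, phi, seed)
        _, s = run_replica(params, schedule, phi, seed)
        series.append(s)
    return series, ensemble_summary(series)


def run_experiment(plan: ExperimentPlan, outdir) -> pd.DataFrame:
    """Run every (mode, phi) cell of the plan; write per-replica and summary CSVs.

    Returns the tidy long-format summary table
    (mode, phi, time_tau, mean/SE for both metrics, n).
    """
    from . import io  # deferred: io imports ExperimentPlan from here

    outdir = Path(outdir) / plan.name
    outdir.mkdir(parents=True, exist_ok=True)
    summaries = []
    failures = []
    for mode in plan.modes:
        for phi in plan.phis:
            celldir = outdir / f"{mode}_phi{phi:.2f}"
            celldir.mkdir(parents=True, exist_ok=True)
            params = SimulationParameters.for_volume_fraction(
                phi, n_beads_per_ring=plan.n_beads_per_ring
            )
            schedule = default_schedule(
                mode, plan.n_beads_per_ring, **plan.schedule_overrides
            )
            series = []
            for i in range(plan.n_replicas):
                seed = plan.base_seed + i
                csv_path = celldir / f"replica_{seed}.csv"
                if csv_path.exists():
                    logger.info("skipping completed replica %s", csv_path)
                    series.append(io.read_metrics_csv(csv_path, replica_seed=seed))
                    continue
                try:
                    _, s = run_replica(params, schedule, phi, seed)
                except InstabilityError as exc:
                    logger.error("replica seed=%d (mode=%s phi=%.2f) failed: %s", seed, mode, phi, exc)
                    failures.append((mode, phi, seed, str(exc)))
                    continue
                io.write_metrics_csv(s, csv_path)
                io.write_metadata(
                    csv_path.with_suffix(".json"), params, schedule, seed,
                    extra={"mode": mode, "phi": phi},
                )
                series.append(s)
            if len(series) >= 2:
                summaries.append(io.summary_to_frame(ensemble_summary(series), mode, phi))
    table = (
        pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    )
    table.to_csv(outdir / "summary.csv", index=False)
    if failures:
        raise InstabilityError(
            f"{len(failures)} replica(s) failed: "
            + "; ".join(f"mode={m} phi={p} seed={s}: {msg}" for m, p, s, msg in failures)
        )
    return table
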