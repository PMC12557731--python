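"""Brownian-dynamics integration and the phased segregation protocol.

A run proceeds through three phases.  First the two intermixed rings relax
and demix entropically (no attraction).  At ``t_relax`` compaction may begin:
a nonspecific bead-bead attraction ramps linearly from 0 to ``eps_max`` over
``t_ramp`` ("slow" and "fast" differ only in the ramp duration).  In the
global modes the attraction is suppressed for pairs straddling the
inhibition plane — the plane through the midpoint of the two chain centers
of mass, computed once at compaction onset and frozen (a fixed proxy for the
future division plane; set a finite ``plane_update_interval`` to let it track the
nucleoids).  In the ``spreading`` mode the attraction instead acts only in
cis, between beads of the same chain that an activation front, emanating
from one origin bead per ring, has already passed.  Finally, from
``t_membrane_on`` every bead feels the membrane-adhesion well, letting the
compacted nucleoids re-associate with the vesicle wall.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import logging
import math

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .errors import (
    ConfigurationInvariantError,
    InstabilityError,
    IntegrationError,
    InvalidParameterError,
)
from .model import (
    CHAIN_A,
    CHAIN_B,
    Configuration,
    Plane,
    SimulationParameters,
    attraction_force,
    ring_neighbor_arrays,
    soft_core_force,
)

logger = logging.getLogger("ringseg")

COMPACTION_MODES = ("none", "slow", "fast", "spreading")
_MODE_CODE = {"none": 0, "slow": 1, "fast": 1, "spreading": 2}


# ---------------------------------------------------------------------------
# schedule


@dataclass(frozen=True)
class PhaseSchedule:
    """Timings (tau) and mode of the relax / compact / membrane protocol."""

    t_relax: float = 1000.0
    compaction_mode: str = "fast"
    t_ramp: float = 50.0
    t_membrane_on: float = 1050.0
    t_total: float = 1600.0
    snapshot_interval: float = 25.0
    spreading_speed: float = 0.5
    spreading_origin: int | str = "auto"
    plane_update_interval: float = 25.0

    def __post_init__(self) -> None:
        if self.compaction_mode not in COMPACTION_MODES:
            raise InvalidParameterError(
                f"compaction_mode must be one of {COMPACTION_MODES}, got {self.compaction_mode!r}"
            )
        if not (0.0 <= self.t_relax <= self.t_membrane_on <= self.t_total):
            raise InvalidParameterError(
                "need 0 <= t_relax <= t_membrane_on <= t_total, got "
                f"t_relax={self.t_relax}, t_membrane_on={self.t_membrane_on}, t_total={self.t_total}"
            )
        if self.compaction_mode != "none" and self.t_ramp <= 0:
            raise InvalidParameterError("t_ramp must be > 0 unless compaction_mode='none'")
        if self.snapshot_interval <= 0:
            raise InvalidParameterError("snapshot_interval must be > 0")
        if self.compaction_mode == "spreading" and self.spreading_speed < 0:
            raise InvalidParameterError("spreading_speed must be >= 0")
        if not (self.spreading_origin == "auto" or isinstance(self.spreading_origin, int)):
            raise InvalidParameterError("spreading_origin must be 'auto' or a bead index")
        if self.plane_update_interval <= 0:
            raise InvalidParameterError("plane_update_interval must be positive (inf = frozen)")

    def with_(self, **changes) -> "PhaseSchedule":
        return replace(self, **changes)


def default_schedule(mode: str, n_beads_per_ring: int = 200, **overrides) -> PhaseSchedule:
    """Desk-scale schedule for a given compaction mode and system size.

    Phase durations scale with the ring Rouse time (~N^2), anchored at
    t_relax = 1000 tau for 200-bead rings, which is where the entropic
    efficiency curve of that system plateaus.  The fast ramp is a small
    fraction of the relaxation time, the slow ramp is comparable to it —
    the contrast between the two, not either absolute duration, is the
    modeled quantity.
    """
    if mode not in COMPACTION_MODES:
        raise InvalidParameterError(f"unknown compaction mode {mode!r}")
    scale = (n_beads_per_ring / 200.0) ** 2
    t_relax = 1000.0 * scale
    # Slow compaction deliberately outlasts the run: the ramp is still
    # unfinished at t_total, modeling compaction that has not completed by
    # the time the cell divides.
    t_ramp = {"none": 50.0 * scale, "fast": 50.0 * scale,
              "slow": 1600.0 * scale, "spreading": 50.0 * scale}[mode]
    # Activation front covers a half-ring in ~200 tau (at the 200-bead scale).
    speed = (n_beads_per_ring / 2.0) / (200.0 * scale)
    base = dict(
        t_relax=t_relax,
        compaction_mode=mode,
        t_ramp=t_ramp,
        t_total=1600.0 * scale,
        snapshot_interval=25.0 * scale,
        spreading_speed=speed,
        plane_update_interval=25.0 * scale,
    )
    base.update(overrides)
    # Membrane re-association at the end of the compaction ramp, or at the
    # end of the run if the ramp is still unfinished then.
    base.setdefault("t_membrane_on", min(base["t_relax"] + base["t_ramp"], base["t_total"]))
    return PhaseSchedule(**base)


# ---------------------------------------------------------------------------
# small operations


def step_brownian(
    config: Configuration,
    forces: np.ndarray,
    params: SimulationParameters,
    rng: np.random.Generator,
) -> Configuration:
    """One overdamped Euler-Maruyama step: x += dt/gamma F + sqrt(2 kT dt/gamma) xi."""
    forces = np.asarray(forces, dtype=float)
    if not np.all(np.isfinite(forces)):
        bad = int(np.flatnonzero(~np.isfinite(forces).all(axis=1))[0])
        raise IntegrationError(f"non-finite force on bead {bad}")
    disp = (params.dt / params.gamma) * forces
    disp = disp + params.noise_amplitude * rng.standard_normal(config.positions.shape)
    if not np.all(np.isfinite(disp)):
        bad = int(np.flatnonzero(~np.isfinite(disp).all(axis=1))[0])
        raise IntegrationError(f"non-finite displacement for bead {bad}")
    return Configuration(
        config.positions + disp, config.chain_id, config.bonds, config.time + params.dt
    )


def build_neighbor_pairs(config: Configuration, cutoff: float) -> np.ndarray:
    """All bead pairs (i < j) with separation < cutoff, via a k-d tree."""
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be positive")
    tree = cKDTree(config.positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.sort(pairs.astype(np.int64), axis=1)
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


def attraction_strength_at(t: float, schedule: PhaseSchedule, params: SimulationParameters) -> float:
    """Compaction well depth (kT) at time t: 0, linear ramp, then plateau."""
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    if schedule.compaction_mode == "none" or t < schedule.t_relax:
        return 0.0
    if t < schedule.t_relax + schedule.t_ramp:
        return params.eps_max * (t - schedule.t_relax) / schedule.t_ramp
    return params.eps_max


def compute_inhibition_plane(config: Configuration) -> Plane:
    """Plane through the midpoint of the two chain COMs, normal along their axis.

    If the COMs coincide (separation < 1e-6) the normal defaults to +z.
    """
    com_a = config.com(CHAIN_A)
    com_b = config.com(CHAIN_B)
    axis = com_a - com_b
    norm = float(np.linalg.norm(axis))
    if norm < 1e-6:
        normal = np.array([0.0, 0.0, 1.0])
    else:
        normal = axis / norm
    return Plane(point=0.5 * (com_a + com_b), normal=normal)


# ---------------------------------------------------------------------------
# spreading state


@dataclass
class SpreadingState:
    """Per-bead activation bookkeeping for in-cis spreading compaction.

    ``front`` is the fractional number of beads the activation signal has
    covered (per direction) since onset; a bead activates once the integer
    front reaches its contour distance from its chain's origin bead.
    """

    activated: np.ndarray
    activation_time: np.ndarray
    origins: tuple[int, ...]
    contour_distance: np.ndarray
    front: float = 0.0
    time: float = 0.0

    @classmethod
    def initial(cls, bonds: np.ndarray, chain_id: np.ndarray, origins) -> "SpreadingState":
        n = chain_id.shape[0]
        contour = contour_distances(bonds, n, origins)
        activated = contour == 0
        activation_time = np.where(activated, 0.0, np.inf)
        return cls(activated, activation_time, tuple(int(o) for o in origins), contour)


def contour_distances(bonds: np.ndarray, n_beads: int, origins) -> np.ndarray:
    """Per-bead ring distance (in beads, along the shorter arc) to its origin."""
    nxt, _ = ring_neighbor_arrays(bonds, n_beads)
    dist = np.full(n_beads, -1, dtype=np.int64)
    for origin in origins:
        ring = [int(origin)]
        node = int(nxt[origin])
        while node != origin:
            ring.append(node)
            node = int(nxt[node])
        m = len(ring)
        for k, bead in enumerate(ring):
            dist[bead] = min(k, m - k)
    if np.any(dist < 0):
        raise ConfigurationInvariantError("every ring needs exactly one spreading origin")
    return dist


def advance_spreading(state: SpreadingState, dt: float, speed: float, bonds=None) -> SpreadingState:
    """Grow the activated contour interval symmetrically at ``speed`` beads/tau.

    Activation is monotone and keeps, per chain, one contiguous interval
    containing the origin; after time t the active count per ring is
    min(N, 1 + 2*floor(speed*t)).
    """
    del bonds  # topology is frozen in state.contour_distance
    front = state.front + speed * dt
    time = state.time + dt
    reach = math.floor(front)
    newly = (~state.activated) & (state.contour_distance <= reach)
    activated = state.activated | newly
    activation_time = state.activation_time.copy()
    activation_time[newly] = time
    return SpreadingState(
        activated, activation_time, state.origins, state.contour_distance, front, time
    )


def force_tables(params: SimulationParameters, n_bins: int = 8192):
    """Force tables the kernel interpolates: F(r)/r for the soft-core
    repulsion and the unit-depth attraction on a uniform grid in r^2 over
    [0, r_att^2], plus the membrane well force over [R - r_mem, R].  Built
    from the analytic forms in :mod:`ringseg.model`; dividing by r folds the
    pair-direction normalization into the table so the inner loop needs no
    square root."""
    r2 = np.linspace(0.0, params.r_att**2, n_bins + 1)
    r = np.sqrt(r2)
    safe_r = np.where(r > 1e-9, r, 1.0)
    frep = np.asarray(soft_core_force(r, params.E_cross, params.sigma), dtype=np.float64) / safe_r
    # limit of F(r)/r at r -> 0 for the soft core: E_cross * pi^2 / sigma^2
    frep[r <= 1e-9] = params.E_cross * np.pi**2 / params.sigma**2
    fatt = np.asarray(attraction_force(r, 1.0, params.sigma, params.r_att), dtype=np.float64) / safe_r
    shell = np.linspace(params.R_vesicle - params.r_mem, params.R_vesicle, 1025)
    fmem = (0.5 * params.eps_mem * np.pi / params.r_mem) * np.sin(
        np.pi * (params.R_vesicle - shell) / params.r_mem
    )
    return frep, fatt, np.asarray(fmem, dtype=np.float64)


# ---------------------------------------------------------------------------
# protocol runner


@dataclass
class RunResult:
    """Snapshots of one replica plus everything needed to reproduce it."""

    snapshots: list
    schedule: PhaseSchedule
    params: SimulationParameters
    seed: int

    @property
    def times(self) -> np.ndarray:
        return np.array([c.time for c in self.snapshots])

    @property
    def final(self) -> Configuration:
        return self.snapshots[-1]


def run_protocol(
    params: SimulationParameters,
    schedule: PhaseSchedule,
    initial: Configuration,
    seed: int,
) -> RunResult:
    """Integrate the full phased protocol; reproducible bit-for-bit from seed."""
    initial.validate(R_vesicle=params.R_vesicle, sigma=params.sigma)

    pos = np.ascontiguousarray(initial.positions, dtype=np.float64).copy()
    chain = np.ascontiguousarray(initial.chain_id, dtype=np.int8)
    bonds = initial.bonds
    n = pos.shape[0]
    nxt, prv = ring_neighbor_arrays(bonds, n)
    contour = np.zeros(n, dtype=np.int64)

    dt = params.dt
    steps_total = int(round(schedule.t_total / dt))
    snap_every = max(1, int(round(schedule.snapshot_interval / dt)))
    step_relax = min(int(round(schedule.t_relax / dt)), steps_total)

    plane_every = None
    if math.isfinite(schedule.plane_update_interval):
        plane_every = max(1, int(round(schedule.plane_update_interval / dt)))
    plane_steps = (
        set(range(step_relax + plane_every, steps_total, plane_every))
        if plane_every is not None
        else set()
    )
    boundaries = sorted(
        {steps_total, step_relax}
        | set(range(snap_every, steps_total, snap_every))
        | plane_steps
    )
    snapshot_steps = set(range(snap_every, steps_total, snap_every)) | {steps_total}

    mode = _MODE_CODE[schedule.compaction_mode]
    plane = None
    use_plane = False
    plane_point = np.zeros(3)
    plane_normal = np.array([0.0, 0.0, 1.0])
    pairs_cap = max(4096, n * 256)
    pairs_i = np.empty(pairs_cap, dtype=np.int32)
    pairs_j = np.empty(pairs_cap, dtype=np.int32)
    skin = 2.0 * params.sigma

    frep_tab, fatt_tab, fmem_tab = force_tables(params)

    # One sequential noise stream per run: chunking cannot change the values.
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2**31), 0x7E4B]))
    max_slice = 1000  # steps per kernel call; bounds the noise buffer

    def current_config(step: int) -> Configuration:
        return Configuration(pos.copy(), chain.copy(), bonds.copy(), time=step * dt)

    def setup_compaction(step: int) -> None:
        nonlocal plane, use_plane, plane_point, plane_normal, contour
        plane = compute_inhibition_plane(current_config(step))
        plane_point = plane.point
        plane_normal = plane.normal
        use_plane = mode == 1
        if schedule.compaction_mode == "spreading":
            origins = _spreading_origins(current_config(step), plane, schedule.spreading_origin)
            contour = contour_distances(bonds, n, origins)
            logger.info("t=%.1f tau: spreading compaction begins at origins %s", step * dt, origins)
        else:
            logger.info(
                "t=%.1f tau: %s compaction begins, inhibition plane normal %s",
                step * dt, schedule.compaction_mode, np.round(plane_normal, 3),
            )

    logger.info(
        "run_protocol: mode=%s, %d beads, R=%.2f sigma, %d steps, seed=%d",
        schedule.compaction_mode, n, params.R_vesicle, steps_total, seed,
    )
    snapshots = [current_config(0)]
    if steps_total == 0:
        return RunResult(snapshots, schedule, params, seed)

    if step_relax == 0 and mode != 0:
        setup_compaction(0)

    step = 0
    for end in boundaries:
        # During a chunk with no attraction only overlapping pairs (r < sigma)
        # exert pair forces, so the pair list can use the tight cutoff.
        entropic_chunk = mode == 0 or end * dt <= schedule.t_relax
        force_cut = params.sigma if entropic_chunk else params.r_att
        # Dense compacted phases favor a thin skin (smaller pair list);
        # dilute entropic phases favor a thick one (fewer rebuilds).
        chunk_skin = skin if entropic_chunk else 1.5 * params.sigma
        sub = step
        while sub < end:
            n_steps = min(end - sub, max_slice)
            kicks = params.noise_amplitude * rng.standard_normal((n_steps, n, 3))
            status, at = _kernels.advance(
                pos, chain, nxt, prv, contour,
                sub, n_steps, dt, dt / params.gamma, kicks,
                params.E_cross, params.sigma, params.r_att, params.k_bond, params.r0_bond,
                params.k_wall, params.R_vesicle, params.eps_mem, params.r_mem, params.eps_max,
                mode, schedule.t_relax, schedule.t_ramp, schedule.t_membrane_on,
                schedule.spreading_speed,
                use_plane, plane_point, plane_normal,
                force_cut, chunk_skin, pairs_i, pairs_j,
                frep_tab, fatt_tab, fmem_tab,
            )
            if status == _kernels.STATUS_ESCAPE:
                raise InstabilityError(
                    f"bead escaped beyond R_vesicle + sigma at step {at} (t={at * dt:.3f} tau)",
                    step=at,
                )
            if status == _kernels.STATUS_OVERFLOW:
                raise InstabilityError(f"neighbor-list overflow at step {at}", step=at)
            sub += n_steps
        if end > step:
            if not np.all(np.isfinite(pos)):
                raise InstabilityError(f"non-finite position by step {end}", step=end)
            _check_bonds(pos, bonds, params, end)
        step = end
        if step == step_relax and mode != 0 and plane is None:
            setup_compaction(step)
        if step in plane_steps and plane is not None and mode == 1:
            plane = compute_inhibition_plane(current_config(step))
            plane_point, plane_normal = plane.point, plane.normal
        if step in snapshot_steps:
            snapshots.append(current_config(step))

    return RunResult(snapshots, schedule, params, seed)


def _check_bonds(pos: np.ndarray, bonds: np.ndarray, params: SimulationParameters, step: int) -> None:
    lengths = np.linalg.norm(pos[bonds[:, 1]] - pos[bonds[:, 0]], axis=1)
    worst = float(lengths.max())
    if worst >= 2.0 * params.sigma:
        raise InstabilityError(
            f"bond stretched to {worst:.3f} sigma (>= 2 sigma) by step {step}", step=step
        )


def _spreading_origins(config: Configuration, plane: Plane, origin_spec) -> list[int]:
    """One origin bead per chain: the stated index, or the bead farthest
    from the inhibition plane (orienting the initiating sites away from the
    future division plane)."""
    origins = []
    for code in (CHAIN_A, CHAIN_B):
        members = config.beads_of(code)
        if origin_spec == "auto":
            dist = np.abs(plane.signed_distance(config.positions[members]))
            origins.append(int(members[int(np.argmax(dist))]))
        else:
            origins.append(int(members[int(origin_spec) % members.size]))
    return origins
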