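"""Reduced-unit physical model of two circular chromosomes in a spherical vesicle.

The system is a pair of ring bead-spring polymers confined in a rigid sphere
(the vesicle).  Reduced units throughout: the bead diameter ``sigma``, the
thermal energy ``kT`` and the per-bead friction ``gamma`` are all 1, so the
natural time unit is ``tau = gamma * sigma**2 / kT = 1``.

All interactions are bounded and C^1 in the pair distance:

* **Soft-core repulsion** ``U_rep(r) = E_cross * (1 + cos(pi r / sigma))`` for
  ``r < sigma``, zero beyond.  Finite at contact (``2 E_cross`` at ``r = 0``),
  so two DNA strands can pass through one another at a finite energy cost —
  a coarse proxy for topoisomerase-II strand passage.
* **Compaction attraction**: a plateau-bottomed cosine well of depth ``eps``:
  ``-eps`` for ``r <= sigma``, ``-(eps/2)(1 + cos(pi (r-sigma)/(r_att-sigma)))``
  for ``sigma <= r < r_att``, zero beyond.  The flat continuation below
  ``sigma`` keeps the total pair potential continuous where the soft core
  takes over.
* **Harmonic bonds** along each ring, ``(k_bond/2)(r - r0_bond)^2``.
* **Confining wall**: radial harmonic push ``(k_wall/2)(|x| - R)^2`` outside
  the vesicle radius, zero inside.
* **Membrane adhesion**: a cosine well of depth ``eps_mem`` in the shell
  ``[R - r_mem, R]``, minimum at the wall, switched on only late in a run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np

from .errors import ConfigurationInvariantError, InvalidParameterError

CHAIN_A = 0
CHAIN_B = 1
CHAIN_LABELS = ("A", "B")


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class SimulationParameters:
    """Force-field and dynamics constants in reduced units.

    ``sigma`` (bead diameter), ``kT`` and ``gamma`` define the unit system;
    changing them rescales, it does not change the physics.  ``dt`` must be
    small enough that the largest deterministic single-step displacement at
    the soft-core force cap, ``dt * pi * E_cross / (gamma * sigma)``, stays
    below ``0.1 * sigma``.
    """

    sigma: float = 1.0
    kT: float = 1.0
    gamma: float = 1.0
    dt: float = 0.0025
    E_cross: float = 5.0
    k_bond: float = 100.0
    r0_bond: float = 1.0
    eps_max: float = 1.0
    r_att: float = 1.5
    k_wall: float = 100.0
    eps_mem: float = 1.0
    r_mem: float = 1.0
    R_vesicle: float = 7.937005259840998  # 2 x 200 beads at phi = 0.10
    n_beads_per_ring: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "sigma", "kT", "gamma", "dt", "E_cross", "k_bond", "r0_bond",
            "eps_max", "r_att", "k_wall", "eps_mem", "r_mem", "R_vesicle",
        )
        for name in positive:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise InvalidParameterError(f"{name} must be a positive finite number, got {value!r}")
        if self.r_att <= self.sigma:
            raise InvalidParameterError(
                f"r_att must exceed sigma (got r_att={self.r_att}, sigma={self.sigma})"
            )
        if self.n_beads_per_ring < 8:
            raise InvalidParameterError(
                f"n_beads_per_ring must be >= 8, got {self.n_beads_per_ring}"
            )
        # Largest deterministic displacement for a force at the repulsion cap.
        cap_force = math.pi * self.E_cross / self.sigma
        if self.dt * cap_force / self.gamma >= 0.1 * self.sigma:
            raise InvalidParameterError(
                f"dt={self.dt} too large: step displacement at the soft-core force cap "
                f"is {self.dt * cap_force / self.gamma:.4g}, must stay below {0.1 * self.sigma:.4g}"
            )

    @property
    def tau(self) -> float:
        """Natural Brownian time unit gamma*sigma^2/kT."""
        return self.gamma * self.sigma**2 / self.kT

    @property
    def n_beads_total(self) -> int:
        return 2 * self.n_beads_per_ring

    @property
    def noise_amplitude(self) -> float:
        """Standard deviation of the per-coordinate thermal kick per step."""
        return math.sqrt(2.0 * self.kT * self.dt / self.gamma)

    def with_(self, **changes) -> "SimulationParameters":
        return replace(self, **changes)

    @classmethod
    def for_volume_fraction(cls, phi: float, **kwargs) -> "SimulationParameters":
        """Parameters with ``R_vesicle`` set so the beads occupy fraction ``phi``."""
        probe = cls(**kwargs)
        radius = vesicle_radius_from_volume_fraction(probe.n_beads_total, phi, probe.sigma)
        return probe.with_(R_vesicle=radius)


def vesicle_radius_from_volume_fraction(n_total_beads: int, phi: float, sigma: float = 1.0) -> float:
    """Vesicle radius R such that n beads of diameter sigma fill fraction phi.

    Bead volume is taken as (pi/6) sigma^3, hence R = sigma * (n / (8 phi))**(1/3).
    """
    if n_total_beads < 1:
        raise InvalidParameterError(f"n_total_beads must be >= 1, got {n_total_beads}")
    if not (0.0 < phi < 0.4):
        raise InvalidParameterError(f"phi must lie in (0, 0.4), got {phi}")
    return sigma * (n_total_beads / (8.0 * phi)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class Configuration:
    """Bead coordinates, chain labels, ring-bond topology, and elapsed time.

    ``chain_id`` holds 0 for chain A and 1 for chain B.  ``bonds`` is an
    (n_bonds, 2) integer array whose graph must consist of exactly two
    disjoint cycles, one per chain.
    """

    positions: np.ndarray
    chain_id: np.ndarray
    bonds: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.chain_id = np.asarray(self.chain_id, dtype=np.int8)
        self.bonds = np.asarray(self.bonds, dtype=np.int64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ConfigurationInvariantError(
                f"positions must be (M, 3), got shape {self.positions.shape}"
            )
        if self.chain_id.shape != (self.positions.shape[0],):
            raise ConfigurationInvariantError("chain_id must have one entry per bead")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def beads_of(self, chain) -> np.ndarray:
        """Indices of the beads belonging to chain 'A'/'B' (or 0/1)."""
        code = _chain_code(chain)
        return np.flatnonzero(self.chain_id == code)

    def com(self, chain=None) -> np.ndarray:
        """Center of mass of one chain (or of everything)."""
        if chain is None:
            return self.positions.mean(axis=0)
        idx = self.beads_of(chain)
        if idx.size == 0:
            raise ConfigurationInvariantError(f"chain {chain!r} has no beads")
        return self.positions[idx].mean(axis=0)

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(), self.chain_id.copy(), self.bonds.copy(), self.time
        )

    def validate(self, R_vesicle: float | None = None, sigma: float = 1.0) -> None:
        """Check all structural invariants; raise ConfigurationInvariantError."""
        if not np.all(np.isfinite(self.positions)):
            raise ConfigurationInvariantError("non-finite bead position")
        labels = np.unique(self.chain_id)
        if not np.array_equal(labels, [CHAIN_A, CHAIN_B]):
            raise ConfigurationInvariantError(
                f"chain_id must contain both chains A(0) and B(1), got labels {labels}"
            )
        _validate_two_rings(self.bonds, self.chain_id)
        if R_vesicle is not None:
            radii = np.linalg.norm(self.positions, axis=1)
            worst = radii.max()
            if worst > R_vesicle + 0.5 * sigma:
                raise ConfigurationInvariantError(
                    f"bead at radius {worst:.4g} exceeds R_vesicle + sigma/2 = "
                    f"{R_vesicle + 0.5 * sigma:.4g}"
                )


def _chain_code(chain) -> int:
    if chain in (CHAIN_A, CHAIN_B):
        return int(chain)
    if isinstance(chain, str) and chain.upper() in CHAIN_LABELS:
        return CHAIN_LABELS.index(chain.upper())
    raise ConfigurationInvariantError(f"unknown chain label {chain!r}")


def _validate_two_rings(bonds: np.ndarray, chain_id: np.ndarray) -> None:
    n = chain_id.shape[0]
    if bonds.ndim != 2 or bonds.shape[1] != 2:
        raise ConfigurationInvariantError("bonds must be an (n_bonds, 2) array")
    if bonds.shape[0] != n:
        raise ConfigurationInvariantError(
            f"two rings over {n} beads need exactly {n} bonds, got {bonds.shape[0]}"
        )
    if bonds.min(initial=0) < 0 or bonds.max(initial=-1) >= n:
        raise ConfigurationInvariantError("bond index out of range")
    if np.any(chain_id[bonds[:, 0]] != chain_id[bonds[:, 1]]):
        raise ConfigurationInvariantError("a bond connects beads of different chains")
    # Degree 2 everywhere.
    degree = np.zeros(n, dtype=np.int64)
    np.add.at(degree, bonds[:, 0], 1)
    np.add.at(degree, bonds[:, 1], 1)
    if np.any(degree != 2):
        bad = int(np.flatnonzero(degree != 2)[0])
        raise ConfigurationInvariantError(f"bead {bad} has bond degree {degree[bad]} != 2")
    # Each chain must be a single cycle: walk it.
    nxt, prv = ring_neighbor_arrays(bonds, n)
    for code in (CHAIN_A, CHAIN_B):
        members = np.flatnonzero(chain_id == code)
        start = int(members[0])
        seen = 1
        node = int(nxt[start])
        while node != start:
            if chain_id[node] != code or seen > n:
                raise ConfigurationInvariantError(
                    f"bond graph of chain {CHAIN_LABELS[code]} is not a single cycle"
                )
            seen += 1
            node = int(nxt[node])
        if seen != members.size:
            raise ConfigurationInvariantError(
                f"chain {CHAIN_LABELS[code]} splits into more than one cycle"
            )


def ring_neighbor_arrays(bonds: np.ndarray, n_beads: int):
    """Per-bead successor/predecessor arrays for a set of disjoint cycles.

    Orientation is arbitrary but consistent: following ``nxt`` from any bead
    traverses its whole ring exactly once.
    """
    neighbors = [[] for _ in range(n_beads)]
    for i, j in np.asarray(bonds, dtype=np.int64):
        neighbors[int(i)].append(int(j))
        neighbors[int(j)].append(int(i))
    nxt = np.full(n_beads, -1, dtype=np.int64)
    prv = np.full(n_beads, -1, dtype=np.int64)
    for start in range(n_beads):
        if nxt[start] != -1:
            continue
        if len(neighbors[start]) != 2:
            raise ConfigurationInvariantError(f"bead {start} has degree {len(neighbors[start])}")
        prev, node = start, neighbors[start][0]
        while True:
            nxt[prev] = node
            prv[node] = prev
            if node == start:
                break
            a, b = neighbors[node]
            prev, node = node, (b if a == prev else a)
    return nxt, prv


def ring_bonds(n_a: int, n_b: int) -> np.ndarray:
    """Cyclic bonds for chain A on beads [0, n_a) and chain B on [n_a, n_a+n_b)."""
    out = []
    for offset, n in ((0, n_a), (n_a, n_b)):
        for k in range(n):
            out.append((offset + k, offset + (k + 1) % n))
    return np.asarray(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# plane


@dataclass(frozen=True)
class Plane:
    """Oriented plane: a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", np.asarray(self.normal, dtype=float))
        if self.point.shape != (3,) or self.normal.shape != (3,):
            raise InvalidParameterError("plane point and normal must be 3-vectors")
        norm = float(np.linalg.norm(self.normal))
        if abs(norm - 1.0) > 1e-9:
            raise InvalidParameterError(f"plane normal must be unit length, |n|={norm}")

    def signed_distance(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.point) @ self.normal


# ---------------------------------------------------------------------------
# pair interactions (scalar/array forms; the compiled kernel re-implements
# these inline — tests pin the two against each other via finite differences)


def soft_core_energy(r, E_cross: float, sigma: float = 1.0):
    """Bounded repulsion E_cross*(1+cos(pi r/sigma)) for r < sigma, else 0."""
    r = np.asarray(r, dtype=float)
    return np.where(r < sigma, E_cross * (1.0 + np.cos(np.pi * np.minimum(r, sigma) / sigma)), 0.0)


def soft_core_force(r, E_cross: float, sigma: float = 1.0):
    """-dU/dr of the soft core; positive = repulsive. Finite everywhere."""
    r = np.asarray(r, dtype=float)
    return np.where(r < sigma, E_cross * np.pi / sigma * np.sin(np.pi * np.minimum(r, sigma) / sigma), 0.0)


def attraction_energy(r, eps: float, sigma: float = 1.0, r_att: float = 1.5):
    """Plateau-bottomed cosine well: -eps below sigma, 0 beyond r_att."""
    r = np.asarray(r, dtype=float)
    w = r_att - sigma
    u = np.clip((r - sigma) / w, 0.0, 1.0)
    return -(eps / 2.0) * (1.0 + np.cos(np.pi * u))


def attraction_force(r, eps: float, sigma: float = 1.0, r_att: float = 1.5):
    """-dU/dr of the attraction well; negative (pulls inward) on (sigma, r_att)."""
    r = np.asarray(r, dtype=float)
    w = r_att - sigma
    inside = (r > sigma) & (r < r_att)
    u = (np.asarray(r) - sigma) / w
    return np.where(inside, -(eps * np.pi / (2.0 * w)) * np.sin(np.pi * np.clip(u, 0.0, 1.0)), 0.0)


def pair_energy(r, params: SimulationParameters, attraction_on: bool = False, eps_now: float = 0.0):
    """Total nonbonded pair energy at separation r (kT)."""
    total = soft_core_energy(r, params.E_cross, params.sigma)
    if attraction_on and eps_now > 0.0:
        total = total + attraction_energy(r, eps_now, params.sigma, params.r_att)
    return total


def pair_force(r, params: SimulationParameters, attraction_on: bool = False, eps_now: float = 0.0):
    """-dU/dr of the total nonbonded pair interaction (positive = repulsive)."""
    total = soft_core_force(r, params.E_cross, params.sigma)
    if attraction_on and eps_now > 0.0:
        total = total + attraction_force(r, eps_now, params.sigma, params.r_att)
    return total


# ---------------------------------------------------------------------------
# bonded, wall and membrane terms


def bond_forces(config: Configuration, params: SimulationParameters) -> np.ndarray:
    """Per-bead harmonic bond forces; sums to zero over the system."""
    i = config.bonds[:, 0]
    j = config.bonds[:, 1]
    d = config.positions[j] - config.positions[i]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-12):
        # Coincident bonded beads: direction undefined, zero force (finite).
        safe = np.maximum(r, 1e-12)
    else:
        safe = r
    f = (params.k_bond * (r - params.r0_bond) / safe)[:, None] * d
    out = np.zeros_like(config.positions)
    np.add.at(out, i, f)
    np.add.at(out, j, -f)
    return out


def bond_energy(config: Configuration, params: SimulationParameters) -> float:
    i, j = config.bonds[:, 0], config.bonds[:, 1]
    r = np.linalg.norm(config.positions[j] - config.positions[i], axis=1)
    return float(0.5 * params.k_bond * np.sum((r - params.r0_bond) ** 2))


def confinement_energy(position, R_vesicle: float, k_wall: float):
    s = np.linalg.norm(np.atleast_2d(position), axis=1)
    over = np.maximum(s - R_vesicle, 0.0)
    return 0.5 * k_wall * over**2


def confinement_force(position, R_vesicle: float, k_wall: float) -> np.ndarray:
    """Inward radial harmonic push outside the vesicle, zero inside."""
    x = np.atleast_2d(np.asarray(position, dtype=float))
    s = np.linalg.norm(x, axis=1)
    over = np.maximum(s - R_vesicle, 0.0)
    safe = np.maximum(s, 1e-12)
    out = -(k_wall * over / safe)[:, None] * x
    return out[0] if np.asarray(position).ndim == 1 else out


def membrane_adhesion_energy(position, params: SimulationParameters, active: bool = True):
    x = np.atleast_2d(np.asarray(position, dtype=float))
    s = np.linalg.norm(x, axis=1)
    if not active:
        return np.zeros_like(s)
    R, rm, eps = params.R_vesicle, params.r_mem, params.eps_mem
    u = np.clip((R - s) / rm, 0.0, 1.0)  # 0 at the wall, 1 at inner edge
    return -(eps / 2.0) * (1.0 + np.cos(np.pi * u))


def membrane_adhesion_force(position, params: SimulationParameters, active: bool = True) -> np.ndarray:
    """Outward radial pull toward the wall inside the adhesion shell."""
    x = np.atleast_2d(np.asarray(position, dtype=float))
    s = np.linalg.norm(x, axis=1)
    out = np.zeros_like(x)
    if active:
        R, rm, eps = params.R_vesicle, params.r_mem, params.eps_mem
        shell = (s > R - rm) & (s < R) & (s > 1e-12)
        mag = np.zeros_like(s)
        mag[shell] = (0.5 * eps * np.pi / rm) * np.sin(np.pi * (R - s[shell]) / rm)
        out = (mag / np.maximum(s, 1e-12))[:, None] * x
    return out[0] if np.asarray(position).ndim == 1 else out
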