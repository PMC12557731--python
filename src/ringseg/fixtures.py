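"""Deterministic generators of initial states and ground-truth test configurations.

Everything here is a pure function of its arguments (including the seed):
the mixed compact two-ring initial state the protocol starts from, perfectly
segregated reference pairs, single rings, and Gaussian point clouds with a
closed-form discriminability for calibrating the efficiency metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import _kernels
from .errors import GenerationError, InvalidParameterError
from .model import (
    CHAIN_A,
    CHAIN_B,
    Configuration,
    SimulationParameters,
    ring_bonds,
    ring_neighbor_arrays,
    vesicle_radius_from_volume_fraction,
)


class RingFragment(NamedTuple):
    """A single ring: positions plus its (local-index) cyclic bonds."""

    positions: np.ndarray
    bonds: np.ndarray


FIXTURE_KINDS = ("ring", "mixed_compact", "segregated_pair", "gaussian_blobs")


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a named fixture."""

    kind: str
    n_beads: int = 100
    phi: float = 0.10
    separation: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise InvalidParameterError(f"unknown fixture kind {self.kind!r}")
        if self.kind == "gaussian_blobs":
            if self.n_beads < 10:
                raise InvalidParameterError("gaussian_blobs needs n_beads >= 10 per class")
        elif self.n_beads < 8:
            raise InvalidParameterError(f"{self.kind} needs n_beads >= 8 per ring")
        if self.kind in ("mixed_compact",) and not (0.0 < self.phi < 0.4):
            raise InvalidParameterError(f"phi={self.phi} outside (0, 0.4)")
        if self.kind == "segregated_pair" and self.separation <= 0:
            raise InvalidParameterError("separation must be positive")


def make_fixture(spec: FixtureSpec):
    """Build the object a FixtureSpec describes.

    Returns a RingFragment for ``ring``, a Configuration for
    ``mixed_compact`` / ``segregated_pair``, and ``(points, labels)`` for
    ``gaussian_blobs``.
    """
    if spec.kind == "ring":
        return make_ring(spec.n_beads, ring_radius=spec.n_beads / (2 * np.pi))
    params = SimulationParameters.for_volume_fraction(
        spec.phi, n_beads_per_ring=spec.n_beads
    )
    if spec.kind == "mixed_compact":
        return make_mixed_compact_init(params, spec.phi, spec.seed)
    if spec.kind == "segregated_pair":
        return make_segregated_pair(params, spec.separation, spec.seed)
    return make_gaussian_blobs(spec.separation, 1.0, spec.n_beads, spec.seed)


def make_ring(n: int, ring_radius: float, center=(0.0, 0.0, 0.0)) -> RingFragment:
    """n beads equally spaced on a circle in the xy-plane, cyclically bonded."""
    if n < 8:
        raise InvalidParameterError(f"a ring needs at least 8 beads, got {n}")
    theta = 2.0 * np.pi * np.arange(n) / n
    pos = np.column_stack(
        [ring_radius * np.cos(theta), ring_radius * np.sin(theta), np.zeros(n)]
    ) + np.asarray(center, dtype=float)
    bonds = np.column_stack([np.arange(n), (np.arange(n) + 1) % n]).astype(np.int64)
    return RingFragment(pos, bonds)


def _closed_random_walk(n: int, step_length: float, rng: np.random.Generator) -> np.ndarray:
    """A closed (Brownian-bridge) random walk of n beads with ~step_length bonds."""
    steps = rng.standard_normal((n, 3))
    steps -= steps.mean(axis=0)
    scale = step_length / np.sqrt(np.mean(np.sum(steps**2, axis=1)))
    steps *= scale
    pos = np.vstack([np.zeros(3), np.cumsum(steps[:-1], axis=0)])
    return pos - pos.mean(axis=0)


def _squeeze_into_ball(pos: np.ndarray, radius: float) -> np.ndarray:
    extent = float(np.linalg.norm(pos, axis=1).max())
    if extent > radius:
        pos = pos * (radius / extent)
    return pos


def make_mixed_compact_init(
    params: SimulationParameters, phi: float, seed: int
) -> Configuration:
    """Two intermixed compact rings in a ball of half the vesicle radius.

    Each ring is grown as a closed random walk, both centered on the origin,
    squeezed into radius 0.5*R(phi), then briefly relaxed (bonds + soft core
    + tight confinement, crossing allowed) to remove pathological overlaps.
    The result is "compact and mixed": its segregation efficiency is < 0.3.
    """
    n = params.n_beads_per_ring
    R = vesicle_radius_from_volume_fraction(2 * n, phi, params.sigma)
    r_conf = 0.5 * R
    bonds = ring_bonds(n, n)
    chain_id = np.repeat([CHAIN_A, CHAIN_B], n).astype(np.int8)

    from .metrics import lda_efficiency  # local import to avoid a cycle

    ss = np.random.SeedSequence([int(seed) % (2**31), 0x5EED])
    for attempt, child in enumerate(ss.spawn(6)):
        rng = np.random.default_rng(child)
        frags = [
            _squeeze_into_ball(
                _closed_random_walk(n, params.r0_bond, rng), 0.93 * r_conf
            )
            for _ in range(2)
        ]
        pos = np.ascontiguousarray(np.vstack(frags), dtype=np.float64)
        _relax_in_place(pos, bonds, params, r_conf, t_relax=15.0,
                        kernel_seed=int(child.generate_state(1)[0] % (2**31)))
        # Re-superpose the chain centers of mass: the generated state should be
        # mixed, and COM offsets picked up during relaxation are trivially
        # separable by the efficiency metric.
        pos[:n] -= pos[:n].mean(axis=0)
        pos[n:] -= pos[n:].mean(axis=0)
        config = Configuration(pos, chain_id, bonds, time=0.0)
        if lda_efficiency(pos, chain_id) < 0.3:
            config.validate(R_vesicle=R, sigma=params.sigma)
            return config
    raise GenerationError(
        f"could not generate a mixed compact state with efficiency < 0.3 (seed {seed})"
    )


def _relax_in_place(
    pos: np.ndarray,
    bonds: np.ndarray,
    params: SimulationParameters,
    r_confine: float,
    t_relax: float,
    kernel_seed: int,
) -> None:
    """Short crossing-allowed relaxation inside a tight confining sphere."""
    from .engine import force_tables

    n = pos.shape[0]
    nxt, prv = ring_neighbor_arrays(bonds, n)
    contour = np.zeros(n, dtype=np.int64)
    frep_tab, fatt_tab, fmem_tab = force_tables(params)
    cap = max(4096, n * 256)
    pairs_i = np.empty(cap, dtype=np.int32)
    pairs_j = np.empty(cap, dtype=np.int32)
    rng = np.random.default_rng(np.random.SeedSequence([int(kernel_seed), 0x11117]))
    n_steps = int(round(t_relax / params.dt))
    step = 0
    while step < n_steps:
        m = min(1000, n_steps - step)
        kicks = params.noise_amplitude * rng.standard_normal((m, n, 3))
        status, at = _kernels.advance(
            pos, np.zeros(n, dtype=np.int8), nxt, prv, contour,
            step, m, params.dt, params.dt / params.gamma, kicks,
            params.E_cross, params.sigma, params.r_att, params.k_bond, params.r0_bond,
            params.k_wall, r_confine, params.eps_mem, params.r_mem, params.eps_max,
            0, np.inf, 1.0, np.inf, 0.0,
            False, np.zeros(3), np.array([0.0, 0.0, 1.0]),
            params.sigma, 1.25 * params.sigma, pairs_i, pairs_j,
            frep_tab, fatt_tab, fmem_tab,
        )
        if status != _kernels.STATUS_OK:
            raise GenerationError(f"pre-relaxation failed with status {status} at step {at}")
        step += m


def make_segregated_pair(
    params: SimulationParameters, separation: float, seed: int = 0
) -> Configuration:
    """Two compact rings with COMs ``separation`` apart along +x, disjoint in x.

    Each ring is a crumpled closed walk confined to a ball of radius
    0.25*R_vesicle; ``separation`` must exceed twice that blob radius.
    """
    n = params.n_beads_per_ring
    R = params.R_vesicle
    blob_radius = 0.25 * R
    if separation <= 2.0 * blob_radius:
        raise InvalidParameterError(
            f"separation {separation} must exceed twice the blob radius {blob_radius:.3f}"
        )
    if 0.5 * separation + blob_radius > R + 0.5 * params.sigma:
        raise InvalidParameterError(
            f"separation {separation} would push the blobs outside the vesicle"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 0xB10B]))
    offsets = (np.array([+0.5 * separation, 0.0, 0.0]), np.array([-0.5 * separation, 0.0, 0.0]))
    frags = []
    for offset in offsets:
        blob = _squeeze_into_ball(_closed_random_walk(n, params.r0_bond, rng), 0.999 * blob_radius)
        blob = blob - blob.mean(axis=0)
        blob = _squeeze_into_ball(blob, 0.999 * blob_radius)
        frags.append(blob + offset)
    config = Configuration(
        np.vstack(frags),
        np.repeat([CHAIN_A, CHAIN_B], n).astype(np.int8),
        ring_bonds(n, n),
        time=0.0,
    )
    config.validate(R_vesicle=R, sigma=params.sigma)
    return config


def make_gaussian_blobs(
    mean_separation: float, sd: float, n_per_class: int, seed: int = 0
):
    """Two isotropic 3-D Gaussian clouds with means ``mean_separation`` apart.

    Returns ``(points, labels)``.  The Bayes-optimal linear rule gives a
    balanced accuracy Phi(separation / (2 sd)), so the expected efficiency is
    2*Phi(separation/(2 sd)) - 1 — a closed-form calibration target.
    """
    if n_per_class < 10:
        raise InvalidParameterError(f"n_per_class must be >= 10, got {n_per_class}")
    if sd <= 0:
        raise InvalidParameterError("sd must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 0xB10B5]))
    half = np.array([0.5 * mean_separation, 0.0, 0.0])
    a = rng.normal(loc=+half, scale=sd, size=(n_per_class, 3))
    b = rng.normal(loc=-half, scale=sd, size=(n_per_class, 3))
    points = np.vstack([a, b])
    labels = np.repeat([CHAIN_A, CHAIN_B], n_per_class).astype(np.int8)
    return points, labels


def mixed_compact_system(
    phi: float, n_beads_per_ring: int = 200, seed: int = 0, **param_overrides
):
    """Convenience: matched (params, initial configuration) for a volume fraction."""
    params = SimulationParameters.for_volume_fraction(
        phi, n_beads_per_ring=n_beads_per_ring, **param_overrides
    )
    return params, make_mixed_compact_init(params, phi, seed)
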