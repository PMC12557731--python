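"""Interaction terms, geometry and configuration invariants."""

import numpy as np
import pytest

from ringseg.errors import ConfigurationInvariantError, InvalidParameterError
from ringseg.model import (
    Configuration,
    Plane,
    SimulationParameters,
    bond_forces,
    confinement_force,
    membrane_adhesion_energy,
    membrane_adhesion_force,
    pair_energy,
    pair_force,
    ring_bonds,
    vesicle_radius_from_volume_fraction,
)


class TestParameters:
    def test_defaults_valid(self):
        SimulationParameters()

    @pytest.mark.parametrize(
        "bad",
        [dict(sigma=-1), dict(kT=0), dict(E_cross=-2), dict(n_beads_per_ring=4),
         dict(r_att=0.9), dict(dt=0.05)],
    )
    def test_invalid_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            SimulationParameters(**bad)

    def test_dt_cap_scales_with_crossing_penalty(self):
        # the largest allowed dt shrinks as the soft-core cap grows
        SimulationParameters(E_cross=5.0, dt=0.006)
        with pytest.raises(InvalidParameterError):
            SimulationParameters(E_cross=500.0, dt=0.006)
        SimulationParameters(E_cross=500.0, dt=5e-5)


class TestVesicleRadius:
    def test_reference_value(self):
        # (400 / (8*0.10))**(1/3)
        assert vesicle_radius_from_volume_fraction(400, 0.10) == pytest.approx(
            7.937, abs=1e-3
        )

    def test_monotone_in_phi(self):
        assert vesicle_radius_from_volume_fraction(400, 0.05) > vesicle_radius_from_volume_fraction(
            400, 0.20
        )

    @pytest.mark.parametrize("phi", [0.0, -0.1, 0.4, 1.0])
    def test_phi_out_of_range(self, phi):
        with pytest.raises(InvalidParameterError):
            vesicle_radius_from_volume_fraction(400, phi)

    def test_definition_recovers_volume_fraction(self):
        n, phi = 314, 0.17
        R = vesicle_radius_from_volume_fraction(n, phi)
        assert n * (np.pi / 6) / ((4 / 3) * np.pi * R**3) == pytest.approx(phi)


class TestPairInteraction:
    params = SimulationParameters()

    def test_zero_beyond_cutoffs(self):
        r = np.array([1.5, 1.7, 5.0])
        assert np.all(pair_energy(r, self.params, True, 1.0) == 0.0)
        assert np.all(pair_force(r, self.params, True, 1.0) == 0.0)

    def test_finite_cap_at_contact(self):
        assert pair_energy(0.0, self.params) == pytest.approx(2 * self.params.E_cross)
        assert pair_force(0.0, self.params) == pytest.approx(0.0)

    def test_half_sigma_value(self):
        assert pair_energy(0.5, self.params) == pytest.approx(5.0)

    def test_attraction_well_depth_and_continuity(self):
        p = self.params
        # plateau depth -eps below sigma, continuous across sigma
        assert pair_energy(1.0, p, True, 1.0) == pytest.approx(-1.0)
        assert pair_energy(0.999999, p, True, 1.0) == pytest.approx(
            pair_energy(1.000001, p, True, 1.0), abs=1e-4
        )

    def test_force_is_minus_energy_gradient(self, rng):
        """Analytic forces match centered finite differences at 100 random radii."""
        p = self.params
        h = 1e-6
        kinks = np.array([p.sigma, p.r_att])
        r = rng.uniform(0.01, 2.0, size=200)
        r = r[np.min(np.abs(r[:, None] - kinks[None, :]), axis=1) > 1e-3][:100]
        assert len(r) == 100
        for eps_now, att in ((0.0, False), (0.7, True)):
            num = -(pair_energy(r + h, p, att, eps_now) - pair_energy(r - h, p, att, eps_now)) / (2 * h)
            ana = pair_force(r, p, att, eps_now)
            scale = np.maximum(np.abs(ana), np.abs(num))
            ok = scale < 1e-12
            assert np.all(ok | (np.abs(num - ana) / np.where(ok, 1.0, scale) < 1e-5))

    def test_membrane_force_matches_gradient_and_examples(self):
        p = self.params
        R, rm = p.R_vesicle, p.r_mem
        # inactive -> zero
        assert np.allclose(membrane_adhesion_force([1.0, 2.0, 3.0], p, active=False), 0.0)
        # minimum at the wall -> zero radial force
        at_wall = np.array([R, 0.0, 0.0])
        assert np.allclose(membrane_adhesion_force(at_wall, p, active=True), 0.0, atol=1e-9)
        # mid-shell magnitude pi*eps/(2*r_mem), pointing outward
        mid = np.array([R - rm / 2, 0.0, 0.0])
        f = membrane_adhesion_force(mid, p, active=True)
        assert f[0] == pytest.approx(np.pi * p.eps_mem / (2 * rm))
        # finite differences along the radius
        for s in np.linspace(R - 0.9 * rm, R - 0.1 * rm, 7):
            h = 1e-6
            e_plus = membrane_adhesion_energy([s + h, 0, 0], p)[0]
            e_minus = membrane_adhesion_energy([s - h, 0, 0], p)[0]
            f = membrane_adhesion_force([s, 0, 0], p)[0]
            assert f == pytest.approx(-(e_plus - e_minus) / (2 * h), rel=1e-5, abs=1e-8)

    def test_crossing_possible_only_below_bias_threshold(self):
        """A driven bead passes a fixed obstacle iff the drive exceeds the
        soft-core force cap pi*E_cross/sigma; a 100x penalty blocks it."""

        def drive_through(e_cross, bias):
            p = SimulationParameters(E_cross=e_cross, dt=5e-5)
            x = -2.0
            for _ in range(200_000):
                f = pair_force(abs(x), p) * np.sign(x)  # repulsion from origin
                x += p.dt * (bias + f)
                if x > 1.5:
                    return True
            return False

        cap = np.pi * 5.0
        assert drive_through(5.0, 1.1 * cap)
        assert not drive_through(500.0, 1.1 * cap)


class TestBondForces:
    params = SimulationParameters()

    def _two_ring_config(self, rng, n=12, spread=1.0):
        pos = rng.normal(scale=spread, size=(2 * n, 3))
        chain = np.repeat([0, 1], n)
        return Configuration(pos, chain, ring_bonds(n, n))

    def test_zero_at_rest_length(self):
        n = 16
        theta = 2 * np.pi * np.arange(n) / n
        radius = 1.0 / (2 * np.sin(np.pi / n))  # chord length exactly r0=1
        ring = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)])
        pos = np.vstack([ring, ring + [0, 0, 10.0]])
        cfg = Configuration(pos, np.repeat([0, 1], n), ring_bonds(n, n))
        assert np.allclose(bond_forces(cfg, self.params), 0.0, atol=1e-9)

    def test_hookes_law_pair(self):
        # two beads of one bond stretched by d feel equal and opposite k*d
        n = 8
        frag = np.zeros((n, 3))
        frag[:, 0] = np.arange(n) * 10.0  # bonds absurdly long except the probed one
        p = SimulationParameters(k_bond=100.0)
        d = 0.25
        pos = np.array([[0.0, 0, 0], [1.0 + d, 0, 0]])
        cfg = Configuration(
            np.vstack([pos, pos + [0, 0, 50.0], np.zeros((0, 3))]),
            np.repeat([0, 1], 2),
            np.array([[0, 1], [1, 0], [2, 3], [3, 2]]),
        )
        f = bond_forces(cfg, p)
        # both bonds of the 2-ring connect the same beads: force doubled
        assert f[0, 0] == pytest.approx(2 * p.k_bond * d)
        assert np.allclose(f[0], -f[1])

    def test_newtons_third_law_sum_zero(self, rng):
        for _ in range(5):
            cfg = self._two_ring_config(rng)
            total = bond_forces(cfg, self.params).sum(axis=0)
            assert np.allclose(total, 0.0, atol=1e-10)


class TestConfinement:
    def test_inside_zero_outside_linear_continuous(self):
        R, k = 5.0, 100.0
        assert np.allclose(confinement_force([0, 0, 2.5], R, k), 0.0)
        f = confinement_force([0, 0, R + 0.1], R, k)
        assert np.allclose(f, [0, 0, -10.0])
        assert np.allclose(confinement_force([0, 0, R], R, k), 0.0, atol=1e-9)


class TestConfiguration:
    def test_valid_two_rings(self):
        n = 10
        pos = np.random.default_rng(0).normal(size=(2 * n, 3))
        cfg = Configuration(pos, np.repeat([0, 1], n), ring_bonds(n, n))
        cfg.validate()

    def test_cross_chain_bond_rejected(self):
        n = 6
        bonds = ring_bonds(n, n)
        bonds[0] = [0, n]  # connects chain A to chain B
        cfg = Configuration(np.zeros((2 * n, 3)), np.repeat([0, 1], n), bonds)
        with pytest.raises(ConfigurationInvariantError):
            cfg.validate()

    def test_split_ring_rejected(self):
        # chain A as two 5-cycles instead of one 10-cycle
        bonds = []
        for off in (0, 5):
            for k in range(5):
                bonds.append((off + k, off + (k + 1) % 5))
        for k in range(10):
            bonds.append((10 + k, 10 + (k + 1) % 10))
        cfg = Configuration(
            np.zeros((20, 3)), np.repeat([0, 1], 10), np.array(bonds)
        )
        with pytest.raises(ConfigurationInvariantError):
            cfg.validate()

    def test_bead_outside_vesicle_rejected(self):
        n = 8
        pos = np.zeros((2 * n, 3))
        pos[3] = [7.0, 0, 0]
        cfg = Configuration(pos, np.repeat([0, 1], n), ring_bonds(n, n))
        with pytest.raises(ConfigurationInvariantError):
            cfg.validate(R_vesicle=5.0)
        cfg.validate(R_vesicle=7.0)


class TestPlane:
    def test_unit_normal_enforced(self):
        Plane(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(InvalidParameterError):
            Plane(np.zeros(3), np.array([0.0, 0.0, 1.1]))

    def test_signed_distance(self):
        pl = Plane(np.array([1.0, 0, 0]), np.array([1.0, 0, 0]))
        assert pl.signed_distance(np.array([[3.0, 5.0, -2.0]]))[0] == pytest.approx(2.0)
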