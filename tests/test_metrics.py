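"""Segregation metrics: endpoints, calibration, invariances, oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import norm

from ringseg.errors import InvalidParameterError
from ringseg.fixtures import make_gaussian_blobs, make_segregated_pair
from ringseg.metrics import (
    EnsembleResult,
    MetricsSeries,
    com_distance_normalized,
    ensemble_summary,
    lda_efficiency,
    radius_of_gyration,
    segregation_efficiency,
)
from ringseg.model import Configuration, SimulationParameters, ring_bonds


def brute_force_efficiency(points, labels):
    """Independent reference: explicit scatter-matrix loops, midpoint
    threshold, counting loop with the 0.5 tie rule."""
    points = np.asarray(points, float)
    classes = sorted(set(labels.tolist()))
    xa = np.array([p for p, l in zip(points, labels) if l == classes[0]])
    xb = np.array([p for p, l in zip(points, labels) if l == classes[1]])
    mu_a = xa.sum(axis=0) / len(xa)
    mu_b = xb.sum(axis=0) / len(xb)
    d = points.shape[1]
    scatter = np.zeros((d, d))
    for row in xa:
        c = row - mu_a
        scatter += np.outer(c, c)
    for row in xb:
        c = row - mu_b
        scatter += np.outer(c, c)
    pooled = scatter / (len(xa) + len(xb) - 2) + 1e-8 * np.eye(d)
    w = np.linalg.inv(pooled) @ (mu_a - mu_b)
    thr = 0.5 * (mu_a @ w + mu_b @ w)
    hits_a = sum(1.0 if row @ w > thr else (0.5 if row @ w == thr else 0.0) for row in xa)
    hits_b = sum(1.0 if row @ w < thr else (0.5 if row @ w == thr else 0.0) for row in xb)
    balanced = 0.5 * (hits_a / len(xa) + hits_b / len(xb))
    return max(0.0, 2 * balanced - 1)


def two_blob_config(rng, n=40, separation=0.0, sd=1.0):
    a = rng.normal(scale=sd, size=(n, 3)) + [separation / 2, 0, 0]
    b = rng.normal(scale=sd, size=(n, 3)) - [separation / 2, 0, 0]
    return Configuration(np.vstack([a, b]), np.repeat([0, 1], n), ring_bonds(n, n))


class TestEfficiencyEndpoints:
    def test_disjoint_half_spaces_give_one(self):
        params = SimulationParameters(n_beads_per_ring=100)
        cfg = make_segregated_pair(params, separation=8.0)
        assert cfg.positions[cfg.chain_id == 0, 0].min() > 1.0
        assert cfg.positions[cfg.chain_id == 1, 0].max() < -1.0
        assert segregation_efficiency(cfg) == 1.0

    def test_coincident_clouds_give_zero(self, rng):
        pts = rng.normal(size=(50, 3))
        cfg = Configuration(
            np.vstack([pts, pts]), np.repeat([0, 1], 50), ring_bonds(50, 50)
        )
        assert segregation_efficiency(cfg) == 0.0

    def test_gaussian_blob_calibration(self):
        """Two unit-sd clouds 2 sigma apart: efficiency = 2*Phi(1)-1 ~ 0.683."""
        pts, labels = make_gaussian_blobs(2.0, 1.0, 10_000, seed=3)
        expected = 2 * norm.cdf(1.0) - 1
        assert lda_efficiency(pts, labels) == pytest.approx(expected, abs=0.02)

    def test_zero_separation_is_chance_level(self):
        pts, labels = make_gaussian_blobs(0.0, 1.0, 10_000, seed=4)
        assert lda_efficiency(pts, labels) < 0.05

    def test_separable_limit(self):
        pts, labels = make_gaussian_blobs(50.0, 1.0, 200, seed=5)
        assert lda_efficiency(pts, labels) == 1.0


class TestEfficiencyOracles:
    def test_matches_brute_force_on_random_sets(self, rng):
        for k in range(50):
            n = int(rng.integers(5, 40))
            sep = rng.uniform(0, 3)
            pts = rng.normal(size=(2 * n, 3))
            pts[:n, 0] += sep
            labels = np.repeat([0, 1], n)
            assert lda_efficiency(pts, labels) == pytest.approx(
                brute_force_efficiency(pts, labels), abs=1e-6
            )

    def test_matches_sklearn_balanced_accuracy(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.metrics import balanced_accuracy_score

        pts, labels = make_gaussian_blobs(2.0, 1.0, 2000, seed=11)
        lda = LinearDiscriminantAnalysis(solver="lsqr").fit(pts, labels)
        sk = balanced_accuracy_score(labels, lda.predict(pts))
        assert lda_efficiency(pts, labels) == pytest.approx(2 * sk - 1, abs=0.01)


class TestEfficiencyInvariances:
    @given(st.integers(0, 10_000))
    def test_rigid_motion_and_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        cfg = two_blob_config(rng, n=25, separation=rng.uniform(0, 3))
        base = segregation_efficiency(cfg)
        rot = Rotation.random(random_state=int(seed)).as_matrix()
        shift = rng.normal(scale=5, size=3)
        moved = Configuration(
            cfg.positions @ rot.T + shift, cfg.chain_id, cfg.bonds
        )
        assert segregation_efficiency(moved) == pytest.approx(base, abs=1e-9)
        swapped = Configuration(cfg.positions, 1 - cfg.chain_id, cfg.bonds)
        assert segregation_efficiency(swapped) == pytest.approx(base, abs=1e-9)

    def test_monotone_in_separation_of_congruent_blobs(self, rng):
        blob = rng.normal(size=(60, 3))
        effs = []
        for sep in np.linspace(0, 8, 9):
            pos = np.vstack([blob + [sep / 2, 0, 0], blob - [sep / 2, 0, 0]])
            effs.append(lda_efficiency(pos, np.repeat([0, 1], 60)))
        assert np.all(np.diff(effs) >= -1e-12)
        assert effs[0] == 0.0 and effs[-1] == 1.0


class TestComDistance:
    def test_examples(self):
        n = 20
        a = np.tile([4.0, 0, 0], (n, 1))
        b = np.tile([-4.0, 0, 0], (n, 1))
        cfg = Configuration(np.vstack([a, b]), np.repeat([0, 1], n), ring_bonds(n, n))
        assert com_distance_normalized(cfg, R_vesicle=8.0) == pytest.approx(1.0)
        cfg0 = Configuration(np.vstack([a, a]), np.repeat([0, 1], n), ring_bonds(n, n))
        assert com_distance_normalized(cfg0, 8.0) == pytest.approx(0.0)

    def test_rotation_invariance(self, rng):
        for k in range(20):
            cfg = two_blob_config(rng, n=15, separation=rng.uniform(0, 4))
            base = com_distance_normalized(cfg, 5.0)
            rot = Rotation.random(random_state=k).as_matrix()
            rotated = Configuration(cfg.positions @ rot.T, cfg.chain_id, cfg.bonds)
            assert com_distance_normalized(rotated, 5.0) == pytest.approx(base)


class TestRadiusOfGyration:
    def test_examples(self):
        n = 10
        coincident = np.zeros((n, 3))
        pair = np.zeros((n, 3))
        pair[: n // 2, 0] = 3.0  # half at x=3, half at x=0 -> rg = 1.5
        cfg = Configuration(
            np.vstack([coincident, pair]), np.repeat([0, 1], n), ring_bonds(n, n)
        )
        assert radius_of_gyration(cfg, "A") == 0.0
        assert radius_of_gyration(cfg, "B") == pytest.approx(1.5)

    def test_translation_invariance(self, rng):
        cfg = two_blob_config(rng, n=20)
        base = radius_of_gyration(cfg, "A")
        moved = Configuration(cfg.positions + [3, -7, 2], cfg.chain_id, cfg.bonds)
        assert radius_of_gyration(moved, "A") == pytest.approx(base)

    def test_unknown_chain_rejected(self, rng):
        with pytest.raises(Exception):
            radius_of_gyration(two_blob_config(rng), "C")


class TestEnsembleSummary:
    def _series(self, values, seed=0):
        t = np.arange(len(values), dtype=float)
        v = np.asarray(values, dtype=float)
        return MetricsSeries(t, v, v / 2, v, v, replica_seed=seed)

    def test_identical_replicas_have_zero_se(self):
        s = self._series([0.1, 0.5, 0.9])
        out = ensemble_summary([s, s, s])
        assert np.allclose(out.se_efficiency, 0.0)
        assert np.allclose(out.mean_efficiency, [0.1, 0.5, 0.9])

    def test_two_replica_formula(self):
        out = ensemble_summary([self._series([0.2]), self._series([0.8])])
        assert out.mean_efficiency[0] == pytest.approx(0.5)
        assert out.se_efficiency[0] == pytest.approx(0.3)  # |a-b|/2

    def test_se_close_to_population_value(self, rng):
        sigma = 0.07
        series = [
            self._series(np.clip(0.5 + rng.normal(0, sigma, size=6), 0, 1), seed=i)
            for i in range(50)
        ]
        out = ensemble_summary(series)
        assert np.all(np.abs(out.se_efficiency - sigma / np.sqrt(50)) < 0.2 * sigma)

    def test_mismatched_grids_rejected(self):
        a = self._series([0.1, 0.2])
        b = MetricsSeries([0.0, 2.0], [0.1, 0.2], [0, 0], [1, 1], [1, 1], 1)
        with pytest.raises(InvalidParameterError):
            ensemble_summary([a, b])

    def test_needs_two_replicas(self):
        with pytest.raises(InvalidParameterError):
            ensemble_summary([self._series([0.1])])


class TestSeriesValidation:
    def test_efficiency_bounds_enforced(self):
        with pytest.raises(InvalidParameterError):
            MetricsSeries([0.0], [1.2], [0.1], [1.0], [1.0], 0)

    def test_com_distance_bound_enforced(self):
        with pytest.raises(InvalidParameterError):
            MetricsSeries([0.0], [0.5], [2.5], [1.0], [1.0], 0)
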