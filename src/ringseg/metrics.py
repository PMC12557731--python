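"""Segregation measures and ensemble statistics.

Two observables summarize how well the two chromosomes have separated:

* **Segregation efficiency** — how linearly separable the two labeled bead
  clouds are.  A two-class Fisher discriminant is fit to the 3-D bead
  coordinates (pooled within-class covariance, diagonal regularization
  1e-8, threshold at the midpoint of the projected class means, points on
  the threshold counting half to each class), and the balanced training
  accuracy ``acc`` is mapped affinely to ``max(0, 2*acc - 1)``: chance-level
  mixing gives 0, perfect separation gives 1.
* **Normalized COM distance** — distance between the chain centers of mass
  divided by the vesicle radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateConfigurationError, InvalidParameterError
from .model import CHAIN_A, CHAIN_B, Configuration, _chain_code


def lda_efficiency(points: np.ndarray, labels: np.ndarray) -> float:
    """Fisher-LDA segregation efficiency of a labeled 3-D point cloud.

    ``labels`` must contain exactly two classes with >= 2 points each.
    """
    x = np.asarray(points, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateConfigurationError(f"need exactly two classes, got {classes.size}")
    xa = x[y == classes[0]]
    xb = x[y == classes[1]]
    if len(xa) < 2 or len(xb) < 2:
        raise DegenerateConfigurationError("each class needs at least 2 points")

    mu_a = xa.mean(axis=0)
    mu_b = xb.mean(axis=0)
    ca = xa - mu_a
    cb = xb - mu_b
    pooled = (ca.T @ ca + cb.T @ cb) / (len(xa) + len(xb) - 2)
    pooled = pooled + 1e-8 * np.eye(x.shape[1])
    try:
        w = np.linalg.solve(pooled, mu_a - mu_b)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConfigurationError(
            "pooled within-class covariance singular despite regularization"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise DegenerateConfigurationError("non-finite discriminant direction")

    scores_a = xa @ w
    scores_b = xb @ w
    threshold = 0.5 * (mu_a @ w + mu_b @ w)
    # Fisher direction points from B toward A, so A scores above the threshold.
    acc_a = np.mean((scores_a > threshold) + 0.5 * (scores_a == threshold))
    acc_b = np.mean((scores_b < threshold) + 0.5 * (scores_b == threshold))
    balanced = 0.5 * (acc_a + acc_b)
    return max(0.0, 2.0 * balanced - 1.0)


def segregation_efficiency(config: Configuration) -> float:
    """LDA segregation efficiency of a two-chain configuration (0 mixed, 1 split)."""
    return lda_efficiency(config.positions, config.chain_id)


def com_distance_normalized(config: Configuration, R_vesicle: float) -> float:
    """|COM_A - COM_B| / R_vesicle."""
    if R_vesicle <= 0:
        raise InvalidParameterError("R_vesicle must be positive")
    return float(np.linalg.norm(config.com(CHAIN_A) - config.com(CHAIN_B)) / R_vesicle)


def radius_of_gyration(config: Configuration, chain) -> float:
    """RMS bead distance from the chain's center of mass."""
    idx = config.beads_of(_chain_code(chain))
    pts = config.positions[idx]
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


# ---------------------------------------------------------------------------
# per-replica series and ensemble statistics


@dataclass
class MetricsSeries:
    """Per-snapshot metrics of one replica."""

    times: np.ndarray
    efficiency: np.ndarray
    com_distance_norm: np.ndarray
    rg_a: np.ndarray
    rg_b: np.ndarray
    replica_seed: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        self.com_distance_norm = np.asarray(self.com_distance_norm, dtype=float)
        self.rg_a = np.asarray(self.rg_a, dtype=float)
        self.rg_b = np.asarray(self.rg_b, dtype=float)
        n = self.times.shape[0]
        for name in ("efficiency", "com_distance_norm", "rg_a", "rg_b"):
            if getattr(self, name).shape != (n,):
                raise InvalidParameterError(f"{name} length does not match times")
        if np.any(self.efficiency < 0) or np.any(self.efficiency > 1):
            raise InvalidParameterError("efficiency must lie in [0, 1]")
        if np.any(self.com_distance_norm < 0) or np.any(self.com_distance_norm >= 2):
            raise InvalidParameterError("normalized COM distance must lie in [0, 2)")


@dataclass
class EnsembleResult:
    """Across-replica mean and standard error (SD/sqrt(n)) at each time."""

    times: np.ndarray
    mean_efficiency: np.ndarray
    se_efficiency: np.ndarray
    mean_dist: np.ndarray
    se_dist: np.ndarray
    n_replicas: int

    @property
    def final_mean_efficiency(self) -> float:
        return float(self.mean_efficiency[-1])

    @property
    def final_se_efficiency(self) -> float:
        return float(self.se_efficiency[-1])


def compute_metrics_series(result) -> MetricsSeries:
    """Evaluate both segregation metrics plus per-chain Rg on every snapshot."""
    R = result.params.R_vesicle
    times, eff, dist, rga, rgb = [], [], [], [], []
    for snap in result.snapshots:
        times.append(snap.time)
        eff.append(segregation_efficiency(snap))
        dist.append(com_distance_normalized(snap, R))
        rga.append(radius_of_gyration(snap, CHAIN_A))
        rgb.append(radius_of_gyration(snap, CHAIN_B))
    return MetricsSeries(
        np.array(times), np.array(eff), np.array(dist), np.array(rga), np.array(rgb),
        replica_seed=result.seed,
    )


def ensemble_summary(series) -> EnsembleResult:
    """Pointwise mean and SE over replicas sharing one time grid."""
    series = list(series)
    if len(series) < 2:
        raise InvalidParameterError("ensemble_summary needs at least 2 replicas")
    times = series[0].times
    for s in series[1:]:
        if s.times.shape != times.shape or not np.allclose(s.times, times):
            raise InvalidParameterError("replicas do not share a common time grid")
    eff = np.stack([s.efficiency for s in series])
    dist = np.stack([s.com_distance_norm for s in series])
    n = len(series)
    return EnsembleResult(
        times=times.copy(),
        mean_efficiency=eff.mean(axis=0),
        se_efficiency=eff.std(axis=0, ddof=1) / np.sqrt(n),
        mean_dist=dist.mean(axis=0),
        se_dist=dist.std(axis=0, ddof=1) / np.sqrt(n),
        n_replicas=n,
    )
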