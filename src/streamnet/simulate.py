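"""Synthetic data generation for the simulation study.

Data are generated on two fixed dendritic networks (small, ``n_seg = 100``,
and large, ``n_seg = 2000``) at fixed observation and prediction locations.
The response follows a Gaussian model

    Y(s) = beta0 + k1 * (beta1 X1 + beta2 X2 + beta3 X3) + Z1(s) + k2 Z2(s) + eps

with ``Z1`` an exponential tail-up process (partial sill 1, range ``r_phi``),
``Z2`` an exponential Euclidean process (sill 1, range ``0.3 v``) present only
when ``k2 = 1``, and ``eps`` iid with variance ``sigma2 = 0.1``.  The
covariates ``X1, X2, X3`` are independent tail-up fields (partial sill 1,
range ``v / 2``, nugget 0.1).  ``X2`` is a spatially structured *unobserved
confounder*: it enters the truth with coefficient ``beta2 = 1`` but is never
given to the fitted models.  ``X3`` is observed but irrelevant
(``beta3 = 0``).  ``v`` is the maximum pairwise stream distance between the
study's points on the network, so ranges scale with network extent.

The five two-level design factors (``k1``, ``k2``, ``r_phi``, ``n``,
``n_seg``) cross into 32 scenarios; all remaining constants are fixed.
Observation and prediction values are drawn jointly (one multivariate-normal
draw over obs+pred) so prediction scoring sees the same latent surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.linalg import cholesky

from .covariance import EuclideanParams, TailUpParams, euclid_cov, tailup_cov
from .network import NetworkPointSet, StreamNetwork, generate_network, max_separation

__all__ = [
    "ScenarioConfig",
    "scenario_grid",
    "StudyGeometry",
    "SimulatedDataset",
    "ScenarioSimulator",
    "simulate_covariates",
    "simulate_response",
]

_JITTER = 1e-10  # diagonal jitter retried on Cholesky failure


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the 2^5 factorial design plus the study's fixed constants.

    ``r_phi_factor`` stores the tail-up range as a multiple of the network's
    maximum separation ``v`` (0.3 or 1.0) and is resolved against the
    concrete ``v`` at simulation time.
    """

    k1: float  # fixed-effect strength in {0.1, 1}
    k2: int  # Euclidean component present in {0, 1}
    r_phi_factor: float  # tail-up range / v in {0.3, 1.0}
    n: int  # observations in {100, 500}
    n_seg: int  # network size in {100, 2000}
    # fixed constants
    beta0: float = 1.0
    beta1: float = 1.0
    beta2: float = 1.0
    beta3: float = 0.0
    sigma2: float = 0.1
    tu_partial_sill: float = 1.0
    eu_sill: float = 1.0
    r_psi_factor: float = 0.3  # Euclidean range / v
    cov_range_factor: float = 0.5  # covariate tail-up range / v
    cov_nugget: float = 0.1
    cov_partial_sill: float = 1.0
    n_pred: int = 1000
    reps: int = 500
    redraw_covariates: bool = True  # fresh X fields each replicate

    @property
    def label(self) -> str:
        return (f"k1={self.k1},k2={self.k2},rphi={self.r_phi_factor}v,"
                f"n={self.n},nseg={self.n_seg}")

    def resolve_r_phi(self, v: float) -> float:
        return self.r_phi_factor * v

    def resolve_r_psi(self, v: float) -> float:
        return self.r_psi_factor * v


def scenario_grid() -> list[ScenarioConfig]:
    """Full cross of the five two-level factors: 32 scenarios, fixed order."""
    grid = []
    for k1 in (0.1, 1.0):
        for k2 in (0, 1):
            for r_phi_factor in (0.3, 1.0):
                for n in (100, 500):
                    for n_seg in (100, 2000):
                        grid.append(ScenarioConfig(
                            k1=k1, k2=k2, r_phi_factor=r_phi_factor,
                            n=n, n_seg=n_seg))
    return grid


@dataclass
class StudyGeometry:
    """A network with its frozen observation and prediction locations.

    Built once per study run (network construction and point placement are
    held fixed across scenarios and replicates).  ``v`` is the maximum
    pairwise stream distance over the union of both observation sets and the
    prediction set — a single constant per network.
    """

    net: StreamNetwork
    obs: dict[int, NetworkPointSet]  # keyed by n
    pred: NetworkPointSet
    v: float

    @classmethod
    def build(cls, n_seg: int, seed: int, n_obs_levels=(100, 500),
              n_pred: int = 1000, mean_length: float = 1.0) -> "StudyGeometry":
        # binary branching forces an odd segment count (2k+1 for k
        # confluences); even design labels round up to the nearest valid size
        n_actual = n_seg if n_seg % 2 == 1 else n_seg + 1
        ss = SeedSequence(entropy=seed, spawn_key=(n_seg,))
        seeds = ss.generate_state(2 + len(n_obs_levels)) % (2**31 - 1)
        net = generate_network(n_actual, seed=int(seeds[0]),
                               mean_length=mean_length)
        obs = {n: net.sample_points(n, seed=int(s), role="observation")
               for n, s in zip(n_obs_levels, seeds[1:])}
        pred = net.sample_points(n_pred, seed=int(seeds[-1]), role="prediction")
        union = pred
        for o in obs.values():
            union = NetworkPointSet.concat(union, o)
        v = max_separation(union, net)
        return cls(net=net, obs=obs, pred=pred, v=v)


@dataclass
class SimulatedDataset:
    """One simulated replicate: covariates, responses and retained truth."""

    scenario: ScenarioConfig
    rep_id: int
    net: StreamNetwork
    obs: NetworkPointSet
    pred: NetworkPointSet
    v: float
    X1: np.ndarray  # over obs + pred (obs first)
    X2: np.ndarray
    X3: np.ndarray
    Y_obs: np.ndarray
    Y_pred: np.ndarray
    truth: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.obs)

    def design(self, which: str = "obs", intercept: bool = True) -> np.ndarray:
        """Fitted-model design: intercept (optional) + X1 + X3 (X2 withheld)."""
        sl = slice(0, self.n_obs) if which == "obs" else slice(self.n_obs, None)
        cols = [self.X1[sl], self.X3[sl]]
        if intercept:
            cols.insert(0, np.ones_like(cols[0]))
        return np.column_stack(cols)

    def to_dataframe(self):
        import pandas as pd
        n = self.n_obs
        m = len(self.pred)
        return pd.DataFrame({
            "point_id": np.arange(n + m),
            "role": ["observation"] * n + ["prediction"] * m,
            "segment_id": np.concatenate([self.obs.segment_ids, self.pred.segment_ids]),
            "updist": np.concatenate([self.obs.updist, self.pred.updist]),
            "X1": self.X1, "X2": self.X2, "X3": self.X3,
            "Y": np.concatenate([self.Y_obs, self.Y_pred]),
        })


def _chol(cov: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor with a small diagonal jitter fallback."""
    try:
        return cholesky(cov, lower=True)
    except np.linalg.LinAlgError:
        pass
    except Exception:
        pass
    n = cov.shape[0]
    jitter = _JITTER
    for _ in range(8):
        try:
            return cholesky(cov + jitter * np.eye(n), lower=True)
        except Exception:
            jitter *= 100.0
    raise np.linalg.LinAlgError("covariance not factorizable even with jitter")


class ScenarioSimulator:
    """Generates replicates for one scenario on a fixed geometry.

    Cholesky factors of the covariate, tail-up and Euclidean covariances are
    computed once (they depend only on the frozen geometry and the scenario's
    ranges) and reused across replicates.  Replicate ``rep_id`` under base
    seed ``s`` uses the deterministic stream ``SeedSequence(s, spawn_key=
    (scenario_index, rep_id))`` so datasets are bit-reproducible and
    independent across replicates.
    """

    def __init__(self, geometry: StudyGeometry, cfg: ScenarioConfig,
                 base_seed: int, scenario_index: int = 0):
        if geometry.net.n_seg not in (cfg.n_seg, cfg.n_seg + 1):
            raise ValueError("geometry network size does not match scenario")
        self.geometry = geometry
        self.cfg = cfg
        self.base_seed = base_seed
        self.scenario_index = scenario_index
        net, v = geometry.net, geometry.v
        self.all_points = NetworkPointSet.concat(
            geometry.obs[cfg.n], geometry.pred, role="all")
        np_all = len(self.all_points)

        cov_x = tailup_cov(self.all_points, self.all_points,
                           TailUpParams(cfg.cov_partial_sill,
                                        cfg.cov_range_factor * v), net)
        cov_x = cov_x + cfg.cov_nugget * np.eye(np_all)
        self._chol_x = _chol(cov_x)

        cov_z1 = tailup_cov(self.all_points, self.all_points,
                            TailUpParams(cfg.tu_partial_sill,
                                         cfg.resolve_r_phi(v)), net)
        self._chol_z1 = _chol(cov_z1)

        if cfg.k2:
            cov_z2 = euclid_cov(self.all_points.coords, self.all_points.coords,
                                EuclideanParams(cfg.eu_sill, cfg.resolve_r_psi(v)))
            self._chol_z2 = _chol(cov_z2)
        else:
            self._chol_z2 = None

        if not cfg.redraw_covariates:
            rng = self._rng(-1)
            self._fixed_X = [self._chol_x @ rng.standard_normal(np_all)
                             for _ in range(3)]

    def _rng(self, rep_id: int):
        ss = SeedSequence(entropy=self.base_seed,
                          spawn_key=(self.scenario_index, rep_id + 1))
        return default_rng(ss)

    def replicate(self, rep_id: int) -> SimulatedDataset:
        cfg, geo = self.cfg, self.geometry
        rng = self._rng(rep_id)
        m = len(self.all_points)
        if cfg.redraw_covariates:
            X1, X2, X3 = (self._chol_x @ rng.standard_normal(m) for _ in range(3))
        else:
            X1, X2, X3 = self._fixed_X
            rng.standard_normal(3 * m)  # keep downstream stream alignment
        Z1 = self._chol_z1 @ rng.standard_normal(m)
        if cfg.k2:
            Z2 = self._chol_z2 @ rng.standard_normal(m)
        else:
            Z2 = np.zeros(m)
        eps = np.sqrt(cfg.sigma2) * rng.standard_normal(m)
        mean = cfg.beta0 + cfg.k1 * (cfg.beta1 * X1 + cfg.beta2 * X2
                                     + cfg.beta3 * X3)
        Y = mean + Z1 + cfg.k2 * Z2 + eps
        n = cfg.n
        return SimulatedDataset(
            scenario=cfg, rep_id=rep_id, net=geo.net,
            obs=geo.obs[cfg.n], pred=geo.pred, v=geo.v,
            X1=X1, X2=X2, X3=X3,
            Y_obs=Y[:n], Y_pred=Y[n:],
            truth={
                "beta": (cfg.beta0, cfg.beta1, cfg.beta2, cfg.beta3),
                "coef_X1": cfg.k1 * cfg.beta1,
                "coef_X3": cfg.k1 * cfg.beta3,
                "Z1": Z1, "Z2": Z2,
            },
        )


# ------------------------------------------------------- standalone drawers
def simulate_covariates(points: NetworkPointSet, net: StreamNetwork,
                        v: float, seed: int,
                        partial_sill: float = 1.0, nugget: float = 0.1):
    """Three independent tail-up covariate fields (range v/2, plus nugget)."""
    if len(points) == 0:
        raise ValueError("need a nonempty point set")
    cov = tailup_cov(points, points, TailUpParams(partial_sill, 0.5 * v), net)
    cov = cov + nugget * np.eye(len(points))
    L = _chol(cov)
    rng = default_rng(seed)
    return tuple(L @ rng.standard_normal(len(points)) for _ in range(3))


def simulate_response(points: NetworkPointSet, net: StreamNetwork,
                      cfg: ScenarioConfig, X1, X2, X3, seed: int, v: float):
    """Draw the Gaussian response at ``points`` given covariate fields."""
    m = len(points)
    rng = default_rng(seed)
    Z1 = _chol(tailup_cov(points, points,
                          TailUpParams(cfg.tu_partial_sill,
                                       cfg.resolve_r_phi(v)), net)
               ) @ rng.standard_normal(m)
    if cfg.k2:
        Z2 = _chol(euclid_cov(points.coords, points.coords,
                              EuclideanParams(cfg.eu_sill, cfg.resolve_r_psi(v)))
                   ) @ rng.standard_normal(m)
    else:
        Z2 = np.zeros(m)
    eps = np.sqrt(cfg.sigma2) * rng.standard_normal(m)
    Y = (cfg.beta0 + cfg.k1 * (cfg.beta1 * np.asarray(X1)
                               + cfg.beta2 * np.asarray(X2)
                               + cfg.beta3 * np.asarray(X3))
         + Z1 + cfg.k2 * Z2 + eps)
    truth = {"Z1": Z1, "Z2": Z2, "coef_X1": cfg.k1 * cfg.beta1,
             "coef_X3": cfg.k1 * cfg.beta3}
    return Y, truth
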