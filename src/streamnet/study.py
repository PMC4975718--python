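"""Simulation study driver: fit the three models, score them, aggregate.

For each replicate of a scenario the tail-up geostatistical model, the
penalized network spline and the non-spatial linear baseline are fitted to
the same data; predictions at the held-out locations and the fixed-effect
estimates are scored against the simulated truth.  Per-scenario summaries
are means over replicates, with Monte-Carlo standard errors attached to the
coverage estimates.

Truth conventions: the fitted models estimate the composite coefficient on
``X1`` in the generating mean, which is ``k1 * beta1``; the ``X3``
coefficient truth is ``k1 * beta3 = 0``.  Prediction intervals target new
observations (they include the iid noise), matching how the held-out
responses are generated.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .linear import fit_linear
from .netspline import OdSpec, _model_from_dataset
from .simulate import (ScenarioConfig, ScenarioSimulator, SimulatedDataset,
                       StudyGeometry, scenario_grid)
from .tailup import TailUpGLS, VhptSpec, fit_vhpt, krige_predict

__all__ = [
    "MetricsRecord",
    "TimingRecord",
    "compute_metrics",
    "run_scenario",
    "run_study",
    "run_timing",
    "build_geometries",
]

MODELS = ("vhpt", "od", "linear")


@dataclass
class MetricsRecord:
    """Per-replicate (or aggregated) scores for one model on one scenario."""

    scenario: str
    k1: float
    k2: int
    r_phi_factor: float
    n: int
    n_seg: int
    model: str
    rmspe: float
    pred_bias: float
    pi_coverage: float
    rmse_fixed: float
    est_bias: float
    ci_coverage: float
    reps_used: int = 1

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class TimingRecord:
    model: str
    n: int
    n_seg: int
    t_median: float
    t_q05: float
    t_q95: float
    reps: int


def _fit_one(name: str, dataset: SimulatedDataset):
    """Fit one model; Euclidean/surface terms enter exactly when k2 = 1."""
    k2 = dataset.scenario.k2
    if name == "vhpt":
        fit = fit_vhpt(dataset, VhptSpec(include_euclid=bool(k2)))
        pred = krige_predict(fit, dataset)
    elif name == "od":
        model = _model_from_dataset(dataset, OdSpec(include_surface=bool(k2)))
        fit = model.fit()
        pred = fit.predict(dataset.pred,
                           dataset.design("pred", intercept=False))
    elif name == "linear":
        fit = fit_linear(dataset)
        pred = fit.predict(dataset.design("pred"))
    else:
        raise ValueError(f"unknown model {name!r}")
    return fit, pred


def compute_metrics(fits: dict, dataset: SimulatedDataset) -> list[MetricsRecord]:
    """Score fitted models against the dataset's held-out truth.

    ``fits`` maps model name to a ``(results, PredictionSet)`` pair.
    """
    cfg = dataset.scenario
    truth = {"X1": dataset.truth["coef_X1"], "X3": dataset.truth["coef_X3"]}
    records = []
    for name, (fit, pred) in fits.items():
        err = pred.mean - dataset.Y_pred
        fe = fit.fixed_effects()
        coef_err = np.array([fe[k].estimate - truth[k] for k in ("X1", "X3")])
        ci_cover = np.array([fe[k].covers(truth[k]) for k in ("X1", "X3")])
        records.append(MetricsRecord(
            scenario=cfg.label, k1=cfg.k1, k2=cfg.k2,
            r_phi_factor=cfg.r_phi_factor, n=cfg.n, n_seg=cfg.n_seg,
            model=name,
            rmspe=float(np.sqrt(np.mean(err ** 2))),
            pred_bias=float(np.mean(err)),
            pi_coverage=float(pred.covers(dataset.Y_pred).mean()),
            rmse_fixed=float(np.sqrt(np.mean(coef_err ** 2))),
            est_bias=float(np.mean(coef_err)),
            ci_coverage=float(ci_cover.mean()),
        ))
    return records


def _aggregate(per_rep: list[MetricsRecord], n_failed: int) -> pd.DataFrame:
    df = pd.DataFrame([r.as_dict() for r in per_rep])
    keys = ["scenario", "k1", "k2", "r_phi_factor", "n", "n_seg", "model"]
    metrics = ["rmspe", "pred_bias", "pi_coverage", "rmse_fixed",
               "est_bias", "ci_coverage"]
    agg = df.groupby(keys, sort=False)[metrics].mean().reset_index()
    reps = df.groupby(keys, sort=False).size().reset_index(name="reps_used")
    agg = agg.merge(reps, on=keys)
    for col in ("pi_coverage", "ci_coverage"):
        p = agg[col]
        agg[col + "_mcse"] = np.sqrt(p * (1 - p) / agg["reps_used"])
    agg["reps_failed"] = n_failed
    return agg


def run_scenario(cfg: ScenarioConfig, reps: int, base_seed: int,
                 geometry: StudyGeometry | None = None,
                 scenario_index: int = 0,
                 models=MODELS,
                 keep_replicates: bool = False,
                 progress=None):
    """Simulate ``reps`` datasets from one scenario and score each model.

    Replicates where a model fit raises are excluded (for every model, to
    keep comparisons paired) and counted in ``reps_failed``.  Deterministic
    given ``base_seed``: the geometry and every replicate use seeds derived
    from it.
    """
    if reps < 1:
        raise ValueError("need reps >= 1")
    if geometry is None:
        geometry = StudyGeometry.build(cfg.n_seg, seed=base_seed,
                                       n_pred=cfg.n_pred)
    sim = ScenarioSimulator(geometry, cfg, base_seed=base_seed,
                            scenario_index=scenario_index)
    per_rep: list[MetricsRecord] = []
    n_failed = 0
    for rep in range(reps):
        dataset = sim.replicate(rep)
        try:
            fits = {name: _fit_one(name, dataset) for name in models}
        except (np.linalg.LinAlgError, RuntimeError) as exc:
            n_failed += 1
            if progress:
                progress(f"replicate {rep} failed: {exc}")
            continue
        per_rep.extend(compute_metrics(fits, dataset))
        if progress and (rep + 1) % 25 == 0:
            progress(f"scenario {cfg.label}: replicate {rep + 1}/{reps}")
    agg = _aggregate(per_rep, n_failed)
    if keep_replicates:
        return agg, pd.DataFrame([r.as_dict() for r in per_rep])
    return agg


def build_geometries(configs, base_seed: int) -> dict[int, StudyGeometry]:
    """One frozen geometry per distinct network size, shared across scenarios."""
    out = {}
    for cfg in configs:
        if cfg.n_seg not in out:
            out[cfg.n_seg] = StudyGeometry.build(cfg.n_seg, seed=base_seed,
                                                 n_pred=cfg.n_pred)
    return out


def run_study(configs=None, reps: int = 500, base_seed: int = 0,
              models=MODELS, progress=None) -> pd.DataFrame:
    """Run a set of scenarios against shared frozen geometries."""
    if configs is None:
        configs = scenario_grid()
    geoms = build_geometries(configs, base_seed)
    frames = []
    for idx, cfg in enumerate(configs):
        if progress:
            progress(f"[{idx + 1}/{len(configs)}] {cfg.label}")
        frames.append(run_scenario(cfg, reps, base_seed,
                                   geometry=geoms[cfg.n_seg],
                                   scenario_index=idx, models=models,
                                   progress=progress))
    return pd.concat(frames, ignore_index=True)


def run_timing(n_values, n_seg_values, reps: int = 10, base_seed: int = 0,
               progress=None) -> pd.DataFrame:
    """Wall-clock fit times for the two spatial models across sizes.

    Data are generated from the weak-effect, tail-up-only, long-range
    scenario; only the fit call is timed.  Results are hardware dependent —
    only growth trends are meaningful.
    """
    if not len(n_values) or not len(n_seg_values):
        raise ValueError("need nonempty size lists")
    records = []
    for n_seg in n_seg_values:
        geometry = StudyGeometry.build(n_seg, seed=base_seed,
                                       n_obs_levels=tuple(sorted(set(n_values))))
        for n in n_values:
            cfg = ScenarioConfig(k1=0.1, k2=0, r_phi_factor=1.0,
                                 n=n, n_seg=n_seg)
            sim = ScenarioSimulator(geometry, cfg, base_seed=base_seed)
            times = {"vhpt": [], "od": []}
            for rep in range(reps):
                ds = sim.replicate(rep)
                t0 = time.perf_counter()
                TailUpGLS(ds.Y_obs, ds.design("obs"), ds.obs, ds.net,
                          param_names=["intercept", "X1", "X3"]).fit()
                times["vhpt"].append(time.perf_counter() - t0)
                t0 = time.perf_counter()
                _model_from_dataset(ds, OdSpec()).fit()
                times["od"].append(time.perf_counter() - t0)
            for name, ts in times.items():
                ts = np.array(ts)
                records.append(TimingRecord(
                    model=name, n=n, n_seg=n_seg,
                    t_median=float(np.median(ts)),
                    t_q05=float(np.quantile(ts, 0.05)),
                    t_q95=float(np.quantile(ts, 0.95)),
                    reps=reps))
            if progress:
                progress(f"timing n={n} n_seg={n_seg} done")
    return pd.DataFrame([asdict(r) for r in records])
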