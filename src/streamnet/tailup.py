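"""Geostatistical linear model with tail-up covariance, fitted by REML.

The model is

    y = X beta + Z1 (+ Z2) + eps

with ``Z1`` an exponential tail-up process on the stream network, ``Z2`` an
optional exponential Euclidean process on the embedded coordinates, and
``eps`` iid noise (nugget).  Variance parameters are estimated by restricted
maximum likelihood; fixed effects by generalized least squares at the
estimated covariance; predictions by universal kriging.

The REML criterion used throughout is ``-2`` times the restricted
log-likelihood up to an additive constant:

    log|Sigma| + log|X' Sigma^-1 X| + y' P y,
    P = Sigma^-1 - Sigma^-1 X (X' Sigma^-1 X)^-1 X' Sigma^-1.

Internally the overall variance scale is profiled out analytically, so the
quasi-Newton search runs over variance proportions and log ranges; the
profiled optimum coincides with the optimum of the full criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .base import Z90, FixedEffect, PredictionSet
from .network import NetworkPointSet, StreamNetwork

__all__ = [
    "VhptSpec",
    "TailUpGLS",
    "TailUpResults",
    "reml_neg_loglik",
    "fit_vhpt",
    "krige_predict",
]


@dataclass(frozen=True)
class VhptSpec:
    """Model variant: tail-up only, or tail-up plus Euclidean component."""

    include_euclid: bool = False


class TailUpGLS:
    """Tail-up (optionally + Euclidean) GLS model for one dataset.

    Parameters
    ----------
    y : (n,) response at the observation locations.
    X : (n, p) fixed-effect design matrix (full column rank).
    obs_points : NetworkPointSet of the observation locations.
    net : StreamNetwork carrying topology, flows and the embedding.
    include_euclid : add an exponential Euclidean covariance component.
    param_names : names for the columns of ``X`` (reporting only).
    """

    def __init__(self, y, X, obs_points: NetworkPointSet, net: StreamNetwork,
                 include_euclid: bool = False, param_names=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("y and X row counts differ")
        self.n, self.p = self.X.shape
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("design matrix is rank deficient")
        self.obs_points = obs_points
        self.net = net
        self.include_euclid = include_euclid
        self.param_names = list(param_names) if param_names is not None else \
            [f"x{j}" for j in range(self.p)]
        g = net.pairwise_geometry(obs_points, obs_points)
        self._dist = g.dist
        self._pij = g.pij
        self._euclid = g.euclid
        self._I = np.eye(self.n)

    # ------------------------------------------------------------ kernels
    def _corr_tu(self, rng: float) -> np.ndarray:
        return self._pij * np.exp(-self._dist / rng)

    def _corr_eu(self, rng: float) -> np.ndarray:
        return np.exp(-self._euclid / rng)

    def sigma(self, theta) -> np.ndarray:
        """Covariance matrix at a variance-parameter vector.

        ``theta`` is ``(tu_sill, tu_range, nugget)`` or
        ``(tu_sill, tu_range, nugget, eu_sill, eu_range)``.
        """
        theta = np.asarray(theta, dtype=float)
        S = theta[0] * self._corr_tu(theta[1]) + theta[2] * self._I
        if self.include_euclid:
            S = S + theta[3] * self._corr_eu(theta[4])
        return S

    # --------------------------------------------------------------- REML
    def _reml_parts(self, V: np.ndarray):
        """Cholesky pieces of the restricted likelihood for covariance V."""
        c, low = cho_factor(V, lower=True)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        Vi_X = cho_solve((c, low), self.X)
        Vi_y = cho_solve((c, low), self.y)
        XtViX = self.X.T @ Vi_X
        cx, lowx = cho_factor(XtViX, lower=True)
        logdet_x = 2.0 * np.log(np.diag(cx)).sum()
        bhat = cho_solve((cx, lowx), self.X.T @ Vi_y)
        Q = float(self.y @ Vi_y - (self.X.T @ Vi_y) @ bhat)
        return logdet, logdet_x, Q, bhat, XtViX, (c, low), (cx, lowx)

    def reml_neg_loglik(self, theta) -> float:
        """-2 x restricted log-likelihood (up to a constant) at ``theta``."""
        theta = np.asarray(theta, dtype=float)
        if np.any(theta <= 0):
            raise ValueError("variance parameters must be positive")
        try:
            logdet, logdet_x, Q, *_ = self._reml_parts(self.sigma(theta))
        except np.linalg.LinAlgError:
            S = self.sigma(theta) + 1e-10 * self._I
            try:
                logdet, logdet_x, Q, *_ = self._reml_parts(S)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "covariance not PD at theta") from exc
        return logdet + logdet_x + Q

    # ------------------------------------------------- profiled objective
    def _mix_corr(self, z):
        """Correlation mixture and weights from unconstrained parameters.

        ``z`` is ``(a_tu, log r_tu)`` or ``(a_tu, a_eu, log r_tu, log r_eu)``
        where the ``a`` are log-ratios of component weight to nugget weight.
        """
        if self.include_euclid:
            a = np.array([z[0], z[1], 0.0])
            w = np.exp(a - a.max())
            w /= w.sum()
            V = (w[0] * self._corr_tu(np.exp(z[2]))
                 + w[1] * self._corr_eu(np.exp(z[3]))
                 + w[2] * self._I)
        else:
            a = np.array([z[0], 0.0])
            w = np.exp(a - a.max())
            w /= w.sum()
            V = w[0] * self._corr_tu(np.exp(z[1])) + w[1] * self._I
        return V, w

    def _profiled(self, z) -> float:
        V, _ = self._mix_corr(z)
        try:
            logdet, logdet_x, Q, *_ = self._reml_parts(V)
        except np.linalg.LinAlgError:
            return 1e12
        df = self.n - self.p
        tau2 = Q / df
        if tau2 <= 0:
            return 1e12
        return df * np.log(tau2) + logdet + logdet_x

    def _starts(self):
        d = self._dist[self._pij > 0]
        d = d[d > 0]
        dmax = float(d.max()) if d.size else 1.0
        dmed = float(np.median(d)) if d.size else 0.5
        splits = [(0.8, dmed), (0.5, dmax), (0.2, dmed)]
        starts = []
        for w_sp, r0 in splits:
            a = np.log(w_sp / (1.0 - w_sp))
            if self.include_euclid:
                e = self._euclid[self._euclid > 0]
                emed = float(np.median(e)) if e.size else 0.5
                # split the spatial share evenly between tail-up and Euclidean
                a_each = np.log(0.5 * w_sp / (1.0 - w_sp))
                starts.append([a_each, a_each, np.log(r0), np.log(emed)])
            else:
                starts.append([a, np.log(r0)])
        return starts

    def fit(self, maxiter: int = 200) -> "TailUpResults":
        """Estimate variance parameters by REML and fixed effects by GLS."""
        dmax = float(self._dist.max()) if self._dist.size else 1.0
        if self.include_euclid:
            emax = float(self._euclid.max()) if self._euclid.size else 1.0
            bounds = [(-12, 12), (-12, 12),
                      (np.log(dmax) - 9, np.log(dmax) + 5),
                      (np.log(emax) - 9, np.log(emax) + 5)]
        else:
            bounds = [(-12, 12), (np.log(dmax) - 9, np.log(dmax) + 5)]
        best = None
        any_success = False
        for z0 in self._starts():
            res = minimize(self._profiled, z0, method="L-BFGS-B",
                           bounds=bounds, options={"maxiter": maxiter})
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        z = best.x
        V, w = self._mix_corr(z)
        logdet, logdet_x, Q, bhat, XtViX, chV, chX = self._reml_parts(V)
        tau2 = Q / (self.n - self.p)
        if self.include_euclid:
            theta = np.array([tau2 * w[0], np.exp(z[2]), tau2 * w[2],
                              tau2 * w[1], np.exp(z[3])])
        else:
            theta = np.array([tau2 * w[0], np.exp(z[1]), tau2 * w[1]])
        beta_cov = tau2 * np.linalg.inv(XtViX)
        reml_value = self.reml_neg_loglik(np.maximum(theta, 1e-300))
        return TailUpResults(
            model=self, params=bhat, cov_params=beta_cov, theta=theta,
            reml_value=reml_value,
            converged=bool(any_success and best.success),
        )


class TailUpResults:
    """REML/GLS fit of the tail-up geostatistical model."""

    def __init__(self, model: TailUpGLS, params, cov_params, theta,
                 reml_value: float, converged: bool):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.cov_params = np.asarray(cov_params, dtype=float)
        self.theta = np.asarray(theta, dtype=float)
        self.reml_value = float(reml_value)
        self.converged = bool(converged)
        self.bse = np.sqrt(np.diag(self.cov_params))
        # factorization of the fitted covariance, for kriging
        self._sigma_hat = model.sigma(self.theta)
        self._ch = cho_factor(self._sigma_hat + 1e-12 * model._I, lower=True)
        self._resid = model.y - model.X @ self.params
        self._Si_resid = cho_solve(self._ch, self._resid)

    # ------------------------------------------------------------- summaries
    @property
    def theta_dict(self) -> dict:
        d = {"tu_partial_sill": self.theta[0], "tu_range": self.theta[1],
             "nugget": self.theta[2]}
        if self.model.include_euclid:
            d["eu_sill"] = self.theta[3]
            d["eu_range"] = self.theta[4]
        return d

    def conf_int(self, alpha: float = 0.10) -> np.ndarray:
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def fixed_effects(self) -> dict[str, FixedEffect]:
        ci = self.conf_int()
        return {
            name: FixedEffect(name, float(b), float(s),
                              float(lo), float(hi))
            for name, b, s, (lo, hi) in zip(self.model.param_names,
                                            self.params, self.bse, ci)
        }

    def summary(self) -> str:
        lines = ["Tail-up geostatistical model (REML)",
                 f"  observations: {self.model.n}   "
                 f"fixed effects: {self.model.p}   "
                 f"converged: {self.converged}",
                 f"  -2 restricted loglik (+const): {self.reml_value:.4f}",
                 "  variance parameters:"]
        for k, v in self.theta_dict.items():
            lines.append(f"    {k:>16s}: {v:.6g}")
        lines.append(f"  {'term':>12s} {'coef':>10s} {'se':>9s} "
                     f"{'lo90':>9s} {'hi90':>9s}")
        for fe in self.fixed_effects().values():
            lines.append(f"  {fe.name:>12s} {fe.estimate:10.4f} "
                         f"{fe.se:9.4f} {fe.lo90:9.4f} {fe.hi90:9.4f}")
        return "\n".join(lines)

    # ------------------------------------------------------------ prediction
    def predict(self, pred_points: NetworkPointSet, X_pred) -> PredictionSet:
        """Universal kriging of new observations at ``pred_points``.

        The kriging variance targets a *new observation*: it includes the
        nugget, plus the fixed-effect extrapolation term from estimating
        ``beta``.  Intervals are symmetric normal at the 90% level.
        """
        model = self.model
        X_pred = np.atleast_2d(np.asarray(X_pred, dtype=float))
        g = model.net.pairwise_geometry(model.obs_points, pred_points)
        c = self.theta[0] * g.pij * np.exp(-g.dist / self.theta[1])
        sill_total = self.theta[0] + self.theta[2]
        if model.include_euclid:
            c = c + self.theta[3] * np.exp(-g.euclid / self.theta[4])
            sill_total += self.theta[3]
        mean = X_pred @ self.params + c.T @ self._Si_resid
        Si_c = cho_solve(self._ch, c)
        var_spatial = sill_total - np.einsum("ij,ij->j", c, Si_c)
        m = X_pred.T - model.X.T @ Si_c  # p x npred
        # cov_params equals (X' Sigma^-1 X)^-1 at theta_hat
        var_beta = np.einsum("ij,ij->j", m, self.cov_params @ m)
        var = np.maximum(var_spatial + var_beta, 0.0)
        return PredictionSet.from_mean_se(mean, np.sqrt(var))


# ------------------------------------------------------------ spec wrappers
def reml_neg_loglik(theta, y, Xdesign, obs_points, net,
                    include_euclid: bool = False) -> float:
    """Standalone REML criterion (see :meth:`TailUpGLS.reml_neg_loglik`)."""
    return TailUpGLS(y, Xdesign, obs_points, net,
                     include_euclid=include_euclid).reml_neg_loglik(theta)


def fit_vhpt(dataset, spec: VhptSpec = VhptSpec()) -> TailUpResults:
    """Fit the tail-up GLS model (intercept + X1 + X3) to a dataset."""
    model = TailUpGLS(
        dataset.Y_obs, dataset.design("obs"), dataset.obs, dataset.net,
        include_euclid=spec.include_euclid,
        param_names=["intercept", "X1", "X3"],
    )
    return model.fit()


def krige_predict(fit: TailUpResults, dataset,
                  pred_points: NetworkPointSet | None = None) -> PredictionSet:
    """Universal-kriging predictions at the dataset's prediction locations."""
    pts = pred_points if pred_points is not None else dataset.pred
    return fit.predict(pts, dataset.design("pred"))
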