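"""Non-spatial linear baseline: OLS with normal-theory 90% intervals."""

from __future__ import annotations

import numpy as np

from .base import FixedEffect, PredictionSet, Z90

__all__ = ["LinearModel", "LinearResults", "fit_linear"]

_VAR_FLOOR = 1e-12  # guards degenerate (exact-fit) residual variance


class LinearModel:
    """Ordinary least squares with iid errors."""

    def __init__(self, y, X, param_names=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n, self.p = self.X.shape
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("design matrix is rank deficient")
        self.param_names = list(param_names) if param_names is not None else \
            [f"x{j}" for j in range(self.p)]

    def fit(self) -> "LinearResults":
        XtX = self.X.T @ self.X
        beta = np.linalg.solve(XtX, self.X.T @ self.y)
        resid = self.y - self.X @ beta
        sigma2 = max(float(resid @ resid) / (self.n - self.p), _VAR_FLOOR)
        cov = sigma2 * np.linalg.inv(XtX)
        return LinearResults(self, beta, cov, sigma2)


class LinearResults:
    def __init__(self, model: LinearModel, params, cov_params, sigma2):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.cov_params = np.asarray(cov_params, dtype=float)
        self.sigma2 = float(sigma2)
        self.bse = np.sqrt(np.diag(self.cov_params))
        self.converged = True

    def conf_int(self, alpha: float = 0.10) -> np.ndarray:
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def fixed_effects(self) -> dict[str, FixedEffect]:
        ci = self.conf_int()
        return {
            name: FixedEffect(name, float(b), float(s), float(lo), float(hi))
            for name, b, s, (lo, hi) in zip(self.model.param_names,
                                            self.params, self.bse, ci)
        }

    def summary(self) -> str:
        lines = ["Linear baseline (OLS)",
                 f"  observations: {self.model.n}   sigma2: {self.sigma2:.5f}",
                 f"  {'term':>12s} {'coef':>10s} {'se':>9s} "
                 f"{'lo90':>9s} {'hi90':>9s}"]
        for fe in self.fixed_effects().values():
            lines.append(f"  {fe.name:>12s} {fe.estimate:10.4f} "
                         f"{fe.se:9.4f} {fe.lo90:9.4f} {fe.hi90:9.4f}")
        return "\n".join(lines)

    def predict(self, X_pred) -> PredictionSet:
        """Predictions of new observations with 90% prediction intervals."""
        X_pred = np.atleast_2d(np.asarray(X_pred, dtype=float))
        mean = X_pred @ self.params
        lev = np.einsum("ij,ij->i", X_pred,
                        X_pred @ (self.cov_params / self.sigma2))
        var = self.sigma2 * (1.0 + lev)
        return PredictionSet.from_mean_se(mean, np.sqrt(np.maximum(var,
                                                                   _VAR_FLOOR)))


def fit_linear(dataset) -> LinearResults:
    """OLS fit of intercept + X1 + X3 to a simulated dataset."""
    model = LinearModel(dataset.Y_obs, dataset.design("obs"),
                        param_names=["intercept", "X1", "X3"])
    return model.fit()
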