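"""Gaussian-process emulator of the gas exchange threshold.

Implements GP regression from first principles: a squared-exponential
(anisotropic) covariance

    K(x, x') = sigma^2 * prod_i exp(-|x_i - x'_i|^2 / (2 Phi_i^2)),

a first-order polynomial mean mu(x) = beta_0 + beta^T x, maximum-likelihood
hyperparameters (multi-start L-BFGS in log space with analytic gradients,
polynomial-mean coefficients profiled out by generalized least squares), the
standard posterior mean/variance

    m(z)   = mu(z) + K(z, X)^T K(X, X)^{-1} (y - mu(X))
    s^2(z) = K(z, z) - K(z, X)^T K(X, X)^{-1} K(z, X),

prior/posterior function sampling, and leave-one-out cross-validation with the
mean squared error MSE_LOO = (1/n) sum_i (m_{-i}(x^i) - y_i)^2.

:class:`GPEmulator` follows the scikit-learn estimator contract (``fit`` /
``predict(return_std=...)`` / ``get_params``) so it composes with sklearn
pipelines and model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, RegressorMixin, clone

__all__ = [
    "GPHyperparams",
    "GPPrediction",
    "LOOReport",
    "GPEmulator",
    "sqexp_kernel",
    "sqexp_kernel_matrix",
    "gp_prior_samples",
    "loo_cv",
]


@dataclass
class GPHyperparams:
    """Kernel hyperparameters: signal SD, per-input lengthscales, variance jitter."""

    sigma: float
    lengthscales: np.ndarray
    nugget: float = 0.0

    def __post_init__(self) -> None:
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if np.any(self.lengthscales <= 0):
            raise ValueError("all lengthscales must be positive")
        if self.nugget < 0:
            raise ValueError("nugget must be non-negative")


@dataclass
class GPPrediction:
    """Posterior mean, variance and symmetric 95% interval at query points."""

    mean: np.ndarray
    variance: np.ndarray
    ci95: np.ndarray  # (n, 2): mean -/+ 1.96 * sqrt(variance)


@dataclass
class LOOReport:
    """Leave-one-out cross-validation summary."""

    mean: np.ndarray  # m_{-i}(x^i)
    variance: np.ndarray  # s^2_{-i}(x^i)
    y_true: np.ndarray
    mse_loo: float
    mse_loo_relative: float  # MSE_LOO / mean(y)
    coverage_count: int  # 95% CIs containing y_i
    mode: str

    @property
    def n(self) -> int:
        return self.y_true.size


def sqexp_kernel(x: np.ndarray, x2: np.ndarray, hyper: GPHyperparams) -> float:
    """Squared-exponential covariance between two points."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    if x.shape != x2.shape or x.size != hyper.lengthscales.size:
        raise ValueError(
            f"dimension mismatch: x {x.shape}, x2 {x2.shape}, "
            f"lengthscales {hyper.lengthscales.shape}"
        )
    z = (x - x2) / hyper.lengthscales
    return float(hyper.sigma**2 * np.exp(-0.5 * np.dot(z, z)))


def sqexp_kernel_matrix(
    X: np.ndarray, X2: Optional[np.ndarray], hyper: GPHyperparams
) -> np.ndarray:
    """Covariance matrix between two point sets (no nugget added)."""
    X = np.atleast_2d(X)
    X2 = X if X2 is None else np.atleast_2d(X2)
    d2 = np.zeros((X.shape[0], X2.shape[0]))
    for i, ell in enumerate(hyper.lengthscales):
        diff = (X[:, i, None] - X2[None, :, i]) / ell
        d2 += diff**2
    return hyper.sigma**2 * np.exp(-0.5 * d2)


def _poly_basis(X: np.ndarray) -> np.ndarray:
    """First-order polynomial mean basis H = [1, x]."""
    return np.column_stack([np.ones(X.shape[0]), X])


class GPEmulator(RegressorMixin, BaseEstimator):
    """GP regressor with squared-exponential kernel and linear mean.

    Parameters
    ----------
    n_restarts : multi-start count for the hyperparameter optimizer.
    nugget_rel : diagonal jitter as a fraction of var(y); escalated tenfold on
        factorization failure up to ``nugget_max_rel``.
    objective : ``"ml"`` maximizes the profiled marginal likelihood; ``"reml"``
        maximizes the restricted likelihood, which integrates out the mean
        coefficients and removes the downward bias of the ML signal variance
        when the mean model spends many degrees of freedom (d+1 of n).
    normalize_inputs : standardize inputs to zero mean / unit SD before
        fitting, making lengthscales comparable across heterogeneous units.
    fixed_hyperparams : a :class:`GPHyperparams` (in *standardized* input
        space when ``normalize_inputs``) to use verbatim, skipping maximum
        likelihood.  Mean coefficients are still estimated by GLS.
    random_state : seed for the optimizer restarts (determinism contract).

    Attributes (after fit)
    ----------------------
    hyper_ : fitted :class:`GPHyperparams` (lengthscales in standardized units).
    beta_ : mean-function coefficients (intercept + d slopes).
    X_, y_ : standardized training design and centred outputs.
    L_ : Cholesky factor of K(X, X) + nugget * I.
    """

    def __init__(
        self,
        n_restarts: int = 10,
        nugget_rel: float = 1e-8,
        nugget_max_rel: float = 1e-2,
        estimate_nugget: bool = False,
        objective: str = "ml",
        normalize_inputs: bool = True,
        fixed_hyperparams: Optional[GPHyperparams] = None,
        lengthscale_bounds: tuple = (1e-2, 1e2),
        sigma_rel_bounds: tuple = (1e-6, 1e3),
        maxiter: int = 200,
        random_state: Optional[int] = None,
    ):
        self.n_restarts = n_restarts
        self.nugget_rel = nugget_rel
        self.nugget_max_rel = nugget_max_rel
        self.estimate_nugget = estimate_nugget
        self.objective = objective
        self.normalize_inputs = normalize_inputs
        self.fixed_hyperparams = fixed_hyperparams
        self.lengthscale_bounds = lengthscale_bounds
        self.sigma_rel_bounds = sigma_rel_bounds
        self.maxiter = maxiter
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GPEmulator":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim == 1:
            X = X[:, None]
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in training data")
        n, d = X.shape
        if y.size != n:
            raise ValueError("X and y lengths differ")
        if n < d + 2:
            raise ValueError(f"need n >= d + 2 = {d + 2} points for an identifiable linear mean")

        self.n_features_in_ = d
        if self.normalize_inputs:
            self._x_mean = X.mean(axis=0)
            scale = X.std(axis=0)
            self._x_scale = np.where(scale > 0, scale, 1.0)
        else:
            self._x_mean = np.zeros(d)
            self._x_scale = np.ones(d)
        self._y_mean = float(y.mean())

        self.X_ = (X - self._x_mean) / self._x_scale
        self.y_ = y - self._y_mean
        var_y = float(np.var(y))
        var_y = var_y if var_y > 0 else 1.0
        self._var_y = var_y

        if self.fixed_hyperparams is not None:
            hyper = self.fixed_hyperparams
            if hyper.lengthscales.size != d:
                raise ValueError("fixed_hyperparams dimension mismatch")
            self.hyper_ = GPHyperparams(
                hyper.sigma, hyper.lengthscales.copy(), hyper.nugget
            )
        else:
            self.hyper_ = self._maximize_likelihood(var_y)

        self._factorize(self.hyper_)
        return self

    # negative profiled log marginal likelihood and its gradient, in
    # theta = [log sigma, log Phi_1 .. log Phi_d (, log nugget)]; the nugget is
    # an extra ML parameter when estimate_nugget, otherwise held fixed
    def _nll_and_grad(self, theta: np.ndarray, nugget: float):
        n, d = self.X_.shape
        sigma = np.exp(theta[0])
        if self.estimate_nugget:
            ell = np.exp(theta[1 : 1 + d])
            nugget = float(np.exp(theta[-1]))
        else:
            ell = np.exp(theta[1:])
        hyper = GPHyperparams(sigma, ell, nugget)
        Kse = sqexp_kernel_matrix(self.X_, None, hyper)
        K = Kse + nugget * np.eye(n)
        try:
            L = linalg.cholesky(K, lower=True)
        except linalg.LinAlgError:
            return np.inf, np.zeros_like(theta)
        H = _poly_basis(self.X_)
        Kinv_H = linalg.cho_solve((L, True), H)
        Kinv_y = linalg.cho_solve((L, True), self.y_)
        A = H.T @ Kinv_H
        beta = linalg.solve(A, H.T @ Kinv_y, assume_a="pos")
        r = self.y_ - H @ beta
        alpha = linalg.cho_solve((L, True), r)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        nll = 0.5 * float(r @ alpha) + 0.5 * logdet + 0.5 * n * np.log(2 * np.pi)

        reml = self.objective == "reml"
        if reml:
            sign, logdet_A = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf, np.zeros_like(theta)
            nll += 0.5 * logdet_A
            # d logdet(A)/dtheta = -tr(A^{-1} H' K^{-1} dK K^{-1} H) = -sum(B * dK)
            B = Kinv_H @ linalg.solve(A, Kinv_H.T, assume_a="pos")

        Kinv = linalg.cho_solve((L, True), np.eye(n))
        grad = np.empty_like(theta)

        def _dir_deriv(dK: np.ndarray) -> float:
            g = -0.5 * float(alpha @ dK @ alpha) + 0.5 * float(np.sum(Kinv * dK))
            if reml:
                g -= 0.5 * float(np.sum(B * dK))
            return g

        # d K / d log sigma = 2 * Kse  (envelope theorem covers profiled beta)
        grad[0] = _dir_deriv(2.0 * Kse)
        for i in range(d):
            diff2 = (self.X_[:, i, None] - self.X_[None, :, i]) ** 2
            grad[1 + i] = _dir_deriv(Kse * (diff2 / ell[i] ** 2))  # d K / d log Phi_i
        if self.estimate_nugget:
            grad[-1] = _dir_deriv(nugget * np.eye(n))  # d K / d log nugget
        return nll, grad

    def _maximize_likelihood(self, var_y: float) -> GPHyperparams:
        n, d = self.X_.shape
        sd_y = np.sqrt(var_y)
        rng = np.random.default_rng(self.random_state)
        lo_s, hi_s = self.sigma_rel_bounds
        lo_l, hi_l = self.lengthscale_bounds
        bounds = [(np.log(lo_s * sd_y), np.log(hi_s * sd_y))] + [
            (np.log(lo_l), np.log(hi_l))
        ] * d
        if self.estimate_nugget:
            # noise variance searched between numerical jitter and var(y)
            bounds.append((np.log(1e-8 * var_y), np.log(var_y)))

        nugget = self.nugget_rel * var_y
        nugget_max = self.nugget_max_rel * var_y
        while True:
            best_theta, best_nll = None, np.inf
            for k in range(max(1, self.n_restarts)):
                if k == 0:
                    theta0 = np.concatenate([[np.log(sd_y)], np.zeros(d)])
                else:
                    theta0 = np.concatenate(
                        [
                            [np.log(sd_y) + 0.5 * rng.standard_normal()],
                            rng.uniform(np.log(0.3), np.log(3.0), size=d),
                        ]
                    )
                if self.estimate_nugget:
                    theta0 = np.append(theta0, np.log(1e-2 * var_y))
                res = optimize.minimize(
                    self._nll_and_grad,
                    theta0,
                    args=(nugget,),
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": self.maxiter},
                )
                if res.fun < best_nll:
                    best_theta, best_nll = res.x, float(res.fun)
            if np.isfinite(best_nll):
                d_end = 1 + d
                fitted_nugget = (
                    float(np.exp(best_theta[-1])) if self.estimate_nugget else nugget
                )
                return GPHyperparams(
                    float(np.exp(best_theta[0])), np.exp(best_theta[1:d_end]), fitted_nugget
                )
            nugget *= 10.0
            if nugget > nugget_max:
                raise linalg.LinAlgError(
                    "covariance not positive definite even at maximal nugget"
                )

    def _factorize(self, hyper: GPHyperparams) -> None:
        n = self.X_.shape[0]
        nugget = hyper.nugget if hyper.nugget > 0 else self.nugget_rel * self._var_y
        nugget_max = max(self.nugget_max_rel * self._var_y, nugget)
        while True:
            K = sqexp_kernel_matrix(self.X_, None, hyper) + nugget * np.eye(n)
            try:
                L = linalg.cholesky(K, lower=True)
                break
            except linalg.LinAlgError:
                nugget *= 10.0
                if nugget > nugget_max:
                    raise
        self.hyper_ = GPHyperparams(hyper.sigma, hyper.lengthscales, nugget)
        H = _poly_basis(self.X_)
        Kinv_H = linalg.cho_solve((L, True), H)
        Kinv_y = linalg.cho_solve((L, True), self.y_)
        A = H.T @ Kinv_H
        self.beta_ = linalg.solve(A, H.T @ Kinv_y, assume_a="pos")
        self._resid = self.y_ - H @ self.beta_
        self.alpha_ = linalg.cho_solve((L, True), self._resid)
        self.L_ = L
        self._A = A
        self._Kinv_H = Kinv_H

    # -------------------------------------------------------------- predict

    def _check_fitted(self) -> None:
        if not hasattr(self, "L_"):
            raise RuntimeError("GPEmulator is not fitted; call fit() first")

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return (X - self._x_mean) / self._x_scale

    def predict(
        self, X: np.ndarray, return_std: bool = False, include_mean_uncertainty: bool = False
    ):
        """Posterior mean (and optionally SD) at query points.

        The default variance is the conditional-GP form s^2(z) = K(z,z) -
        K(z,X)^T K(X,X)^{-1} K(z,X), which treats the mean function as known.
        ``include_mean_uncertainty=True`` adds the universal-kriging correction
        u^T (H^T K^{-1} H)^{-1} u with u = h(z) - H^T K^{-1} K(X,z), which
        propagates the uncertainty of the GLS-estimated mean coefficients
        (needed for calibrated intervals when n is barely above d+1).
        """
        self._check_fitted()
        Z = self._standardize(X)
        Kzx = sqexp_kernel_matrix(Z, self.X_, self.hyper_)
        mean = _poly_basis(Z) @ self.beta_ + Kzx @ self.alpha_ + self._y_mean
        if not return_std:
            return mean
        v = linalg.solve_triangular(self.L_, Kzx.T, lower=True)
        var = np.maximum(self.hyper_.sigma**2 - np.sum(v**2, axis=0), 0.0)
        if include_mean_uncertainty:
            u = _poly_basis(Z).T - self._Kinv_H.T @ Kzx.T
            var = var + np.sum(u * linalg.solve(self._A, u, assume_a="pos"), axis=0)
        return mean, np.sqrt(var)

    def predict_dist(self, X: np.ndarray) -> GPPrediction:
        """Posterior mean, variance and 95% interval (m +/- 1.96 s)."""
        mean, std = self.predict(X, return_std=True)
        ci = np.column_stack([mean - 1.96 * std, mean + 1.96 * std])
        return GPPrediction(mean=mean, variance=std**2, ci95=ci)

    def posterior_covariance(self, X: np.ndarray) -> np.ndarray:
        """Full posterior covariance matrix on a set of query points."""
        self._check_fitted()
        Z = self._standardize(X)
        Kzz = sqexp_kernel_matrix(Z, None, self.hyper_)
        Kzx = sqexp_kernel_matrix(Z, self.X_, self.hyper_)
        v = linalg.solve_triangular(self.L_, Kzx.T, lower=True)
        return Kzz - v.T @ v

    def sample_y(
        self, X: np.ndarray, n_samples: int = 1, random_state: Optional[int] = None
    ) -> np.ndarray:
        """Seeded draws from the posterior process on the query grid."""
        mean = self.predict(X)
        cov = self.posterior_covariance(X)
        return _mvn_draws(mean, cov, n_samples, random_state, self._var_y)

    # ------------------------------------------------------------------ LOO

    def loo(
        self,
        X: np.ndarray,
        y: np.ndarray,
        mode: str = "refit",
        include_mean_uncertainty: bool = True,
    ) -> LOOReport:
        """Leave-one-out cross-validation on the given training set.

        ``mode="refit"`` re-estimates hyperparameters on every fold (the
        literal definition of m_{-i}); ``mode="fixed"`` fits hyperparameters
        once on the full data and only recomputes the mean coefficients and
        posterior per fold (fast approximation, clearly labelled).  Fold
        variances include the mean-coefficient uncertainty by default, since
        left-out points probe the regime where the estimated trend matters.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        n, d = X.shape
        if n < d + 3:
            raise ValueError(f"LOO needs n >= d + 3 = {d + 3} points")
        if mode not in ("refit", "fixed"):
            raise ValueError(f"unknown LOO mode {mode!r}")

        if mode == "fixed":
            base = clone(self).fit(X, y)
            fixed = GPHyperparams(
                base.hyper_.sigma, base.hyper_.lengthscales.copy(), base.hyper_.nugget
            )

        means = np.empty(n)
        variances = np.empty(n)
        idx = np.arange(n)
        for i in range(n):
            keep = idx != i
            fold = clone(self)
            if mode == "fixed":
                fold.set_params(fixed_hyperparams=fixed)
            fold.set_params(random_state=self.fold_seed(i))
            try:
                fold.fit(X[keep], y[keep])
            except Exception as exc:  # noqa: BLE001 - re-raise naming the fold
                raise RuntimeError(f"LOO fold {i} failed to fit: {exc}") from exc
            m, s = fold.predict(
                X[i : i + 1], return_std=True, include_mean_uncertainty=include_mean_uncertainty
            )
            means[i], variances[i] = m[0], s[0] ** 2
        err = means - y
        mse = float(np.mean(err**2))
        lo = means - 1.96 * np.sqrt(variances)
        hi = means + 1.96 * np.sqrt(variances)
        coverage = int(np.sum((y >= lo) & (y <= hi)))
        mean_y = float(np.mean(y))
        rel = mse / mean_y if mean_y != 0 else np.inf
        return LOOReport(
            mean=means,
            variance=variances,
            y_true=y.copy(),
            mse_loo=mse,
            mse_loo_relative=rel,
            coverage_count=coverage,
            mode=mode,
        )

    # -------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        """JSON-serializable model state (hyperparameters, mean, training set)."""
        self._check_fitted()
        return {
            "hyper": {
                "sigma": self.hyper_.sigma,
                "lengthscales": self.hyper_.lengthscales.tolist(),
                "nugget": self.hyper_.nugget,
            },
            "mean_coeffs": self.beta_.tolist(),
            "x_mean": self._x_mean.tolist(),
            "x_scale": self._x_scale.tolist(),
            "y_mean": self._y_mean,
            "normalize_inputs": self.normalize_inputs,
            "X": (self.X_ * self._x_scale + self._x_mean).tolist(),
            "y": (self.y_ + self._y_mean).tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GPEmulator":
        """Rebuild a fitted emulator from :meth:`to_dict` output."""
        hyper = GPHyperparams(
            payload["hyper"]["sigma"],
            np.asarray(payload["hyper"]["lengthscales"]),
            payload["hyper"]["nugget"],
        )
        em = cls(
            fixed_hyperparams=hyper, normalize_inputs=payload.get("normalize_inputs", True)
        )
        return em.fit(np.asarray(payload["X"]), np.asarray(payload["y"]))

    def fold_seed(self, i: int) -> int:
        """Deterministic per-fold optimizer seed derived from random_state."""
        base = 0 if self.random_state is None else int(self.random_state)
        return (base * 1000003 + 7919 * (i + 1)) % (2**31)


def _mvn_draws(
    mean: np.ndarray,
    cov: np.ndarray,
    n_samples: int,
    random_state: Optional[int],
    var_scale: float,
) -> np.ndarray:
    """Cholesky-based MVN sampling with nugget escalation on the grid covariance."""
    rng = np.random.default_rng(random_state)
    n = mean.size
    jitter = 1e-12 * max(var_scale, float(np.max(np.abs(np.diag(cov)))), 1e-300)
    for _ in range(8):
        try:
            L = linalg.cholesky(cov + jitter * np.eye(n), lower=True)
            break
        except linalg.LinAlgError:
            jitter *= 10.0
    else:
        raise linalg.LinAlgError("grid covariance not positive definite after jitter escalation")
    z = rng.standard_normal((n, n_samples))
    return (mean[:, None] + L @ z).T


def gp_prior_samples(
    grid: np.ndarray,
    hyper: GPHyperparams,
    mean: float = 0.0,
    n_samples: int = 10,
    random_state: Optional[int] = None,
) -> np.ndarray:
    """Seeded sample functions from the GP prior on a finite grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim == 1:
        grid = grid[:, None]
    cov = sqexp_kernel_matrix(grid, None, hyper) + hyper.nugget * np.eye(grid.shape[0])
    mu = np.full(grid.shape[0], float(mean))
    return _mvn_draws(mu, cov, n_samples, random_state, hyper.sigma**2)


def loo_cv(X: np.ndarray, y: np.ndarray, mode: str = "refit", **emulator_kwargs) -> LOOReport:
    """Convenience wrapper: LOO cross-validation with a fresh :class:`GPEmulator`."""
    return GPEmulator(**emulator_kwargs).loo(X, y, mode=mode)
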