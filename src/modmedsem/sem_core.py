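"""Maximum-likelihood mean/covariance structure engine.

A :class:`SemModel` is defined by a *constraint function* mapping the free
parameter vector to the full set of model matrices (intercepts, loadings,
error variances, latent means, latent covariance).  Nonlinear constraints --
e.g. product-indicator loadings that are products of base loadings -- are
expressed simply by writing them into that function, so the same engine fits
both constrained and unconstrained latent-interaction models.

Fitting minimizes the normal-theory ML discrepancy with mean structure

    F(theta) = log|Sigma| + tr(S Sigma^-1) - log|S| - p
               + (xbar - mu)' Sigma^-1 (xbar - mu)

using analytic derivatives of F with respect to the implied moments chained
with finite-difference Jacobians of the (cheap, data-free) moment map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ModelMatrices",
    "SemModel",
    "FitResult",
    "DerivedEffects",
    "implied_moments",
    "ml_fit",
]

#: Gradient infinity-norm tolerance for declaring convergence.
GTOL = 1e-6
MAX_ITER = 500


@dataclass
class ModelMatrices:
    """Full parameter set of a linear measurement/structure model."""

    tau: np.ndarray      # (p,) intercepts
    lam: np.ndarray      # (p, q) loadings
    theta: np.ndarray    # (p,) error variances (diagonal)
    alpha: np.ndarray    # (q,) latent means
    psi: np.ndarray      # (q, q) latent covariance


@dataclass
class SemModel:
    observed: list[str]
    latent: list[str]
    param_names: list[str]
    start: np.ndarray
    constraint_fn: Callable[[np.ndarray], ModelMatrices]
    #: parameter names whose estimates must be non-negative for a proper solution
    variance_params: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        if len(self.start) != len(self.param_names):
            raise ValueError("start values and parameter names differ in length")
        unknown = set(self.variance_params) - set(self.param_names)
        if unknown:
            raise ValueError(f"variance_params not in param_names: {sorted(unknown)}")

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    def index(self, name: str) -> int:
        return self.param_names.index(name)

    def to_yaml(self, path) -> None:
        """Serialize the model's structural skeleton (names, starts, which
        parameters are variances).  The constraint function itself is code;
        rebuild it with the model builders (e.g. estimators_pi)."""
        import yaml

        doc = {
            "observed": list(self.observed),
            "latent": list(self.latent),
            "param_names": list(self.param_names),
            "start": [float(v) for v in self.start],
            "variance_params": list(self.variance_params),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class DerivedEffects:
    """Moderated-mediation summaries derived from (a, b1, b3) estimates.

    ``index`` is a*b3 (change of the indirect effect per unit moderator);
    ``ind`` maps moderator values z in {-1 SD, 0, +1 SD} to the conditional
    indirect effect a*(b1 + b3*z).
    """

    b3: float
    index: float
    ind: dict[str, float]          # keys: "-1sd", "0", "+1sd"
    sd_moderator: float
    se: dict[str, float] | None = None     # same keys plus "b3", "index"
    p: dict[str, float] | None = None

    @staticmethod
    def from_paths(
        a: float, b1: float, b3: float, sd_z: float
    ) -> "DerivedEffects":
        return DerivedEffects(
            b3=b3,
            index=a * b3,
            ind={
                "-1sd": a * (b1 - b3 * sd_z),
                "0": a * b1,
                "+1sd": a * (b1 + b3 * sd_z),
            },
            sd_moderator=sd_z,
        )


@dataclass
class FitResult:
    method: str
    estimates: dict[str, float]
    loglik: float
    converged: bool
    proper_solution: bool
    n_obs: int
    se: dict[str, float] | None = None
    ci_lower: dict[str, float] | None = None
    ci_upper: dict[str, float] | None = None
    grad_norm: float = np.nan
    cov: np.ndarray | None = None      # free-parameter covariance (order of param_names)
    param_names: list[str] | None = None
    n_free: int = 0

    def theta(self) -> np.ndarray:
        return np.array([self.estimates[k] for k in self.param_names])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.estimates:
            rows.append(
                {
                    "parameter": name,
                    "estimate": self.estimates[name],
                    "se": self.se.get(name, np.nan) if self.se else np.nan,
                }
            )
        return pd.DataFrame(rows)


def implied_moments(
    model: SemModel, free_params: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Implied mean vector and covariance matrix of the observed variables."""
    theta = np.asarray(free_params, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("free parameters must be finite")
    mm = model.constraint_fn(theta)
    mu = mm.tau + mm.lam @ mm.alpha
    sigma = mm.lam @ mm.psi @ mm.lam.T + np.diag(mm.theta)
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise RuntimeError("implied covariance is not symmetric")
    return mu, 0.5 * (sigma + sigma.T)


def _moment_jacobians(
    model: SemModel, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference Jacobians d(mu)/d(theta), d(Sigma)/d(theta).

    The moment map is data-free and cheap (small matrix algebra), so numerical
    Jacobians here cost nothing compared to likelihood evaluations.
    """
    k = len(theta)
    p = len(model.observed)
    dmu = np.empty((k, p))
    dsig = np.empty((k, p, p))
    for j in range(k):
        h = 1e-6 * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        mu_p, sig_p = implied_moments(model, tp)
        mu_m, sig_m = implied_moments(model, tm)
        dmu[j] = (mu_p - mu_m) / (2 * h)
        dsig[j] = (sig_p - sig_m) / (2 * h)
    return dmu, dsig


_PENALTY = 1e10


def _discrepancy_and_grad(
    model: SemModel,
    theta: np.ndarray,
    xbar: np.ndarray,
    S: np.ndarray,
    logdet_S: float,
    want_grad: bool,
) -> tuple[float, np.ndarray | None]:
    p = len(xbar)
    try:
        mu, sigma = implied_moments(model, theta)
        L = np.linalg.cholesky(sigma)
    except (np.linalg.LinAlgError, ValueError):
        return _PENALTY, (np.zeros(len(theta)) if want_grad else None)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    sigma_inv = np.linalg.inv(sigma)
    d = xbar - mu
    sd = sigma_inv @ d
    F = logdet + np.sum(sigma_inv * S) - logdet_S - p + d @ sd
    if not np.isfinite(F):
        return _PENALTY, (np.zeros(len(theta)) if want_grad else None)
    if not want_grad:
        return F, None
    # dF/dSigma = Sigma^-1 - Sigma^-1 (S + d d') Sigma^-1 ; dF/dmu = -2 Sigma^-1 d
    dF_dsigma = sigma_inv - sigma_inv @ (S + np.outer(d, d)) @ sigma_inv
    dF_dmu = -2.0 * sd
    dmu, dsig = _moment_jacobians(model, theta)
    grad = dmu @ dF_dmu + np.einsum("kij,ij->k", dsig, dF_dsigma)
    return F, grad


def _sample_moments(data, observed: Sequence[str]) -> tuple[int, np.ndarray, np.ndarray]:
    if hasattr(data, "values") and not isinstance(data, pd.DataFrame):
        frame = data.values  # IndicatorDataset
    else:
        frame = data
    X = np.asarray(frame.loc[:, list(observed)], dtype=float)
    n = X.shape[0]
    xbar = X.mean(axis=0)
    Xc = X - xbar
    S = Xc.T @ Xc / n  # ML covariance (divisor n)
    return n, xbar, S


def ml_fit(
    model: SemModel,
    data,
    *,
    start: np.ndarray | None = None,
    compute_se: bool = False,
    gtol: float = GTOL,
    max_iter: int = MAX_ITER,
    method_label: str | None = None,
) -> FitResult:
    """Fit a SemModel by normal-theory ML.

    Non-convergence is reported through the ``converged`` flag (never raised)
    so Monte-Carlo completion rates can be tallied.  A solution is *proper*
    when the optimizer converged, every variance-type estimate is
    non-negative, and the implied covariance at the optimum is positive
    definite.
    """
    n, xbar, S = _sample_moments(data, model.observed)
    p = len(model.observed)
    if n <= p:
        raise ValueError(f"need more cases ({n}) than observed variables ({p})")
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(logdet_S):
        raise ValueError(
            "singular sample covariance (zero-variance or collinear columns)"
        )
    theta0 = model.start if start is None else np.asarray(start, dtype=float)

    def obj(t):
        return _discrepancy_and_grad(model, t, xbar, S, logdet_S, want_grad=True)

    theta_hat = theta0
    for _ in range(3):  # L-BFGS-B restarts recover from premature ftol stops
        res = optimize.minimize(
            obj,
            theta_hat,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": gtol / 10},
        )
        theta_hat = res.x
        F_hat, grad = _discrepancy_and_grad(model, theta_hat, xbar, S, logdet_S, True)
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < gtol or not np.isfinite(F_hat) or F_hat >= _PENALTY:
            break
    converged = bool(np.isfinite(F_hat) and F_hat < _PENALTY and grad_norm < gtol)

    # loglik of the fitted model
    if F_hat < _PENALTY:
        loglik = -0.5 * n * (p * np.log(2 * np.pi) + F_hat + logdet_S + p)
    else:
        loglik = -np.inf

    estimates = dict(zip(model.param_names, theta_hat))
    proper = converged
    if proper:
        for name in model.variance_params:
            if estimates[name] < 0:
                proper = False
                break
    if proper:
        try:
            _, sigma_hat = implied_moments(model, theta_hat)
            np.linalg.cholesky(sigma_hat)
        except (np.linalg.LinAlgError, ValueError):
            proper = False

    result = FitResult(
        method=method_label or "ml",
        estimates=estimates,
        loglik=float(loglik),
        converged=converged,
        proper_solution=bool(proper),
        n_obs=n,
        grad_norm=grad_norm,
        param_names=list(model.param_names),
        n_free=model.n_free,
    )
    if compute_se and converged:
        cov = _observed_info_cov(model, theta_hat, xbar, S, logdet_S, n)
        if cov is not None:
            result.cov = cov
            ses = np.sqrt(np.clip(np.diag(cov), 0, None))
            result.se = dict(zip(model.param_names, ses))
            z = 1.959963984540054
            result.ci_lower = {
                k: result.estimates[k] - z * result.se[k] for k in model.param_names
            }
            result.ci_upper = {
                k: result.estimates[k] + z * result.se[k] for k in model.param_names
            }
    return result


def _observed_info_cov(model, theta, xbar, S, logdet_S, n) -> np.ndarray | None:
    """Inverse observed information: Hessian of -loglik = (n/2) Hessian of F."""
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        _, gp = _discrepancy_and_grad(model, tp, xbar, S, logdet_S, True)
        _, gm = _discrepancy_and_grad(model, tm, xbar, S, logdet_S, True)
        H[j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T) * (n / 2.0)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
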