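"""Latent moderated structural equations (LMS).

The interaction M*Z never gets indicators.  Conditional on the moderator
Z = z, the model is linear-Gaussian: X | Z=z is Gaussian via Cov(X,Z),
M = aX + d_M, and Y = cX + (b1 + b3 z) M + b2 z + d_Y, so the 14 indicators
are jointly Gaussian with node-specific mean mu_k and covariance Sigma_k.
Marginalizing Z by Gauss-Hermite quadrature turns the likelihood into a
finite Gaussian mixture over the quadrature nodes:

    L(case) = sum_k w_k N(case; mu_k, Sigma_k)

which is maximized directly.  Gradients are computed analytically with
respect to the node moments (responsibility-weighted Gaussian identities)
and chained with finite-difference Jacobians of the cheap, data-free map
theta -> (mu_k, Sigma_k); per-case score vectors for the sandwich (robust)
covariance come from the same decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .popgen import BLOCKS, COLUMNS, IndicatorDataset
from .estimators_pa import fit_pa
from .estimators_pi import (
    _base_param_names,
    estimate_block_loadings,
    derived_effects_from_fit,
)
from .sem_core import DerivedEffects, FitResult

__all__ = [
    "LmsModel",
    "JnBand",
    "lms_loglik",
    "fit_lms",
    "robust_se",
    "lr_model_comparison",
    "johnson_neyman",
]

_PENALTY = 1e10
#: convergence tolerance on the per-observation log-likelihood gradient
GTOL_PER_OBS = 1e-5
MAX_ITER = 500


@dataclass
class LmsModel:
    """Parameter layout and quadrature order of the LMS estimator."""

    K: int = 16
    interaction: bool = True

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("quadrature order K must be >= 2")
        self.param_names = _base_param_names(self.interaction)

    @property
    def n_free(self) -> int:
        return len(self.param_names)


class _Engine:
    """Likelihood/gradient evaluator bound to one dataset and quadrature rule."""

    def __init__(self, X: np.ndarray, model: LmsModel):
        self.X = X  # (n, p)
        self.n, self.p = X.shape
        self.model = model
        self.names = model.param_names
        self.idx = {n: i for i, n in enumerate(self.names)}
        t, w = special.roots_hermite(model.K)
        self.t_nodes = t
        with np.errstate(divide="ignore"):
            self.logw = np.log(w / np.sqrt(np.pi))  # -inf for underflowed tails is fine
        # index vectors mapping observed rows to their parameters
        lam_idx, tau_idx, th_idx, lat_col = [], [], [], []
        for label, cols in BLOCKS.items():
            lat = {"X": 0, "M": 1, "Z": 2, "Y": 3}[label]
            for j, cname in enumerate(cols):
                lat_col.append(lat)
                lam_idx.append(-1 if j == 0 else self.idx[f"lam_{cname}"])
                tau_idx.append(self.idx[f"tau_{cname}"])
                th_idx.append(self.idx[f"th_{cname}"])
        self._lam_idx = np.array(lam_idx)
        self._tau_idx = np.array(tau_idx)
        self._th_idx = np.array(th_idx)
        self._lat_col = np.array(lat_col)

    # ---- moment map -------------------------------------------------------
    def node_moments(self, theta: np.ndarray):
        """Per-node means (..., K, p) and covariances (..., K, p, p).

        Accepts a single parameter vector or a batch (B, n_params) -- batching
        is what makes the finite-difference Jacobians of this (data-free) map
        cheap.  Returns None when the parameter point is inadmissible
        (non-positive latent variances / conditional variance).
        """
        theta = np.asarray(theta, dtype=float)
        scalar = theta.ndim == 1
        tb = theta[None, :] if scalar else theta
        B = tb.shape[0]
        g = lambda name: tb[:, self.idx[name]]
        var_z, var_x, cov_xz = g("var_z"), g("var_x"), g("cov_xz")
        if np.any(var_z <= 0) or np.any(var_x <= 0):
            return None
        v_x = var_x - cov_xz**2 / var_z  # Var(X | Z), (B,)
        if np.any(v_x <= 0):
            return None
        a, b1, b2, c = g("a"), g("b1"), g("b2"), g("c")
        b3 = g("b3") if self.model.interaction else np.zeros(B)
        resid_m, resid_y = g("resid_m"), g("resid_y")

        z = np.sqrt(2.0 * var_z)[:, None] * self.t_nodes  # (B, K)
        lam_vals = np.where(self._lam_idx < 0, 1.0, tb[:, self._lam_idx])  # (B, p)
        tau = tb[:, self._tau_idx]
        th = tb[:, self._th_idx]
        lam = np.zeros((B, self.p, 4))
        lam[:, np.arange(self.p), self._lat_col] = lam_vals

        r = cov_xz / var_z
        beta = b1[:, None] + b3[:, None] * z  # (B, K)
        m_x = r[:, None] * z
        m_m = a[:, None] * m_x
        m_y = c[:, None] * m_x + beta * m_m + b2[:, None] * z
        lat_mean = np.stack([m_x, m_m, z, m_y], axis=2)  # (B, K, 4)
        mus = tau[:, None, :] + np.einsum("bki,bpi->bkp", lat_mean, lam)

        v_m = a**2 * v_x + resid_m  # (B,)
        c_xm = a * v_x
        c_xy = c[:, None] * v_x[:, None] + beta * c_xm[:, None]  # (B, K)
        c_my = c[:, None] * c_xm[:, None] + beta * v_m[:, None]
        v_y = (
            (c**2 * v_x)[:, None]
            + beta**2 * v_m[:, None]
            + 2 * c[:, None] * beta * c_xm[:, None]
            + resid_y[:, None]
        )
        K = self.model.K
        psi = np.zeros((B, K, 4, 4))
        psi[:, :, 0, 0] = v_x[:, None]
        psi[:, :, 0, 1] = psi[:, :, 1, 0] = c_xm[:, None]
        psi[:, :, 1, 1] = v_m[:, None]
        psi[:, :, 0, 3] = psi[:, :, 3, 0] = c_xy
        psi[:, :, 1, 3] = psi[:, :, 3, 1] = c_my
        psi[:, :, 3, 3] = v_y
        sigmas = lam[:, None, :, :] @ psi @ lam[:, None, :, :].transpose(0, 1, 3, 2)
        sigmas[:, :, np.arange(self.p), np.arange(self.p)] += th[:, None, :]
        if scalar:
            return mus[0], sigmas[0]
        return mus, sigmas

    def _moment_jacobians(self, theta: np.ndarray):
        k = len(theta)
        h = 1e-6 * (1.0 + np.abs(theta))
        batch = np.concatenate(
            [theta[None, :] + np.diag(h), theta[None, :] - np.diag(h)], axis=0
        )
        nm = self.node_moments(batch)
        if nm is None:
            return None
        mus, sigmas = nm
        scale = 1.0 / (2 * h)
        dmu = (mus[:k] - mus[k:]) * scale[:, None, None]
        dsig = (sigmas[:k] - sigmas[k:]) * scale[:, None, None, None]
        return dmu, dsig

    # ---- likelihood -------------------------------------------------------
    def _mixture_parts(self, theta: np.ndarray):
        nm = self.node_moments(theta)
        if nm is None:
            return None
        mus, sigmas = nm
        sign, logdet = np.linalg.slogdet(sigmas)
        if np.any(sign <= 0):
            return None
        diffs = self.X.T[None, :, :] - mus[:, :, None]  # (K, p, n)
        try:
            sol = np.linalg.solve(sigmas, diffs)
        except np.linalg.LinAlgError:
            return None
        quad = np.einsum("kpn,kpn->kn", diffs, sol)
        logcomp = (
            self.logw[:, None]
            - 0.5 * (self.p * np.log(2 * np.pi) + logdet)[:, None]
            - 0.5 * quad
        )  # (K, n)
        m = logcomp.max(axis=0)
        lse = m + np.log(np.exp(logcomp - m).sum(axis=0))
        resp = np.exp(logcomp - lse)  # responsibilities (K, n)
        return lse, resp, sol, sigmas

    def casewise_loglik(self, theta: np.ndarray) -> np.ndarray:
        parts = self._mixture_parts(theta)
        if parts is None:
            return np.full(self.n, -_PENALTY)
        return parts[0]

    def loglik(self, theta: np.ndarray) -> float:
        return float(self.casewise_loglik(theta).sum())

    def negloglik_grad(self, theta: np.ndarray):
        parts = self._mixture_parts(theta)
        if parts is None:
            return _PENALTY, np.zeros(len(theta))
        lse, resp, sol, sigmas = parts
        jac = self._moment_jacobians(theta)
        if jac is None:
            return _PENALTY, np.zeros(len(theta))
        dmu, dsig = jac
        invs = np.linalg.inv(sigmas)
        wsol = sol * resp[:, None, :]
        g_mu = wsol.sum(axis=2)  # (K, p)
        A = np.einsum("kpn,kqn->kpq", wsol, sol)
        R = resp.sum(axis=1)
        g_sig = 0.5 * (A - R[:, None, None] * invs)
        grad = np.einsum("kp,jkp->j", g_mu, dmu) + np.einsum(
            "kpq,jkpq->j", g_sig, dsig
        )
        return -float(lse.sum()), -grad

    def casewise_scores(self, theta: np.ndarray) -> np.ndarray:
        """Per-case score vectors (n, n_params) of the log-likelihood."""
        parts = self._mixture_parts(theta)
        if parts is None:
            raise RuntimeError("likelihood is not defined at theta")
        _, resp, sol, sigmas = parts
        jac = self._moment_jacobians(theta)
        if jac is None:
            raise RuntimeError("moment map not differentiable at theta")
        dmu, dsig = jac
        invs = np.linalg.inv(sigmas)
        wsol = sol * resp[:, None, :]
        s = np.einsum("kpn,jkp->jn", wsol, dmu)
        s += 0.5 * np.einsum("kpn,kqn,jkpq->jn", wsol, sol, dsig)
        tr = np.einsum("kpq,jkpq->jk", invs, dsig)  # (j, K)
        s -= 0.5 * np.einsum("kn,jk->jn", resp, tr)
        return s.T


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, IndicatorDataset):
        return data.values.loc[:, list(COLUMNS)].to_numpy(dtype=float)
    return np.asarray(pd.DataFrame(data).loc[:, list(COLUMNS)], dtype=float)


def lms_loglik(model: LmsModel, params, data) -> float:
    """Quadrature-mixture log-likelihood of the full sample at ``params``."""
    theta = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("parameters must be finite")
    engine = _Engine(_as_matrix(data), model)
    return engine.loglik(theta)


def start_values(data: IndicatorDataset, param_names) -> np.ndarray:
    """Moment-based start values: block CFA moments plus composite-regression paths."""
    frame = data.values
    start = np.zeros(len(param_names))
    idx = {n: i for i, n in enumerate(param_names)}
    phis = {}
    for label, cols in BLOCKS.items():
        lam = estimate_block_loadings(data, label)
        sub = frame.loc[:, list(cols)]
        rest_mean = sub.iloc[:, 1:].mean(axis=1)
        denom = max(lam[1:].mean(), 0.2)
        phi = float(np.cov(sub.iloc[:, 0], rest_mean)[0, 1] / denom)
        phi = min(max(phi, 0.05), 10.0)
        phis[label] = phi
        for j, cname in enumerate(cols):
            if j > 0:
                start[idx[f"lam_{cname}"]] = float(np.clip(lam[j], -3.0, 3.0))
            start[idx[f"tau_{cname}"]] = sub[cname].mean()
            lam_j = 1.0 if j == 0 else start[idx[f"lam_{cname}"]]
            resid = sub[cname].var() - lam_j**2 * phi
            start[idx[f"th_{cname}"]] = float(np.clip(resid, 0.05, None))
    pa_fit, _ = fit_pa(data)
    for name in ("a", "b1", "b2", "c"):
        start[idx[name]] = pa_fit.estimates[name]
    if "b3" in idx:
        start[idx["b3"]] = pa_fit.estimates["b3"]
    start[idx["var_x"]] = phis["X"]
    start[idx["var_z"]] = phis["Z"]
    xc = frame.loc[:, list(BLOCKS["X"])].mean(axis=1)
    zc = frame.loc[:, list(BLOCKS["Z"])].mean(axis=1)
    start[idx["cov_xz"]] = float(np.cov(xc, zc)[0, 1])
    a0 = start[idx["a"]]
    start[idx["resid_m"]] = float(np.clip(phis["M"] - a0**2 * phis["X"], 0.1, None))
    start[idx["resid_y"]] = float(np.clip(0.5 * phis["Y"], 0.1, None))
    return start


def fit_lms(
    data,
    K: int = 16,
    *,
    fix_b3: bool = False,
    se: str = "robust",
    start: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
) -> tuple[FitResult, DerivedEffects]:
    """Maximize the LMS marginal likelihood.

    ``se`` is one of ``"robust"`` (sandwich, the default), ``"hessian"``
    (inverse observed information), or ``"none"``.  Non-convergence is flagged
    on the result, never raised.
    """
    if not isinstance(data, IndicatorDataset):
        data = IndicatorDataset(pd.DataFrame(data))
    model = LmsModel(K=K, interaction=not fix_b3)
    engine = _Engine(_as_matrix(data), model)
    theta0 = start_values(data, model.param_names) if start is None else np.asarray(start, float)

    theta_hat = theta0
    for _ in range(3):  # restarts recover from premature line-search stops
        res = optimize.minimize(
            engine.negloglik_grad,
            theta_hat,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": max_iter,
                "ftol": 1e-13,
                "gtol": GTOL_PER_OBS * engine.n / 10,
            },
        )
        theta_hat = res.x
        f_hat, grad = engine.negloglik_grad(theta_hat)
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < GTOL_PER_OBS * engine.n or f_hat >= _PENALTY:
            break
    converged = bool(f_hat < _PENALTY and grad_norm < GTOL_PER_OBS * engine.n)
    estimates = dict(zip(model.param_names, theta_hat))

    proper = converged
    if proper:
        for name in model.param_names:
            if name.startswith(("th_", "var_", "resid_")) and estimates[name] < 0:
                proper = False
                break
    if proper:
        s = estimates
        if s["var_x"] * s["var_z"] - s["cov_xz"] ** 2 <= 0:
            proper = False

    fit = FitResult(
        method="lms" if not fix_b3 else "lms0",
        estimates=estimates,
        loglik=-f_hat if f_hat < _PENALTY else -np.inf,
        converged=converged,
        proper_solution=bool(proper),
        n_obs=engine.n,
        grad_norm=grad_norm,
        param_names=list(model.param_names),
        n_free=model.n_free,
    )
    if se != "none" and converged:
        try:
            _attach_se(fit, engine, theta_hat, flavor=se)
        except (np.linalg.LinAlgError, RuntimeError):
            fit.se = None
    return fit, derived_effects_from_fit(fit)


def _hessian(engine: _Engine, theta: np.ndarray) -> np.ndarray:
    """Numerical Hessian of the negative log-likelihood from analytic gradients."""
    k = len(theta)
    H = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = engine.negloglik_grad(tp)
        _, gm = engine.negloglik_grad(tm)
        H[j] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def _attach_se(fit: FitResult, engine: _Engine, theta: np.ndarray, flavor: str) -> None:
    A = _hessian(engine, theta)
    A_inv = np.linalg.inv(A)
    if flavor == "robust":
        scores = engine.casewise_scores(theta)
        B = scores.T @ scores
        cov = A_inv @ B @ A_inv
    elif flavor == "hessian":
        cov = A_inv
    else:
        raise ValueError(f"unknown se flavor {flavor!r}")
    cov = 0.5 * (cov + cov.T)
    fit.cov = cov
    ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    fit.se = dict(zip(fit.param_names, ses))
    z = 1.959963984540054
    fit.ci_lower = {k: fit.estimates[k] - z * fit.se[k] for k in fit.param_names}
    fit.ci_upper = {k: fit.estimates[k] + z * fit.se[k] for k in fit.param_names}


def robust_se(fit: FitResult, data, K: int = 16) -> dict[str, float]:
    """Sandwich standard errors A^-1 B A^-1 at the fitted parameters.

    A is the observed-information (Hessian) matrix of the negative
    log-likelihood; B the sum of per-case score outer products.  Updates the
    fit in place and returns the SE mapping.  A singular A raises
    ``np.linalg.LinAlgError`` so callers can count the replication as
    non-complete for SE-based metrics.
    """
    if not fit.converged:
        raise ValueError("robust SEs require a converged fit")
    if not isinstance(data, IndicatorDataset):
        data = IndicatorDataset(pd.DataFrame(data))
    model = LmsModel(K=K, interaction="b3" in fit.estimates)
    engine = _Engine(_as_matrix(data), model)
    theta = np.array([fit.estimates[n] for n in fit.param_names])
    _attach_se(fit, engine, theta, flavor="robust")
    return fit.se


def lr_model_comparison(
    fit_without_interaction: FitResult, fit_with_interaction: FitResult
) -> tuple[float, int, float]:
    """Likelihood-ratio comparison of the linear model against the LMS model.

    Returns (-2 (l0 - l1), df=1, p).  A materially negative statistic signals
    an optimizer failure in the larger model and is truncated to 0 after the
    tolerance check.
    """
    lr = -2.0 * (fit_without_interaction.loglik - fit_with_interaction.loglik)
    if lr < -1e-6 * max(1.0, abs(fit_with_interaction.loglik)):
        import warnings

        warnings.warn(
            "interaction model has lower log-likelihood than the null model; "
            "optimizer may not have converged",
            RuntimeWarning,
            stacklevel=2,
        )
    lr = max(lr, 0.0)
    return lr, 1, float(stats.chi2.sf(lr, 1))


@dataclass
class JnBand:
    """Johnson-Neyman band: simple slope b1 + b3 z with a 95% pointwise CI."""

    z: np.ndarray
    slope: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    significant: np.ndarray  # boolean mask where the CI excludes 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": self.z,
                "slope": self.slope,
                "se": self.se,
                "ci_lower": self.lower,
                "ci_upper": self.upper,
                "significant": self.significant,
            }
        )


def johnson_neyman(fit: FitResult, z_grid, alpha: float = 0.05) -> JnBand:
    """Confidence band around the simple slope of M on Y across moderator values."""
    if fit.cov is None or fit.param_names is None:
        raise ValueError("fit carries no parameter covariance; compute SEs first")
    i1, i3 = fit.param_names.index("b1"), fit.param_names.index("b3")
    b1, b3 = fit.estimates["b1"], fit.estimates["b3"]
    v1, v3 = fit.cov[i1, i1], fit.cov[i3, i3]
    c13 = fit.cov[i1, i3]
    z = np.asarray(z_grid, dtype=float)
    slope = b1 + b3 * z
    se = np.sqrt(np.clip(v1 + z**2 * v3 + 2 * z * c13, 0, None))
    crit = stats.norm.ppf(1 - alpha / 2)
    lower, upper = slope - crit * se, slope + crit * se
    return JnBand(
        z=z, slope=slope, se=se, lower=lower, upper=upper,
        significant=(lower > 0) | (upper < 0),
    )


def jn_crossover_points(fit: FitResult, alpha: float = 0.05) -> np.ndarray:
    """Roots of (b1 + b3 z)^2 = crit^2 SE(z)^2 (closed-form region boundaries)."""
    if fit.cov is None:
        raise ValueError("fit carries no parameter covariance")
    i1, i3 = fit.param_names.index("b1"), fit.param_names.index("b3")
    b1, b3 = fit.estimates["b1"], fit.estimates["b3"]
    v1, v3 = fit.cov[i1, i1], fit.cov[i3, i3]
    c13 = fit.cov[i1, i3]
    crit2 = stats.norm.ppf(1 - alpha / 2) ** 2
    # (b1 + b3 z)^2 - crit2 (v1 + z^2 v3 + 2 z c13) = 0
    A = b3**2 - crit2 * v3
    Bq = 2 * (b1 * b3 - crit2 * c13)
    C = b1**2 - crit2 * v1
    disc = Bq**2 - 4 * A * C
    if A == 0 or disc < 0:
        return np.array([])
    roots = np.array([(-Bq - np.sqrt(disc)) / (2 * A), (-Bq + np.sqrt(disc)) / (2 * A)])
    return np.sort(roots)
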