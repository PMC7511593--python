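"""Composite-score path analysis (PA).

Each latent variable is replaced by the unweighted mean of its indicators and
the two structural equations are fitted by least squares:

    Mc = i1 + a*Xc + e1
    Yc = i2 + c*Xc + b1*Mc + b2*Zc + b3*Mc*Zc + e2

PA ignores measurement error, so its path estimates are attenuated; with the
usual ~.8 reliabilities this underestimates the interaction slope by roughly
8%, and by over 50% when reliabilities drop to ~.6.  The moderated-mediation
index a*b3 and the conditional indirect effects a*(b1 + b3*z) are derived
from the fitted paths, with z at the sample SD of the composite moderator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen import BLOCKS, IndicatorDataset
from .sem_core import DerivedEffects, FitResult

__all__ = ["CompositeData", "make_composites", "fit_pa"]


@dataclass
class CompositeData:
    """Composite (mean) scores per case: Xc, Mc, Zc, Yc and the product MZc."""

    frame: pd.DataFrame  # columns Xc, Mc, Zc, Yc, MZc
    centered: bool

    @property
    def n(self) -> int:
        return len(self.frame)


def make_composites(
    data: IndicatorDataset, center_before_product: bool = True
) -> CompositeData:
    """Block means and their product term.

    When ``center_before_product`` (default), Mc and Zc are mean-centered
    before multiplying; this leaves the interaction slope b3 and all derived
    moderated-mediation quantities unchanged and only reparameterizes the
    lower-order coefficients.
    """
    comp = {
        "Xc": data.block("X").mean(axis=1),
        "Mc": data.block("M").mean(axis=1),
        "Zc": data.block("Z").mean(axis=1),
        "Yc": data.block("Y").mean(axis=1),
    }
    frame = pd.DataFrame(comp)
    if center_before_product:
        frame["MZc"] = (frame["Mc"] - frame["Mc"].mean()) * (
            frame["Zc"] - frame["Zc"].mean()
        )
    else:
        frame["MZc"] = frame["Mc"] * frame["Zc"]
    return CompositeData(frame=frame, centered=center_before_product)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """OLS estimates and coefficient covariance; flags rank deficiency."""
    n, k = X.shape
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return np.full(k, np.nan), np.full((k, k), np.nan), False
    if np.linalg.cond(xtx) > 1e12:
        return np.full(k, np.nan), np.full((k, k), np.nan), False
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (n - k)
    return beta, s2 * xtx_inv, True


def fit_pa(
    data: IndicatorDataset, center_before_product: bool = True
) -> tuple[FitResult, DerivedEffects]:
    """Fit the two composite regressions and derive moderated-mediation effects.

    Least squares always yields a solution for full-rank designs, so the
    completion rate of PA is 1 by construction; a collinear design matrix is
    reported as a non-converged result, never raised.
    """
    comp = make_composites(data, center_before_product).frame
    n = len(comp)
    if n <= 6:
        raise ValueError("need more than 6 cases for the PA regressions")
    ones = np.ones(n)
    Xm = np.column_stack([ones, comp["Xc"]])
    beta_m, cov_m, ok_m = _ols(comp["Mc"].to_numpy(), Xm)
    Xy = np.column_stack([ones, comp["Xc"], comp["Mc"], comp["Zc"], comp["MZc"]])
    beta_y, cov_y, ok_y = _ols(comp["Yc"].to_numpy(), Xy)
    converged = bool(ok_m and ok_y)

    names = ["a", "c", "b1", "b2", "b3"]
    if converged:
        a = beta_m[1]
        c, b1, b2, b3 = beta_y[1:]
        estimates = {"a": a, "c": c, "b1": b1, "b2": b2, "b3": b3}
        se = {
            "a": np.sqrt(cov_m[1, 1]),
            "c": np.sqrt(cov_y[1, 1]),
            "b1": np.sqrt(cov_y[2, 2]),
            "b2": np.sqrt(cov_y[3, 3]),
            "b3": np.sqrt(cov_y[4, 4]),
        }
        # Gaussian loglik of the two regressions (ML variance estimates)
        resid_m = comp["Mc"].to_numpy() - Xm @ beta_m
        resid_y = comp["Yc"].to_numpy() - Xy @ beta_y
        ll = 0.0
        for r in (resid_m, resid_y):
            s2 = r @ r / n
            ll += -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
        sd_z = comp["Zc"].std(ddof=1)
        effects = DerivedEffects.from_paths(a, b1, b3, sd_z)
        effects.se = _delta_method_se(a, b1, b3, sd_z, cov_m, cov_y)
    else:
        estimates = {k: np.nan for k in names}
        se = None
        ll = np.nan
        effects = DerivedEffects(
            b3=np.nan, index=np.nan,
            ind={"-1sd": np.nan, "0": np.nan, "+1sd": np.nan},
            sd_moderator=np.nan,
        )

    z = 1.959963984540054
    fit = FitResult(
        method="pa",
        estimates=estimates,
        se=se,
        ci_lower={k: estimates[k] - z * se[k] for k in names} if se else None,
        ci_upper={k: estimates[k] + z * se[k] for k in names} if se else None,
        loglik=float(ll),
        converged=converged,
        proper_solution=converged,
        n_obs=n,
        param_names=names,
        n_free=len(names) + 2,  # + two intercepts
    )
    return fit, effects


def _delta_method_se(a, b1, b3, sd_z, cov_m, cov_y) -> dict[str, float]:
    """Delta-method SEs of b3, a*b3 and the conditional indirect effects.

    The two regressions have independent errors, so the joint covariance of
    (a, b1, b3) is block diagonal: Var(a) from the M-equation, (b1, b3) from
    the Y-equation (indices 2 and 4 of its coefficient vector).
    """
    var_a = cov_m[1, 1]
    cov_b = cov_y[np.ix_([2, 4], [2, 4])]  # (b1, b3)
    out = {"b3": float(np.sqrt(cov_y[4, 4]))}
    # index = a*b3
    g = np.array([b3, 0.0, a])  # d/d(a, b1, b3)
    V = np.zeros((3, 3))
    V[0, 0] = var_a
    V[1:, 1:] = cov_b
    out["index"] = float(np.sqrt(g @ V @ g))
    for key, zval in (("-1sd", -sd_z), ("0", 0.0), ("+1sd", sd_z)):
        g = np.array([b1 + b3 * zval, a, a * zval])
        out[key] = float(np.sqrt(g @ V @ g))
    return out
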