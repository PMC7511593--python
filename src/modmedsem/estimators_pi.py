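"""Product-indicator SEM estimators (CPI and UPI).

The latent interaction M*Z is measured by products of indicators of M and Z.
Indicators are paired by descending factor loading ("matching"): with the
population loadings this pairs (m1,z1), (m2,z2), (m4,z3) and leaves m3
unproducted.  The constrained approach (CPI) ties every product-indicator
parameter to the base parameters:

    lambda_mz  = lambda_m * lambda_z
    Var(d_mz)  = lambda_m^2 Var(M) Var(d_z) + lambda_z^2 Var(Z) Var(d_m)
                 + Var(d_m) Var(d_z)
    Var(MZ)    = Var(M) Var(Z) + Cov(M,Z)^2,   Cov(M,Z) = a Cov(X,Z)
    E(MZ)      = a Cov(X,Z)

while the unconstrained approach (UPI) keeps only the latent-mean constraint
E(MZ) = a Cov(X,Z) and frees the rest (one product loading fixed for scale).
Both are fitted with the generic ML engine in :mod:`.sem_core`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen import BLOCKS, COLUMNS, IndicatorDataset
from .sem_core import (
    DerivedEffects,
    FitResult,
    ModelMatrices,
    SemModel,
    ml_fit,
)

__all__ = [
    "ProductPairing",
    "match_indicators",
    "build_product_indicators",
    "cpi_constraint_fn",
    "build_sem_model",
    "fit_cpi",
    "fit_upi",
]

PRODUCT_COLUMNS = ("mz1", "mz2", "mz3")


@dataclass
class ProductPairing:
    """Ordered (m-indicator, z-indicator) pairs plus any unmatched indicators."""

    pairs: list[tuple[str, str]]
    unmatched: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m, z in self.pairs:
            if m in seen or z in seen:
                raise ValueError("an indicator appears in more than one pair")
            seen.update((m, z))


def match_indicators(
    loadings_M, loadings_Z,
    m_names=BLOCKS["M"], z_names=BLOCKS["Z"],
) -> ProductPairing:
    """Pair indicators of M and Z rank-by-rank on descending loadings.

    Ties are broken by original indicator order; leftover indicators of the
    longer block stay unmatched (they still load on their own factor).
    """
    lm = np.asarray(loadings_M, dtype=float)
    lz = np.asarray(loadings_Z, dtype=float)
    if len(lm) < 1 or len(lz) < 1:
        raise ValueError("each factor needs at least one indicator")
    # stable sort on negated loadings keeps original order among ties
    m_order = np.argsort(-lm, kind="stable")
    z_order = np.argsort(-lz, kind="stable")
    k = min(len(lm), len(lz))
    pairs = [(m_names[m_order[i]], z_names[z_order[i]]) for i in range(k)]
    matched = {name for pair in pairs for name in pair}
    unmatched = [n for n in (*m_names, *z_names) if n not in matched]
    return ProductPairing(pairs=pairs, unmatched=unmatched)


def build_product_indicators(
    data: IndicatorDataset, pairing: ProductPairing, centering: bool = True
) -> pd.DataFrame:
    """Append product columns mz1..mzK to the indicator data.

    With ``centering`` (default) the paired columns are mean-centered before
    multiplying, which puts the latent-mean constraint E(MZ) = a Cov(X,Z) on
    the centered metric with product intercepts of zero.
    """
    frame = data.values.copy()
    for k, (m, z) in enumerate(pairing.pairs, start=1):
        if m not in frame.columns or z not in frame.columns:
            raise ValueError(f"pairing refers to unknown columns ({m}, {z})")
        mcol = frame[m] - frame[m].mean() if centering else frame[m]
        zcol = frame[z] - frame[z].mean() if centering else frame[z]
        frame[f"mz{k}"] = mcol * zcol
    return frame


def cpi_constraint_fn(base: dict, pairs: list[tuple[str, str]]) -> dict:
    """Product-indicator parameters implied by the base free parameters.

    ``base`` maps base parameter names (loadings ``lam_m1``.., error
    variances ``th_m1``.., and a, var_x, var_z, cov_xz, resid_m) to values.
    Returns lam_mz / th_mz per pair plus var_mz and mean_mz.
    """
    var_m = base["a"] ** 2 * base["var_x"] + base["resid_m"]
    var_z = base["var_z"]
    if var_m < 0 or var_z < 0:
        raise ValueError("negative implied latent variance")
    out = {"var_mz": var_m * var_z + (base["a"] * base["cov_xz"]) ** 2,
           "mean_mz": base["a"] * base["cov_xz"]}
    for k, (m, z) in enumerate(pairs, start=1):
        lam_m = base[f"lam_{m}"]
        lam_z = base[f"lam_{z}"]
        th_m = base[f"th_{m}"]
        th_z = base[f"th_{z}"]
        if th_m < 0 or th_z < 0:
            raise ValueError("negative error variance input")
        out[f"lam_mz{k}"] = lam_m * lam_z
        out[f"th_mz{k}"] = lam_m**2 * var_m * th_z + lam_z**2 * var_z * th_m + th_m * th_z
    return out


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

_BLOCK_LATENT = {"X": 0, "M": 1, "Z": 2, "Y": 4}  # latent order X, M, Z, MZ, Y


def _base_param_names(interaction: bool) -> list[str]:
    names = []
    for label, cols in BLOCKS.items():
        names += [f"lam_{c}" for c in cols[1:]]  # first loading fixed at 1
    names += [f"tau_{c}" for c in COLUMNS]
    names += [f"th_{c}" for c in COLUMNS]
    names += ["a", "b1", "b2", "c"] + (["b3"] if interaction else [])
    names += ["var_x", "var_z", "cov_xz", "resid_m", "resid_y"]
    return names


def build_sem_model(
    pairing: ProductPairing | None = None,
    constrained: bool = True,
    interaction: bool = True,
    start: np.ndarray | None = None,
) -> SemModel:
    """Assemble the moderated-mediation SemModel.

    ``interaction=False`` gives the linear latent mediation model (no MZ
    factor, no products) used as the null model in likelihood-ratio
    comparisons and as an oracle against the closed-form population moments.
    """
    if interaction and pairing is None:
        raise ValueError("an interaction model needs a product pairing")
    param_names = _base_param_names(interaction)
    if interaction and not constrained:
        n_prod = len(pairing.pairs)
        param_names += [f"lam_mz{k}" for k in range(2, n_prod + 1)]
        param_names += [f"th_mz{k}" for k in range(1, n_prod + 1)]
        param_names += ["var_mz", "cov_x_mz", "cov_z_mz"]

    observed = list(COLUMNS)
    if interaction:
        observed += [f"mz{k}" for k in range(1, len(pairing.pairs) + 1)]
    latent = ["X", "M", "Z", "MZ", "Y"] if interaction else ["X", "M", "Z", "Y"]
    n_lat = len(latent)
    y_idx = n_lat - 1
    mz_idx = 3 if interaction else None
    p = len(observed)
    idx = {name: i for i, name in enumerate(param_names)}
    pairs = pairing.pairs if interaction else []

    def constraint(theta: np.ndarray) -> ModelMatrices:
        g = lambda name: theta[idx[name]]
        lam = np.zeros((p, n_lat))
        tau = np.zeros(p)
        th = np.zeros(p)
        col = 0
        for label, cols in BLOCKS.items():
            lat = _BLOCK_LATENT[label] if interaction else min(_BLOCK_LATENT[label], 3)
            for j, cname in enumerate(cols):
                lam[col, lat] = 1.0 if j == 0 else g(f"lam_{cname}")
                tau[col] = g(f"tau_{cname}")
                th[col] = g(f"th_{cname}")
                col += 1
        a, b1, b2, c = g("a"), g("b1"), g("b2"), g("c")
        b3 = g("b3") if interaction else 0.0
        var_x, var_z = g("var_x"), g("var_z")
        cov_xz = g("cov_xz")
        resid_m, resid_y = g("resid_m"), g("resid_y")
        var_m = a**2 * var_x + resid_m
        cov_mz_lat = a * cov_xz  # Cov(M, Z)

        if interaction:
            base = {name: theta[idx[name]] for name in param_names}
            if constrained:
                derived = cpi_constraint_fn(
                    {**base, "lam_m1": 1.0, "lam_z1": 1.0,
                     **{f"lam_{c2[0]}": 1.0 for c2 in BLOCKS.values()}},
                    pairs,
                )
                var_mz = derived["var_mz"]
                mean_mz = derived["mean_mz"]
                cov_x_mz = cov_z_mz = 0.0
                lam_mz = [derived[f"lam_mz{k}"] for k in range(1, len(pairs) + 1)]
                th_mz = [derived[f"th_mz{k}"] for k in range(1, len(pairs) + 1)]
            else:
                var_mz = g("var_mz")
                mean_mz = a * cov_xz  # Eq-10-type constraint kept under UPI
                cov_x_mz, cov_z_mz = g("cov_x_mz"), g("cov_z_mz")
                lam_mz = [1.0] + [g(f"lam_mz{k}") for k in range(2, len(pairs) + 1)]
                th_mz = [g(f"th_mz{k}") for k in range(1, len(pairs) + 1)]
            for k in range(len(pairs)):
                lam[col, mz_idx] = lam_mz[k]
                tau[col] = 0.0  # centered metric
                th[col] = th_mz[k]
                col += 1

        # latent covariance: exogenous-ish block then the Y equation
        psi = np.zeros((n_lat, n_lat))
        psi[0, 0] = var_x
        psi[0, 1] = psi[1, 0] = a * var_x
        psi[1, 1] = var_m
        psi[0, 2] = psi[2, 0] = cov_xz
        psi[1, 2] = psi[2, 1] = cov_mz_lat
        psi[2, 2] = var_z
        alpha = np.zeros(n_lat)
        if interaction:
            psi[3, 3] = var_mz
            psi[0, 3] = psi[3, 0] = cov_x_mz
            psi[2, 3] = psi[3, 2] = cov_z_mz
            cov_m_mz = a * cov_x_mz  # M = aX + d_M, d_M independent of MZ
            psi[1, 3] = psi[3, 1] = cov_m_mz
            w = np.array([c, b1, b2, b3])
            alpha[3] = mean_mz
            alpha[y_idx] = b3 * mean_mz
        else:
            w = np.array([c, b1, b2])
        cov_y = psi[:y_idx, :y_idx] @ w
        psi[:y_idx, y_idx] = cov_y
        psi[y_idx, :y_idx] = cov_y
        psi[y_idx, y_idx] = w @ cov_y + resid_y
        return ModelMatrices(tau=tau, lam=lam, theta=th, alpha=alpha, psi=psi)

    variance_params = [n for n in param_names if n.startswith(("th_", "var_", "resid_"))]
    if start is None:
        start = default_start(param_names)
    return SemModel(
        observed=observed,
        latent=latent,
        param_names=param_names,
        start=start,
        constraint_fn=constraint,
        variance_params=variance_params,
    )


def default_start(param_names, frame: pd.DataFrame | None = None) -> np.ndarray:
    """Start heuristics: loadings 1, variances from the sample (or 0.5), paths 0."""
    start = np.empty(len(param_names))
    for i, name in enumerate(param_names):
        if name.startswith("lam_"):
            start[i] = 1.0
        elif name.startswith("tau_"):
            col = name[4:]
            start[i] = frame[col].mean() if frame is not None and col in frame else 0.0
        elif name.startswith("th_"):
            col = name[3:]
            start[i] = (
                0.5 * frame[col].var() if frame is not None and col in frame else 0.5
            )
        elif name.startswith("var_") or name.startswith("resid_"):
            start[i] = 0.5
        else:  # structural paths and cov terms
            start[i] = 0.0
    return start


def estimate_block_loadings(data: IndicatorDataset, block: str) -> np.ndarray:
    """Quick moment estimates of a block's loadings (first fixed at 1).

    lambda_j = Cov(v_j, r_j) / Cov(v_1, r_j), with r_j the mean of the
    remaining indicators excluding v_1 and v_j: both covariances isolate
    lambda * Var(latent) terms, so measurement error cancels in the ratio.
    """
    cols = list(BLOCKS[block])
    mat = data.values.loc[:, cols].to_numpy()
    k = mat.shape[1]
    lam = np.ones(k)
    cov = np.cov(mat, rowvar=False)
    for j in range(1, k):
        rest = [i for i in range(k) if i not in (0, j)]
        num = cov[j, rest].mean()
        den = cov[0, rest].mean()
        lam[j] = num / den if den != 0 else 1.0
    return lam


def _fit_pi(
    data: IndicatorDataset,
    constrained: bool,
    centering: bool = True,
    pairing: ProductPairing | None = None,
    compute_se: bool = False,
) -> tuple[FitResult, DerivedEffects]:
    if pairing is None:
        pairing = match_indicators(
            estimate_block_loadings(data, "M"), estimate_block_loadings(data, "Z")
        )
    frame = build_product_indicators(data, pairing, centering=centering)
    model = build_sem_model(pairing, constrained=constrained, interaction=True)
    model.start = default_start(model.param_names, frame)
    label = "cpi" if constrained else "upi"
    fit = ml_fit(model, frame, compute_se=compute_se, method_label=label)
    effects = derived_effects_from_fit(fit)
    return fit, effects


def fit_cpi(data: IndicatorDataset, **kw) -> tuple[FitResult, DerivedEffects]:
    """Constrained product-indicator fit (all four constraint sets active)."""
    return _fit_pi(data, constrained=True, **kw)


def fit_upi(data: IndicatorDataset, **kw) -> tuple[FitResult, DerivedEffects]:
    """Unconstrained product-indicator fit (latent-mean constraint only)."""
    return _fit_pi(data, constrained=False, **kw)


def derived_effects_from_fit(fit: FitResult) -> DerivedEffects:
    """Moderated-mediation effects (and delta-method SEs when a parameter
    covariance is available) from a latent-model fit with parameters
    a, b1, b3, var_z.

    The moderator SD is the model-estimated sqrt(Var(Z)) -- the latent
    metric, which is all a latent-variable estimator can see.
    """
    est = fit.estimates
    a, b1 = est.get("a", np.nan), est.get("b1", np.nan)
    b3 = est.get("b3", 0.0)
    var_z = est.get("var_z", np.nan)
    sd_z = float(np.sqrt(var_z)) if var_z > 0 else np.nan
    eff = DerivedEffects.from_paths(a, b1, b3, sd_z)
    if fit.cov is not None and fit.param_names is not None:
        names = ["a", "b1", "b3"]
        try:
            sel = [fit.param_names.index(n) for n in names]
        except ValueError:
            return eff
        V = fit.cov[np.ix_(sel, sel)]
        se = {"b3": float(np.sqrt(max(V[2, 2], 0.0)))}
        grads = {
            "index": np.array([b3, 0.0, a]),
            "-1sd": np.array([b1 - b3 * sd_z, a, -a * sd_z]),
            "0": np.array([b1, a, 0.0]),
            "+1sd": np.array([b1 + b3 * sd_z, a, a * sd_z]),
        }
        for key, grad in grads.items():
            se[key] = float(np.sqrt(max(grad @ V @ grad, 0.0)))
        eff.se = se
        from scipy import stats

        vals = {"b3": b3, "index": a * b3, **eff.ind}
        eff.p = {
            k: float(2 * stats.norm.sf(abs(vals[k]) / se[k])) if se[k] > 0 else np.nan
            for k in se
        }
    return eff
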