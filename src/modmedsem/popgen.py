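"""Population model and data generation for the second-stage moderated mediation design.

The structural model is

    M = a*X + delta_M
    Y = c*X + b1*M + b2*Z + b3*M*Z + delta_Y

with jointly Gaussian exogenous latents (X, Z) and congeneric measurement models
per block: three indicators each for X and Z, four each for M and Y, every
indicator ``tau + lambda * latent + error``.  The module provides

* the canonical population parameterization used throughout the simulation
  studies (:func:`make_population_spec`),
* a dataset generator (:func:`generate_dataset`) supporting five measurement
  error distributions (normal, uniform, two symmetric heavy-tailed types, and
  a skewed chi-square type),
* exact implied first/second moments for the normal-error case
  (:func:`population_moments`), usable as an oracle for both the generator and
  any covariance-structure estimator, and
* Cronbach's alpha per indicator block (:func:`cronbach_alpha`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BLOCKS",
    "COLUMNS",
    "MeasurementSpec",
    "StructuralSpec",
    "PopulationSpec",
    "IndicatorDataset",
    "DesignCell",
    "make_population_spec",
    "sample_error",
    "generate_dataset",
    "population_moments",
    "cronbach_alpha",
    "rng_for",
]

#: Fixed block layout: block label -> indicator column names (order matters).
BLOCKS: dict[str, tuple[str, ...]] = {
    "X": ("x1", "x2", "x3"),
    "M": ("m1", "m2", "m3", "m4"),
    "Z": ("z1", "z2", "z3"),
    "Y": ("y1", "y2", "y3", "y4"),
}

#: Fixed column order of the 14-indicator vector.
COLUMNS: tuple[str, ...] = BLOCKS["X"] + BLOCKS["M"] + BLOCKS["Z"] + BLOCKS["Y"]

ERROR_DISTRIBUTIONS = (
    "normal",
    "uniform01",
    "symm_moderate_kurtosis",
    "symm_high_kurtosis",
    "skewed_chisq1",
)

#: Distribution-type codes 1..5 -> error distribution names.
DISTRIBUTION_TYPES: dict[int, str] = dict(enumerate(ERROR_DISTRIBUTIONS, start=1))


@dataclass
class MeasurementSpec:
    """Congeneric measurement model for one indicator block."""

    block: str
    loadings: np.ndarray
    intercepts: np.ndarray
    error_variances: np.ndarray
    error_distribution: str = "normal"

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.error_variances = np.asarray(self.error_variances, dtype=float)
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}; expected one of {sorted(BLOCKS)}")
        k = len(BLOCKS[self.block])
        if not (len(self.loadings) == len(self.intercepts) == len(self.error_variances) == k):
            raise ValueError(
                f"block {self.block} needs {k} loadings/intercepts/error variances"
            )
        if self.loadings[0] != 1.0:
            raise ValueError("first loading must be fixed at 1.0 (scaling indicator)")
        if np.any(self.error_variances <= 0):
            raise ValueError("error variances must be positive")
        if self.error_distribution not in ERROR_DISTRIBUTIONS:
            raise ValueError(
                f"unknown error distribution {self.error_distribution!r}; "
                f"expected one of {ERROR_DISTRIBUTIONS}"
            )

    @property
    def n_indicators(self) -> int:
        return len(self.loadings)


@dataclass
class StructuralSpec:
    """Structural coefficients and latent (co)variances of the population model."""

    a: float
    b1: float
    b2: float
    b3: float
    c: float
    var_X: float = 1.0
    var_Z: float = 1.0
    cov_XZ: float = 0.0
    resid_var_M: float = 0.36
    resid_var_Y: float = 0.36

    def __post_init__(self) -> None:
        if self.var_X <= 0 or self.var_Z <= 0:
            raise ValueError("latent variances must be positive")
        if self.var_X * self.var_Z - self.cov_XZ**2 <= 0:
            raise ValueError("(X, Z) covariance matrix is not positive definite")
        if self.resid_var_M <= 0 or self.resid_var_Y <= 0:
            raise ValueError("structural residual variances must be positive")

    @property
    def var_M(self) -> float:
        """Implied variance of the mediator, a^2 Var(X) + Var(delta_M)."""
        return self.a**2 * self.var_X + self.resid_var_M

    @property
    def var_MZ(self) -> float:
        """Implied variance of the latent product, Var(M)Var(Z) + Cov(M,Z)^2."""
        return self.var_M * self.var_Z + (self.a * self.cov_XZ) ** 2

    @property
    def mean_MZ(self) -> float:
        """Implied mean of the latent product, Cov(M, Z) = a Cov(X, Z)."""
        return self.a * self.cov_XZ


@dataclass
class PopulationSpec:
    """Full population model: four measurement blocks plus the structural part."""

    X: MeasurementSpec
    M: MeasurementSpec
    Z: MeasurementSpec
    Y: MeasurementSpec
    structural: StructuralSpec

    def block(self, label: str) -> MeasurementSpec:
        return getattr(self, label)

    def to_yaml(self, path) -> None:
        doc = {
            "blocks": {
                b: {
                    "loadings": self.block(b).loadings.tolist(),
                    "intercepts": self.block(b).intercepts.tolist(),
                    "error_variances": self.block(b).error_variances.tolist(),
                    "error_distribution": self.block(b).error_distribution,
                }
                for b in BLOCKS
            },
            "structural": asdict(self.structural),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        blocks = {
            b: MeasurementSpec(block=b, **doc["blocks"][b]) for b in BLOCKS
        }
        return cls(structural=StructuralSpec(**doc["structural"]), **blocks)


@dataclass
class IndicatorDataset:
    """Rectangular n x 14 case-by-indicator dataset with fixed column order."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if isinstance(self.values, np.ndarray):
            self.values = pd.DataFrame(self.values, columns=list(COLUMNS))
        missing = [c for c in COLUMNS if c not in self.values.columns]
        if missing:
            raise ValueError(f"dataset is missing indicator columns {missing}")
        self.values = self.values.loc[:, list(COLUMNS)].astype(float)
        if self.values.isna().any().any():
            raise ValueError("dataset contains missing values")

    @property
    def n(self) -> int:
        return len(self.values)

    def block(self, label: str) -> pd.DataFrame:
        return self.values.loc[:, list(BLOCKS[label])]

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IndicatorDataset":
        return cls(pd.read_csv(path))


@dataclass
class DesignCell:
    """One condition of the factorial simulation design.

    The class-level sets list the conditions used in the two simulation
    studies; they can be extended for custom designs.
    """

    n: int = 500
    b3: float = 0.2
    reliability: str = "high"
    distribution_type: int = 1
    cor_xz: float = 0.0

    N_LEVELS = {100, 200, 500, 1000}
    B3_LEVELS = {0.0, 0.2, 0.4}
    RELIABILITY_LEVELS = {"high", "low"}
    COR_LEVELS = {0.0, 0.3}

    def __post_init__(self) -> None:
        if self.n not in self.N_LEVELS:
            raise ValueError(f"n={self.n} not in {sorted(self.N_LEVELS)}")
        if self.b3 not in self.B3_LEVELS:
            raise ValueError(f"b3={self.b3} not in {sorted(self.B3_LEVELS)}")
        if self.reliability not in self.RELIABILITY_LEVELS:
            raise ValueError(f"reliability must be one of {sorted(self.RELIABILITY_LEVELS)}")
        if self.distribution_type not in DISTRIBUTION_TYPES:
            raise ValueError(f"distribution_type must be in {sorted(DISTRIBUTION_TYPES)}")
        if self.cor_xz not in self.COR_LEVELS:
            raise ValueError(f"cor_xz={self.cor_xz} not in {sorted(self.COR_LEVELS)}")

    def label(self) -> str:
        return (
            f"n{self.n}_b3{self.b3:g}_{self.reliability}"
            f"_type{self.distribution_type}_cor{self.cor_xz:g}"
        )


# Population factor loadings (first loading fixed at 1 for scale).
_LOADINGS = {
    "X": (1.0, 0.65, 0.72),
    "M": (1.0, 0.81, 0.53, 0.66),
    "Z": (1.0, 0.83, 0.79),
    "Y": (1.0, 0.68, 0.75, 0.83),
}
_INTERCEPT = 0.5
_ERROR_VARIANCE = {"high": 0.36, "low": 1.5}


def make_population_spec(cell: DesignCell) -> PopulationSpec:
    """Population parameterization for one design cell.

    High reliability sets every indicator error variance to 0.36
    (block reliabilities around .82-.90), low reliability to 1.5 (around
    .54-.68).  Non-normal error distributions (types 2-5) apply to the M- and
    Z-block measurement errors only; X- and Y-block errors stay normal.
    """
    theta = _ERROR_VARIANCE[cell.reliability]
    mz_dist = DISTRIBUTION_TYPES[cell.distribution_type]
    blocks = {}
    for label, lam in _LOADINGS.items():
        k = len(lam)
        blocks[label] = MeasurementSpec(
            block=label,
            loadings=np.array(lam),
            intercepts=np.full(k, _INTERCEPT),
            error_variances=np.full(k, theta),
            error_distribution=mz_dist if label in ("M", "Z") else "normal",
        )
    structural = StructuralSpec(
        a=0.75, b1=0.56, b2=0.48, b3=cell.b3, c=0.3,
        var_X=1.0, var_Z=1.0, cov_XZ=cell.cor_xz,
        resid_var_M=0.36, resid_var_Y=0.36,
    )
    return PopulationSpec(structural=structural, **blocks)


def sample_error(
    dist: str,
    variance_scale: float,
    n: int,
    rng: np.random.Generator,
    *,
    df_high_kurtosis: float = 4.5,
    rescale_natural: bool = False,
) -> np.ndarray:
    """Draw ``n`` i.i.d. measurement errors from one of the five error types.

    normal
        N(0, variance_scale).
    uniform01
        U[0, 1] centered to mean 0; natural variance 1/12 kept unless
        ``rescale_natural`` (the raw distribution is part of the design, and
        rescaling would leave skew/kurtosis but change the reliability
        manipulation it induces).
    symm_moderate_kurtosis
        z / sqrt(chi2(5)/3) with z standard normal: symmetric, unit variance,
        elevated kurtosis; rescaled to ``variance_scale``.
    symm_high_kurtosis
        Same construction with a heavier divisor chi2(df)/(df-2),
        df = ``df_high_kurtosis`` (< 5), giving higher kurtosis at unit
        variance; rescaled to ``variance_scale``.
    skewed_chisq1
        chi-square(1) centered to mean 0 (skewness sqrt(8)); natural variance
        2 kept unless ``rescale_natural``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if dist == "normal":
        return rng.normal(0.0, np.sqrt(variance_scale), size=n)
    if dist == "uniform01":
        draws = rng.uniform(0.0, 1.0, size=n) - 0.5
        if rescale_natural:
            draws *= np.sqrt(variance_scale / (1.0 / 12.0))
        return draws
    if dist == "symm_moderate_kurtosis":
        z = rng.normal(size=n)
        chi = rng.chisquare(5.0, size=n)
        return np.sqrt(variance_scale) * z / np.sqrt(chi / 3.0)
    if dist == "symm_high_kurtosis":
        df = df_high_kurtosis
        if not 2.0 < df:
            raise ValueError("df_high_kurtosis must exceed 2")
        z = rng.normal(size=n)
        chi = rng.chisquare(df, size=n)
        return np.sqrt(variance_scale) * z / np.sqrt(chi / (df - 2.0))
    if dist == "skewed_chisq1":
        draws = rng.chisquare(1.0, size=n) - 1.0
        if rescale_natural:
            draws *= np.sqrt(variance_scale / 2.0)
        return draws
    raise ValueError(f"unknown error distribution {dist!r}")


def generate_dataset(
    spec: PopulationSpec, n: int, rng: np.random.Generator
) -> IndicatorDataset:
    """Simulate an n x 14 indicator dataset from the population model.

    Latents (X, Z) are jointly Gaussian; the structural equations produce M
    and Y (including the latent M*Z product term); each indicator adds a
    block-specific measurement error draw.  Bit-identical for a given rng
    state.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = spec.structural
    cov_xz = np.array([[s.var_X, s.cov_XZ], [s.cov_XZ, s.var_Z]])
    X, Z = rng.multivariate_normal([0.0, 0.0], cov_xz, size=n, method="cholesky").T
    M = s.a * X + rng.normal(0.0, np.sqrt(s.resid_var_M), size=n)
    Y = (
        s.c * X + s.b1 * M + s.b2 * Z + s.b3 * M * Z
        + rng.normal(0.0, np.sqrt(s.resid_var_Y), size=n)
    )
    latents = {"X": X, "M": M, "Z": Z, "Y": Y}
    out = np.empty((n, len(COLUMNS)))
    col = 0
    for label in ("X", "M", "Z", "Y"):
        block = spec.block(label)
        eta = latents[label]
        for j in range(block.n_indicators):
            err = sample_error(
                block.error_distribution, block.error_variances[j], n, rng
            )
            out[:, col] = block.intercepts[j] + block.loadings[j] * eta + err
            col += 1
    return IndicatorDataset(out)


def latent_moments(s: StructuralSpec) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the latent vector (X, M, Z, MZ, Y).

    Exact under Gaussian (X, Z, delta_M): third central moments of zero-mean
    Gaussians vanish, so the product term MZ is uncorrelated with X, M, Z, and
    Var(MZ) = Var(M)Var(Z) + Cov(M,Z)^2.
    """
    var_M = s.var_M
    cov_MZ = s.a * s.cov_XZ
    var_mz = s.var_MZ
    # order: X, M, Z, MZ
    phi = np.array(
        [
            [s.var_X, s.a * s.var_X, s.cov_XZ, 0.0],
            [s.a * s.var_X, var_M, cov_MZ, 0.0],
            [s.cov_XZ, cov_MZ, s.var_Z, 0.0],
            [0.0, 0.0, 0.0, var_mz],
        ]
    )
    w = np.array([s.c, s.b1, s.b2, s.b3])
    cov_y = phi @ w
    var_y = w @ phi @ w + s.resid_var_Y
    mean = np.array([0.0, 0.0, 0.0, s.mean_MZ, s.b3 * s.mean_MZ])
    cov = np.empty((5, 5))
    cov[:4, :4] = phi
    cov[:4, 4] = cov_y
    cov[4, :4] = cov_y
    cov[4, 4] = var_y
    return mean, cov


def population_moments(spec: PopulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact implied mean vector and covariance matrix of the 14 indicators.

    Valid only when every measurement error is normal (the Gaussian moment
    identities behind the MZ terms require it); other types raise.
    """
    for label in BLOCKS:
        if spec.block(label).error_distribution != "normal":
            raise ValueError(
                "population_moments requires normal measurement errors "
                f"(block {label} has {spec.block(label).error_distribution!r})"
            )
    lat_mean, lat_cov = latent_moments(spec.structural)
    # loading matrix onto (X, M, Z, Y) = latent indices (0, 1, 2, 4)
    p = len(COLUMNS)
    lam = np.zeros((p, 5))
    tau = np.empty(p)
    theta = np.empty(p)
    col = 0
    for label, lat_idx in (("X", 0), ("M", 1), ("Z", 2), ("Y", 4)):
        block = spec.block(label)
        k = block.n_indicators
        lam[col : col + k, lat_idx] = block.loadings
        tau[col : col + k] = block.intercepts
        theta[col : col + k] = block.error_variances
        col += k
    mean = tau + lam @ lat_mean
    cov = lam @ lat_cov @ lam.T + np.diag(theta)
    return mean, cov


def cronbach_alpha(dataset: IndicatorDataset, block: str) -> float:
    """Cronbach's alpha of one indicator block: (k/(k-1)) (1 - sum item var / var of sum)."""
    if block not in BLOCKS:
        raise ValueError(f"unknown block {block!r}")
    items = dataset.block(block).to_numpy()
    k = items.shape[1]
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    item_vars = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return 1.0
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def population_alpha(spec: PopulationSpec, block: str) -> float:
    """Closed-form population Cronbach's alpha of a block (normal-error oracle)."""
    _, cov = population_moments(spec)
    idx = [COLUMNS.index(c) for c in BLOCKS[block]]
    sub = cov[np.ix_(idx, idx)]
    k = len(idx)
    return k / (k - 1) * (1.0 - np.trace(sub) / sub.sum())


def rng_for(master_seed: int, *stream: int) -> np.random.Generator:
    """Deterministic substream generator (e.g. per cell index, replication index)."""
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF, *map(int, stream)])
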