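"""Case-resampling bootstrap and Wald tests.

The bootstrap resamples cases with replacement, re-runs an arbitrary
estimator function, and summarizes the draws by their standard deviation
(bootstrap SE) and empirical 2.5/97.5 percentiles (percentile CI).  Draws on
which the estimator fails to deliver a proper solution are counted and
excluded rather than re-drawn, so the nominal number of draws B stays
interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BootstrapResult", "bootstrap", "wald_test"]


@dataclass
class BootstrapResult:
    B: int
    draws: pd.DataFrame          # usable draws only, one column per statistic
    se: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    n_failed: int

    @property
    def usable(self) -> bool:
        return len(self.draws) >= 2


def bootstrap(
    estimator_fn: Callable[[pd.DataFrame], Mapping[str, float] | None],
    data,
    B: int = 100,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Nonparametric case bootstrap of an estimator.

    ``estimator_fn`` receives a resampled DataFrame and returns a mapping of
    statistic name -> value, or ``None`` to signal a failed (improper /
    non-converged) draw.  With a fixed rng state the result is bit-for-bit
    reproducible.
    """
    if B < 2:
        raise ValueError("need at least B=2 bootstrap draws")
    rng = np.random.default_rng() if rng is None else rng
    frame = data.values if hasattr(data, "values") and not isinstance(data, pd.DataFrame) else pd.DataFrame(data)
    n = len(frame)
    rows = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sample = frame.iloc[idx].reset_index(drop=True)
        try:
            est = estimator_fn(sample)
        except Exception:
            est = None
        if est is None or any(not np.isfinite(v) for v in est.values()):
            n_failed += 1
            continue
        rows.append(dict(est))
    draws = pd.DataFrame(rows)
    if len(draws) < 2:
        return BootstrapResult(B=B, draws=draws, se={}, ci_lower={}, ci_upper={}, n_failed=n_failed)
    se = {c: float(draws[c].std(ddof=1)) for c in draws.columns}
    # outward-rounded order statistics keep endpoints members of the draw set
    lo = {c: float(np.percentile(draws[c], 2.5, method="lower")) for c in draws.columns}
    hi = {c: float(np.percentile(draws[c], 97.5, method="higher")) for c in draws.columns}
    return BootstrapResult(B=B, draws=draws, se=se, ci_lower=lo, ci_upper=hi, n_failed=n_failed)


def wald_test(estimate: float, se: float, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Two-sided normal-theory test of H0: parameter = 0.

    Returns (z, p, reject at alpha).
    """
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = estimate / se
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p, bool(p < alpha)
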