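"""Monte-Carlo orchestration and evaluation metrics.

Runs the factorial simulation designs (study 1: sample size x interaction
effect x reliability; study 2: error distribution x exogenous correlation x
interaction effect at N = 200) over any subset of the four estimators, and
summarizes per-cell performance with the standard Monte-Carlo criteria:

* relative bias (estimate - truth)/truth, acceptability |RB| <= 0.10;
* SE ratio mean(SE)/SD(estimates), acceptability [0.9, 1.1];
* coverage of the 95% interval, acceptability > 0.90;
* rejection rate of the Wald test (power for non-zero truth, type-I error
  for zero truth, binomial window [0.0365, 0.0635] at 1,000 replications);
* completion rate (proportion of proper solutions).

Metrics are computed over proper-solution replications only; completion is
reported separately.  Replications use deterministic substreams derived from
(master seed, cell index, replication index), so any cell can be reproduced
in isolation and results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .popgen import DesignCell, generate_dataset, make_population_spec, rng_for
from .estimators_pa import fit_pa
from .estimators_pi import fit_cpi, fit_upi
from .estimators_lms import fit_lms

__all__ = [
    "relative_bias",
    "se_ratio",
    "coverage",
    "rejection_rate",
    "run_cell",
    "summarize",
    "write_report",
    "cell_truths",
    "study1_cells",
    "study2_cells",
]

PARAMS = ("b3", "index", "ind_-1sd", "ind_0", "ind_+1sd")
RB_THRESHOLD = 0.10
SE_RATIO_WINDOW = (0.9, 1.1)
TYPE1_WINDOW = (0.0365, 0.0635)


def relative_bias(estimates, truth: float) -> float:
    """(mean(estimates) - truth) / truth; undefined (raises) at truth = 0."""
    if truth == 0:
        raise ValueError(
            "relative bias is undefined for zero truth; report raw bias instead"
        )
    estimates = np.asarray(estimates, dtype=float)
    return float((estimates.mean() - truth) / truth)


def se_ratio(se_values, estimates) -> float:
    """mean(estimated SEs) / SD(estimates across replications), SD with n-1."""
    estimates = np.asarray(estimates, dtype=float)
    se_values = np.asarray(se_values, dtype=float)
    if len(estimates) < 2:
        raise ValueError("need at least 2 estimates")
    sd = estimates.std(ddof=1)
    if sd == 0:
        raise ValueError("zero empirical SD")
    return float(se_values.mean() / sd)


def coverage(ci_lowers, ci_uppers, truth: float) -> float:
    """Fraction of closed intervals [lo, hi] containing the truth."""
    lo = np.asarray(ci_lowers, dtype=float)
    hi = np.asarray(ci_uppers, dtype=float)
    if lo.shape != hi.shape:
        raise ValueError("interval bound vectors differ in length")
    return float(np.mean((lo <= truth) & (truth <= hi)))


def rejection_rate(p_values, alpha: float = 0.05) -> float:
    """Fraction of replications with p < alpha (power or type-I error)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return np.nan
    return float(np.mean(p < alpha))


def cell_truths(cell: DesignCell) -> dict[str, float]:
    """Population values of the reported quantities (moderator SD = sqrt(Var Z) = 1)."""
    s = make_population_spec(cell).structural
    sd_z = np.sqrt(s.var_Z)
    return {
        "b3": s.b3,
        "index": s.a * s.b3,
        "ind_-1sd": s.a * (s.b1 - s.b3 * sd_z),
        "ind_0": s.a * s.b1,
        "ind_+1sd": s.a * (s.b1 + s.b3 * sd_z),
    }


def study1_cells() -> list[DesignCell]:
    """The 4 x 3 x 2 design: N x b3 x reliability, normal errors, cor(X,Z)=0."""
    return [
        DesignCell(n=n, b3=b3, reliability=rel)
        for b3 in (0.0, 0.2, 0.4)
        for rel in ("high", "low")
        for n in (100, 200, 500, 1000)
    ]


def study2_cells() -> list[DesignCell]:
    """Non-normality design at N=200, high reliability: 5 types x 2 cors x 2 b3."""
    return [
        DesignCell(n=200, b3=b3, reliability="high", distribution_type=t, cor_xz=cor)
        for b3 in (0.0, 0.2)
        for cor in (0.0, 0.3)
        for t in (1, 2, 3, 4, 5)
    ]


def _record_from(fit, effects, estimator: str, rep: int) -> dict:
    rec = {
        "estimator": estimator,
        "rep": rep,
        "converged": bool(fit.converged),
        "proper": bool(fit.proper_solution),
    }
    vals = {
        "b3": effects.b3,
        "index": effects.index,
        "ind_-1sd": effects.ind["-1sd"],
        "ind_0": effects.ind["0"],
        "ind_+1sd": effects.ind["+1sd"],
    }
    se_map = effects.se or {}
    rename = {"ind_-1sd": "-1sd", "ind_0": "0", "ind_+1sd": "+1sd"}
    z95 = 1.959963984540054
    from scipy import stats

    for key, val in vals.items():
        se = se_map.get(rename.get(key, key), np.nan)
        rec[f"{key}_est"] = val
        rec[f"{key}_se"] = se
        if np.isfinite(se) and se > 0 and np.isfinite(val):
            rec[f"{key}_p"] = float(2 * stats.norm.sf(abs(val) / se))
            rec[f"{key}_lo"] = val - z95 * se
            rec[f"{key}_hi"] = val + z95 * se
        else:
            rec[f"{key}_p"] = np.nan
            rec[f"{key}_lo"] = np.nan
            rec[f"{key}_hi"] = np.nan
    return rec


def run_cell(
    cell: DesignCell,
    estimators=("pa", "cpi", "upi", "lms"),
    reps: int = 200,
    master_seed: int = 0,
    *,
    cell_index: int = 0,
    lms_K: int = 16,
    lms_se: str = "robust",
) -> list[dict]:
    """Run one design cell: generate data and apply each estimator per replication.

    Estimator exceptions are caught and logged as non-complete replications;
    the cell never aborts.  Identical (master_seed, cell_index, rep) always
    yields identical records.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    unknown = set(estimators) - {"pa", "cpi", "upi", "lms"}
    if unknown:
        raise ValueError(f"unknown estimators: {sorted(unknown)}")
    spec = make_population_spec(cell)
    records: list[dict] = []
    for rep in range(reps):
        rng = rng_for(master_seed, cell_index, rep)
        dataset = generate_dataset(spec, cell.n, rng)
        for name in estimators:
            try:
                if name == "pa":
                    fit, eff = fit_pa(dataset)
                elif name == "cpi":
                    fit, eff = fit_cpi(dataset, compute_se=True)
                elif name == "upi":
                    fit, eff = fit_upi(dataset, compute_se=True)
                else:
                    fit, eff = fit_lms(dataset, K=lms_K, se=lms_se)
                rec = _record_from(fit, eff, name, rep)
            except Exception:
                rec = {
                    "estimator": name,
                    "rep": rep,
                    "converged": False,
                    "proper": False,
                }
                for key in PARAMS:
                    for suffix in ("est", "se", "p", "lo", "hi"):
                        rec[f"{key}_{suffix}"] = np.nan
            for field, value in asdict(cell).items():
                rec[field] = value
            records.append(rec)
    return records


def summarize(records: list[dict]) -> pd.DataFrame:
    """One metrics row per (estimator x parameter), plus an averaged "ind" block.

    Bias is relative (RB) for non-zero truths and raw mean bias (flagged by
    ``bias_type``) where the truth is zero.  All accuracy metrics use
    proper-solution replications only.
    """
    if not records:
        raise ValueError("no records to summarize")
    frame = pd.DataFrame(records)
    rows = []
    cell_fields = ["n", "b3", "reliability", "distribution_type", "cor_xz"]
    for (estimator, *cell_vals), grp in frame.groupby(
        ["estimator"] + cell_fields, sort=False
    ):
        cell = DesignCell(**dict(zip(cell_fields, cell_vals)))
        truths = cell_truths(cell)
        total = len(grp)
        ok = grp[grp["proper"]]
        completion = len(ok) / total
        param_rows = {}
        for param in PARAMS:
            truth = truths[param]
            est = ok[f"{param}_est"].dropna()
            row = {
                **{f: v for f, v in zip(cell_fields, cell_vals)},
                "estimator": estimator,
                "parameter": param,
                "truth": truth,
                "n_reps_used": len(est),
                "completion_rate": completion,
            }
            if len(est) >= 2:
                if truth != 0:
                    row["bias"] = relative_bias(est, truth)
                    row["bias_type"] = "relative"
                else:
                    row["bias"] = float(est.mean())
                    row["bias_type"] = "raw"
                ses = ok.loc[est.index, f"{param}_se"].dropna()
                try:
                    row["se_ratio"] = (
                        se_ratio(ses, est[ses.index]) if len(ses) >= 2 else np.nan
                    )
                except ValueError:
                    row["se_ratio"] = np.nan
                lo = ok.loc[est.index, f"{param}_lo"].dropna()
                hi = ok.loc[est.index, f"{param}_hi"].dropna()
                row["coverage"] = coverage(lo, hi.loc[lo.index], truth) if len(lo) else np.nan
                pvals = ok.loc[est.index, f"{param}_p"].dropna()
                row["power_or_type1"] = rejection_rate(pvals) if len(pvals) else np.nan
                row["rate_type"] = "type1" if truth == 0 else "power"
            else:
                for k in ("bias", "se_ratio", "coverage", "power_or_type1"):
                    row[k] = np.nan
                row["bias_type"] = row["rate_type"] = "na"
            rows.append(row)
            param_rows[param] = row
        # averaged indirect-effect block across the three moderator values
        ind_keys = ["ind_-1sd", "ind_0", "ind_+1sd"]
        avg = {
            **{f: v for f, v in zip(cell_fields, cell_vals)},
            "estimator": estimator,
            "parameter": "ind",
            "truth": np.mean([truths[k] for k in ind_keys]),
            "n_reps_used": param_rows["ind_0"]["n_reps_used"],
            "completion_rate": completion,
            "bias_type": "averaged",
            "rate_type": param_rows["ind_0"].get("rate_type", "na"),
        }
        for metric in ("bias", "se_ratio", "coverage", "power_or_type1"):
            vals = [param_rows[k].get(metric, np.nan) for k in ind_keys]
            avg[metric] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else np.nan
        rows.append(avg)
    return pd.DataFrame(rows)


def write_report(table: pd.DataFrame, path) -> None:
    """CSV metrics table plus a formatted text companion (RB / SE ratio /
    coverage / rejection blocks, estimators as rows)."""
    table.to_csv(path, index=False)
    txt_path = str(path)
    txt_path = txt_path[: txt_path.rfind(".")] + ".txt" if "." in txt_path else txt_path + ".txt"
    blocks = []
    for metric, label in (
        ("bias", "Bias (relative unless flagged raw)"),
        ("se_ratio", "SE ratio"),
        ("coverage", "Coverage"),
        ("power_or_type1", "Power / Type I"),
        ("completion_rate", "Completion rate"),
    ):
        pivot = table.pivot_table(
            index=["estimator", "parameter"],
            columns=[c for c in ("n", "b3", "reliability", "distribution_type", "cor_xz")
                     if table[c].nunique() > 1] or ["n"],
            values=metric,
            aggfunc="first",
        )
        blocks.append(f"== {label} ==\n{pivot.round(3).to_string()}\n")
    with open(txt_path, "w") as fh:
        fh.write("\n".join(blocks))
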