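"""Group-comparison machinery: contingency and rank tests, robust z-score
models, log-LV comparison with delta-method back-transform, quasi-binomial
disconnection models, and Benjamini-Hochberg FDR.

Robust linear fits use M-estimation with the Huber psi (tuning 1.345) and
MAD scale. Chi-square tests are Pearson without continuity correction;
Fisher's exact test uses the minimum-likelihood two-sided rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

HUBER_T = 1.345


@dataclass
class ComparisonResult:
    """One tested contrast: estimate, SE, raw p and (if adjusted) FDR q."""

    estimate: float
    se: float
    p: float
    q: float | None = None
    family: str = ""


def contingency_test(table, method: str = "chisq") -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) or Fisher's exact test.

    Returns (statistic, two-sided p). Fisher's statistic is the odds ratio;
    its two-sided p sums hypergeometric probabilities of all tables at most
    as likely as the observed one.
    """
    t = np.asarray(table)
    if t.ndim != 2 or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise DataError("contingency table must be a 2-D array of nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DataError("contingency table has a zero margin")
    if method == "chisq":
        stat, p, _, _ = stats.chi2_contingency(t, correction=False)
        return float(stat), float(p)
    if method == "fisher":
        if t.shape != (2, 2):
            raise DataError("Fisher's exact test requires a 2x2 table")
        stat, p = stats.fisher_exact(t, alternative="two-sided")
        return float(stat), float(p)
    raise DataError(f"unknown method {method!r}")


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p (exact for small tie-free samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def _robust_fit(y: np.ndarray, x: np.ndarray):
    model = sm.RLM(y, x, M=sm.robust.norms.HuberT(t=HUBER_T))
    return model.fit(scale_est="mad")


def _wald_p(est: float, se: float) -> float:
    if se == 0 or not np.isfinite(se):
        return 1.0 if est == 0 else 0.0
    return float(2 * stats.norm.sf(abs(est) / se))


def robust_z_comparison(z_values, group_labels) -> dict:
    """Robust per-group mean z (tested against 0) and between-group test.

    Fits a cell-means robust regression of z on the two group indicators for
    the per-group means, and an intercept+indicator parameterization for the
    group difference.
    """
    z = np.asarray(z_values, dtype=float)
    groups = np.asarray(group_labels)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise DataError("exactly two patient groups required")
    for g in levels:
        if (groups == g).sum() < 3:
            raise DataError(f"group {g!r} has fewer than 3 subjects")

    d = np.column_stack([(groups == g).astype(float) for g in levels])
    if np.allclose(z - d @ np.linalg.lstsq(d, z, rcond=None)[0], 0):
        # degenerate exact fit (e.g. all-zero z): MAD scale collapses
        means = {g: float(z[groups == g].mean()) for g in levels}
        out = {
            g: ComparisonResult(means[g], 0.0, _wald_p(means[g], 0.0)) for g in levels
        }
        diff = means[levels[1]] - means[levels[0]]
        out["between"] = ComparisonResult(diff, 0.0, _wald_p(diff, 0.0))
        return out

    cell = _robust_fit(z, d)
    out = {
        g: ComparisonResult(
            float(cell.params[i]), float(cell.bse[i]),
            _wald_p(float(cell.params[i]), float(cell.bse[i])),
        )
        for i, g in enumerate(levels)
    }
    contrast = _robust_fit(z, np.column_stack([np.ones_like(z), d[:, 1]]))
    out["between"] = ComparisonResult(
        float(contrast.params[1]), float(contrast.bse[1]), float(contrast.pvalues[1])
    )
    return out


def _marginal_mean(x_all: np.ndarray, group_cols: dict, g: str) -> np.ndarray:
    """Average design row with the group indicator forced to g (G-computation)."""
    x = x_all.copy()
    for name, col in group_cols.items():
        x[:, col] = 1.0 if name == g else 0.0
    return x.mean(axis=0)


def _dummies(values: np.ndarray, prefix: str) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(values))[1:]  # drop first level
    cols = [(values == lv).astype(float) for lv in levels]
    names = [f"{prefix}[{lv}]" for lv in levels]
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(values), 0)), names


def compare_lesion_volume(lv_ml, group, sex, center, zero_offset: float | None = None) -> dict:
    """Sex- and center-adjusted robust comparison of log lesion volume.

    Group means are estimated marginally over the observed sex/center
    distribution and back-transformed to the original scale by the delta
    method: mean = exp(mu), SE = exp(mu) * SE(mu). Zeros are offset by half
    the smallest positive LV (configurable).
    """
    lv = np.asarray(lv_ml, dtype=float)
    groups = np.asarray(group)
    if np.all(lv == 0):
        raise DataError("all lesion volumes are zero")
    if np.any(lv < 0):
        raise DataError("lesion volumes must be >= 0")
    if np.any(lv == 0):
        offset = zero_offset if zero_offset is not None else lv[lv > 0].min() / 2.0
        lv = lv + offset
    y = np.log(lv)

    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise DataError("exactly two groups required")
    g1 = (groups == levels[1]).astype(float)
    male = (np.asarray(sex) == "M").astype(float)
    cdum, cnames = _dummies(np.asarray(center), "center")
    x = np.column_stack([np.ones_like(y), g1, male, cdum])
    fit = _robust_fit(y, x)
    cov = fit.cov_params()

    group_cols = {levels[1]: 1}
    out = {}
    for g in levels:
        c = _marginal_mean(x, group_cols, g)
        mu = float(c @ fit.params)
        se_mu = float(np.sqrt(c @ cov @ c))
        out[g] = ComparisonResult(np.exp(mu), np.exp(mu) * se_mu, _wald_p(mu, se_mu))
    out["between"] = ComparisonResult(
        float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
    )
    return out


def compare_disconnection(proportions, group, sex, center, trials=None) -> dict:
    """Sex- and center-adjusted quasi-binomial comparison of proportions.

    Reports marginal estimated mean percentages per group (averaging
    predicted probabilities over the observed sex/center distribution, with
    delta-method SEs) and the Wald p for the group effect under the
    estimated dispersion. ``trials`` (optional) supplies binomial
    denominators as variance weights when proportions are k/m counts.
    """
    prop = np.asarray(proportions, dtype=float)
    if np.any((prop < 0) | (prop > 1)):
        raise DataError("proportions must lie in [0, 1]")
    groups = np.asarray(group)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise DataError("exactly two groups required")
    g1 = (groups == levels[1]).astype(float)
    male = (np.asarray(sex) == "M").astype(float)
    cdum, _ = _dummies(np.asarray(center), "center")
    x = np.column_stack([np.ones_like(prop), g1, male, cdum])
    kwargs = {} if trials is None else {"var_weights": np.asarray(trials, dtype=float)}
    fit = sm.GLM(prop, x, family=sm.families.Binomial(), **kwargs).fit(scale="X2")
    cov = np.asarray(fit.cov_params())

    out = {"dispersion": float(fit.scale)}
    group_cols = {levels[1]: 1}
    for g in levels:
        xg = x.copy()
        xg[:, 1] = 1.0 if g == levels[1] else 0.0
        eta = xg @ fit.params
        p_i = 1.0 / (1.0 + np.exp(-eta))
        mean_p = float(p_i.mean())
        grad = (p_i * (1 - p_i))[:, None] * xg
        c = grad.mean(axis=0)
        se = float(np.sqrt(c @ cov @ c))
        out[g] = ComparisonResult(100.0 * mean_p, 100.0 * se, _wald_p(mean_p, se))
    out["between"] = ComparisonResult(
        float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
    )
    return out


def fdr_adjust(p_values, family: str = "") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over one test family."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def group_comparison_report(
    cohort: pd.DataFrame, metric_table: pd.DataFrame, zscores: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the per-metric comparison table (estimates, SE, p, q).

    Rows: LV (back-transformed means), each z-scored metric (robust mean z
    per group and between-group test), each disconnection index (estimated
    mean percentages). FDR is applied once over every p in this table.
    """
    joined = cohort.merge(metric_table, on="subject_id", validate="one_to_one")
    patients = joined[joined["group"] != "HC"]
    levels = sorted(patients["group"].unique())
    rows = []

    def push(metric, results, unit, group_p=True):
        # raw-scale rows (LV, disconnection) carry no meaningful test vs 0,
        # so only their between-group p enters the FDR family
        for key in levels + ["between"]:
            r = results[key]
            rows.append(
                {
                    "metric": metric, "contrast": key, "unit": unit,
                    "estimate": r.estimate, "se": r.se,
                    "p": r.p if (group_p or key == "between") else np.nan,
                }
            )

    push(
        "lv_ml",
        compare_lesion_volume(
            patients["lv_ml"], patients["group"], patients["sex"], patients["center_id"]
        ),
        "mL",
        group_p=False,
    )
    for metric in ("inter_disc_pct", "intra_disc_pct"):
        if metric in patients.columns:
            push(
                metric,
                compare_disconnection(
                    patients[metric].to_numpy() / 100.0,
                    patients["group"], patients["sex"], patients["center_id"],
                ),
                "%",
                group_p=False,
            )
    zcols = [c for c in zscores.columns if c not in ("subject_id", "group", "center_id")]
    for metric in zcols:
        push(metric, robust_z_comparison(zscores[metric], zscores["group"]), "z")

    report = pd.DataFrame(rows)
    report["q"] = np.nan
    tested = report["p"].notna()
    report.loc[tested, "q"] = fdr_adjust(
        report.loc[tested, "p"].to_numpy(), family="group_comparison"
    )
    return report
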