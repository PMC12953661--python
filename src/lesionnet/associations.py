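"""Univariable odds-ratio models for impairment, group-interaction tests and
the balanced downsampled bootstrap.

Point estimates come from maximum-likelihood logistic regression;
inference uses heteroscedasticity-robust (sandwich, HC1) covariance.
Reported ORs are rescaled to interpretation units (per year, per 10% LV
increase, per percentage point, per z-unit) by multiplying the coefficient
by the unit factor before exponentiating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._rng import substream
from .errors import ConvergenceError, DataError

#: log(1.1): converts a log-LV coefficient into a per-10%-LV-increase OR
LV_10PCT_FACTOR = float(np.log(1.1))

UNIT_FACTORS = {
    "per_unit": 1.0,
    "per_year": 1.0,
    "per_pct": 1.0,
    "per_z": 1.0,
    "per_10pct_lv": LV_10PCT_FACTOR,
}


@dataclass
class AssociationResult:
    predictor: str
    or_: float
    ci_low: float
    ci_high: float
    p: float
    unit: str
    beta: float
    se: float
    n: int


def _screen_dummies(y: np.ndarray, x: np.ndarray, candidates) -> np.ndarray:
    """Column mask dropping degenerate adjustment dummies.

    In small bootstrap replicates an adjustment-covariate level (e.g. one
    center) can hold < 2 subjects or a constant outcome, which quasi-separates
    its indicator. Such levels are pooled into the reference by dropping the
    dummy; the focal predictor is never screened.
    """
    keep = np.ones(x.shape[1], dtype=bool)
    for j in candidates:
        col = x[:, j]
        if set(np.unique(col)) <= {0.0, 1.0}:
            on = col == 1.0
            if on.sum() < 2 or len(np.unique(y[on])) < 2:
                keep[j] = False
        elif np.ptp(col) == 0:
            keep[j] = False
    return keep


def _fit_logit(y: np.ndarray, x: np.ndarray, label: str, screen_cols=()):
    if len(np.unique(y)) < 2:
        raise DataError(f"outcome is constant in model for {label!r}")
    keep = _screen_dummies(y, x, screen_cols)
    cols = [j for j in range(x.shape[1]) if keep[j]]
    cand = [j for j in screen_cols if keep[j]]
    while True:
        fit = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y, x[:, cols]).fit(disp=0, cov_type="HC1", maxiter=200)
            except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
                if not cand:
                    raise ConvergenceError(
                        f"logistic fit failed for {label!r}: {exc}"
                    ) from exc
        if fit is not None:
            ok = fit.mle_retvals.get("converged", True) and np.all(
                np.abs(fit.params) <= 50
            )
            if ok:
                return fit
            if not cand:
                raise ConvergenceError(f"separation or non-convergence for {label!r}")
        # quasi-separation survives the pre-screen when a level holds copies
        # of very few subjects; drop the most extreme adjustment dummy
        if fit is not None:
            worst = max(cand, key=lambda j: abs(fit.params[cols.index(j)]))
        else:
            worst = min(cand, key=lambda j: x[:, j].sum())
        cand.remove(worst)
        cols.remove(worst)


def _design(df: pd.DataFrame, predictor: str, covariates: tuple) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(df)), df[predictor].to_numpy(dtype=float)]
    names = ["intercept", predictor]
    for cov in covariates:
        vals = df[cov]
        if vals.dtype == object or str(vals.dtype) == "category":
            levels = sorted(vals.unique())[1:]
            for lv in levels:
                cols.append((vals == lv).to_numpy(dtype=float))
                names.append(f"{cov}[{lv}]")
        else:
            cols.append(vals.to_numpy(dtype=float))
            names.append(cov)
    return np.column_stack(cols), names


def univariable_or(
    df: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple = (),
    unit: str = "per_unit",
    alpha: float = 0.05,
) -> AssociationResult:
    """Robust-SE logistic regression OR for one predictor.

    ``unit`` selects the reporting scale; for ``per_10pct_lv`` the predictor
    must already be log(LV), and the OR is exp(beta * ln 1.1).
    """
    if unit not in UNIT_FACTORS:
        raise DataError(f"unknown unit {unit!r}")
    data = df.dropna(subset=[outcome, predictor, *covariates])
    y = data[outcome].to_numpy(dtype=float)
    x, names = _design(data, predictor, covariates)
    fit = _fit_logit(y, x, predictor, screen_cols=range(2, x.shape[1]))
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    factor = UNIT_FACTORS[unit]
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return AssociationResult(
        predictor=predictor,
        or_=float(np.exp(beta * factor)),
        ci_low=float(np.exp((beta - zcrit * se) * factor)),
        ci_high=float(np.exp((beta + zcrit * se) * factor)),
        p=float(fit.pvalues[1]),
        unit=unit,
        beta=beta,
        se=se,
        n=len(data),
    )


def interaction_test(
    df: pd.DataFrame,
    outcome: str,
    predictor: str,
    group: str,
    covariates: tuple = (),
) -> float:
    """Wald p (robust covariance) for the group-by-predictor interaction."""
    data = df.dropna(subset=[outcome, predictor, group, *covariates])
    glevels = sorted(data[group].unique())
    if len(glevels) != 2:
        raise DataError("interaction test requires exactly two groups")
    x, names = _design(data, predictor, covariates)
    n_cov = x.shape[1]
    gind = (data[group] == glevels[1]).to_numpy(dtype=float)
    pred = data[predictor].to_numpy(dtype=float)
    x = np.column_stack([x, gind, gind * pred])
    fit = _fit_logit(
        data[outcome].to_numpy(dtype=float), x, f"{predictor}x{group}",
        screen_cols=range(2, n_cov),  # never screen the group or interaction terms
    )
    return float(fit.pvalues[-1])


@dataclass
class BootstrapResult:
    estimate: float  # median replicate value, OR scale
    ci_low: float
    ci_high: float
    p: float
    reps: int
    n_failed: int


def balanced_bootstrap(
    analysis,
    df: pd.DataFrame,
    group_col: str = "group",
    n_per_group: int = 80,
    reps: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Balanced downsampled bootstrap of a scalar log-OR analysis.

    Each replicate draws ``n_per_group`` subjects with replacement from every
    group, reruns ``analysis(replicate_df) -> log-OR``, and accumulates the
    statistic. Reports percentile CIs on the OR scale and a two-sided
    bootstrap p = 2 * min(P(stat <= 0), P(stat >= 0)), floored at 1/reps.
    Replicates that fail to converge are dropped and tallied; more than 20%
    failures is an error.
    """
    rng = substream(seed, "balanced_bootstrap")
    groups = {g: sub.index.to_numpy() for g, sub in df.groupby(group_col)}
    for g, idx in groups.items():
        if len(idx) < 3:
            raise DataError(f"group {g!r} has fewer than 3 subjects")
    stats_out = []
    n_failed = 0
    for _ in range(reps):
        take = np.concatenate(
            [rng.choice(idx, size=n_per_group, replace=True) for idx in groups.values()]
        )
        try:
            stats_out.append(float(analysis(df.loc[take])))
        except (DataError, ConvergenceError):
            n_failed += 1
    if n_failed > 0.2 * reps:
        raise ConvergenceError(
            f"{n_failed}/{reps} bootstrap replicates failed to converge"
        )
    vals = np.asarray(stats_out)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    frac_le = float(np.mean(vals <= 0))
    frac_ge = float(np.mean(vals >= 0))
    p = min(1.0, max(1.0 / reps, 2.0 * min(frac_le, frac_ge)))
    return BootstrapResult(
        estimate=float(np.exp(np.median(vals))),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p=p,
        reps=len(vals),
        n_failed=n_failed,
    )


#: predictor -> (unit, center-adjusted?) used by the standard report
STANDARD_PREDICTORS = {
    "age_at_mri": ("per_year", False),
    "sex_male": ("per_unit", False),
    "disease_duration": ("per_year", False),
    "lv_log": ("per_10pct_lv", True),
    "nbv": ("per_z", False),
    "ngmv": ("per_z", False),
    "nwmv": ("per_z", False),
    "density": ("per_z", False),
    "mean_strength": ("per_z", False),
    "efficiency": ("per_z", False),
    "clustering": ("per_z", False),
    "modularity": ("per_z", False),
    "inter_disc_pct": ("per_pct", True),
    "intra_disc_pct": ("per_pct", True),
    "commissural_ratio": ("per_z", False),
    "intra_hemi_efficiency": ("per_z", False),
    "conservation_ratio": ("per_z", False),
}


def association_frame(
    cohort: pd.DataFrame, metric_table: pd.DataFrame, zscores: pd.DataFrame
) -> pd.DataFrame:
    """Patient-level analysis frame with predictors on their reporting scales."""
    base = cohort[cohort["group"] != "HC"][
        ["subject_id", "group", "center_id", "sex", "age_at_mri",
         "disease_duration", "sdmt_impaired"]
    ].copy()
    base["sex_male"] = (base["sex"] == "M").astype(float)
    base["impaired"] = base["sdmt_impaired"].astype(float)
    raw = metric_table[["subject_id", "lv_ml", "inter_disc_pct", "intra_disc_pct"]]
    out = base.merge(raw, on="subject_id")
    with np.errstate(divide="ignore"):
        out["lv_log"] = np.where(out["lv_ml"] > 0, np.log(out["lv_ml"]), np.nan)
    zcols = [c for c in zscores.columns if c not in ("subject_id", "group", "center_id")]
    out = out.merge(zscores[["subject_id"] + zcols], on="subject_id")
    return out.reset_index(drop=True)


def association_report(
    frame: pd.DataFrame,
    n_per_group: int = 80,
    reps: int = 5000,
    seed: int = 0,
    predictors: dict | None = None,
) -> pd.DataFrame:
    """Per-group univariable ORs, interaction p, and bootstrap CIs/p."""
    predictors = predictors or {
        k: v for k, v in STANDARD_PREDICTORS.items() if k in frame.columns
    }
    levels = sorted(frame["group"].unique())
    rows = []
    for pred, (unit, adj) in predictors.items():
        covs = ("center_id",) if adj else ()
        for g in levels:
            sub = frame[frame["group"] == g]
            res = univariable_or(sub, "impaired", pred, covariates=covs, unit=unit)

            def stat(d, _pred=pred, _covs=covs, _unit=unit):
                r = univariable_or(d, "impaired", _pred, covariates=_covs, unit=_unit)
                return np.log(r.or_)

            boot = balanced_bootstrap(
                stat, sub, group_col="group", n_per_group=n_per_group,
                reps=reps, seed=seed,
            )
            rows.append(
                {
                    "predictor": pred, "group": g, "unit": unit,
                    "or": res.or_, "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "p": res.p,
                    "boot_ci_low": boot.ci_low, "boot_ci_high": boot.ci_high,
                    "boot_p": boot.p, "boot_failed": boot.n_failed,
                }
            )
        try:
            p_int = interaction_test(frame, "impaired", pred, "group", covariates=covs)
        except (DataError, ConvergenceError):
            p_int = np.nan
        for row in rows[-len(levels):]:
            row["interaction_p"] = p_int
    return pd.DataFrame(rows)
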