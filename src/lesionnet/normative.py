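"""Multicenter normative z-scoring with heteroscedastic center variances.

The healthy-control reference is a linear mean model (sex, age, sex x age,
center) fit by feasible generalized least squares: weighted least squares
and per-center residual variances are iterated to convergence. A patient's
z-score is the raw deviation from the reference prediction divided by the
patient's center residual SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DataError


@dataclass
class ReferenceModel:
    """Fitted healthy-reference model for one metric."""

    metric: str
    coefficients: pd.Series  # indexed by design term
    sigma_by_center: dict
    age_center: float
    centers: tuple
    n_per_center: dict
    n_iterations: int
    converged: bool
    age_range: tuple = (np.nan, np.nan)
    history: list = field(default_factory=list, repr=False)


def _design(
    df: pd.DataFrame, age_center: float, centers: tuple
) -> tuple[np.ndarray, list]:
    male = (df["sex"] == "M").to_numpy(dtype=float)
    age_c = df["age_at_mri"].to_numpy(dtype=float) - age_center
    cols = [np.ones(len(df)), male, age_c, male * age_c]
    names = ["intercept", "male", "age_c", "male_age_c"]
    for c in centers[1:]:  # first center absorbed by the intercept
        cols.append((df["center_id"] == c).to_numpy(dtype=float))
        names.append(f"center[{c}]")
    return np.column_stack(cols), names


def fit_reference(
    hc: pd.DataFrame,
    metric: str,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> ReferenceModel:
    """Fit the heteroscedastic reference model to healthy-control rows.

    Residual variance per center uses that center's residual degrees of
    freedom (n_c minus the center's share of model parameters), which
    reduces small-center bias relative to dividing by n_c.
    """
    required = {"sex", "age_at_mri", "center_id", metric}
    missing = required - set(hc.columns)
    if missing:
        raise DataError(f"missing columns: {sorted(missing)}")
    if hc[metric].isna().any():
        raise DataError(f"metric {metric!r} has missing values")
    centers = tuple(sorted(hc["center_id"].unique()))
    n_per_center = hc["center_id"].value_counts().to_dict()
    for c in centers:
        if n_per_center[c] < 2:
            raise DataError(f"center {c!r} has fewer than 2 healthy controls")

    age_center = float(hc["age_at_mri"].mean())
    x, names = _design(hc, age_center, centers)
    y = hc[metric].to_numpy(dtype=float)
    n, p = x.shape
    center_codes = hc["center_id"].to_numpy()

    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    sigma2 = {c: 1.0 for c in centers}
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - x @ beta
        new_sigma2 = {}
        for c in centers:
            idx = center_codes == c
            n_c = int(idx.sum())
            dof = n_c - p * n_c / n  # center's share of model parameters
            rss = float(resid[idx] @ resid[idx])
            if rss == 0:
                raise ConvergenceError(
                    f"center {c!r} has zero residual variance for {metric!r}"
                )
            new_sigma2[c] = rss / dof
        history.append(dict(new_sigma2))
        rel = max(
            abs(new_sigma2[c] - sigma2[c]) / new_sigma2[c] for c in centers
        )
        sigma2 = new_sigma2
        w = np.array([1.0 / sigma2[c] for c in center_codes])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(x * sw[:, None], y * sw, rcond=None)
        if rel < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"variance iteration for {metric!r} did not converge in {max_iter} "
            f"iterations; trace: {history[-3:]}"
        )
    return ReferenceModel(
        metric=metric,
        coefficients=pd.Series(beta, index=names),
        sigma_by_center={c: float(np.sqrt(sigma2[c])) for c in centers},
        age_center=age_center,
        centers=centers,
        n_per_center={c: int(n_per_center[c]) for c in centers},
        n_iterations=it,
        converged=converged,
        age_range=(float(hc["age_at_mri"].min()), float(hc["age_at_mri"].max())),
        history=history,
    )


def predict_reference(rows: pd.DataFrame, model: ReferenceModel) -> np.ndarray:
    unseen = set(rows["center_id"]) - set(model.centers)
    if unseen:
        raise DataError(
            f"center(s) {sorted(unseen)} not present in the reference model"
        )
    x, _ = _design(rows, model.age_center, model.centers)
    return x @ model.coefficients.to_numpy()


def zscore(rows: pd.DataFrame, model: ReferenceModel) -> np.ndarray:
    """z = (observed - predicted) / center residual SD, sign preserved.

    Ages outside the reference range are scored (the reference is expected
    to span the patient age spectrum) but trigger an extrapolation warning.
    """
    lo, hi = model.age_range
    ages = rows["age_at_mri"].to_numpy(dtype=float)
    if np.isfinite(lo) and ((ages < lo) | (ages > hi)).any():
        warnings.warn(
            f"{metric_name(model)}: scoring ages outside the reference range "
            f"[{lo:.1f}, {hi:.1f}] (extrapolation)"
        )
    yhat = predict_reference(rows, model)
    sigma = np.array([model.sigma_by_center[c] for c in rows["center_id"]])
    return (rows[model.metric].to_numpy(dtype=float) - yhat) / sigma


def metric_name(model: ReferenceModel) -> str:
    return model.metric


def zscore_table(
    cohort: pd.DataFrame,
    metric_table: pd.DataFrame,
    metrics: list | None = None,
    exclude: tuple = ("lv_ml", "inter_disc_pct", "intra_disc_pct"),
) -> tuple[pd.DataFrame, dict]:
    """Z-score all requested metrics for patients against the HC reference.

    Returns (patients-only z table, fitted models). LV and disconnection
    indices are excluded by default: they are analyzed on their raw scales.
    Per-metric failures are collected and reported together; the remaining
    metrics are still scored.
    """
    joined = cohort.merge(metric_table, on="subject_id", validate="one_to_one")
    if metrics is None:
        metrics = [
            c for c in metric_table.columns if c != "subject_id" and c not in exclude
        ]
    hc = joined[joined["group"] == "HC"]
    patients = joined[joined["group"] != "HC"]
    if hc.empty:
        raise DataError("no healthy controls available to fit the reference")

    out = patients[["subject_id", "group", "center_id"]].reset_index(drop=True)
    models: dict[str, ReferenceModel] = {}
    failures: dict[str, str] = {}
    for metric in metrics:
        try:
            model = fit_reference(hc, metric)
            out[metric] = zscore(patients, model)
            models[metric] = model
        except (DataError, ConvergenceError) as exc:  # keep scoring the rest
            failures[metric] = str(exc)
    if failures:
        summary = "; ".join(f"{m}: {msg}" for m, msg in failures.items())
        warnings.warn(f"z-scoring failed for {len(failures)} metric(s): {summary}")
    return out, models


def serialize_model(model: ReferenceModel) -> dict:
    """Audit-friendly plain structure (JSON/YAML serializable)."""
    return {
        "metric": model.metric,
        "coefficients": {k: float(v) for k, v in model.coefficients.items()},
        "sigma_by_center": model.sigma_by_center,
        "age_center": model.age_center,
        "age_range": [float(a) for a in model.age_range],
        "centers": list(model.centers),
        "n_per_center": model.n_per_center,
        "n_iterations": model.n_iterations,
        "converged": model.converged,
    }
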