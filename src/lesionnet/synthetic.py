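"""Synthetic multicenter cohorts, toy parcellations/tractograms/lesions.

Generates subject tables and per-subject metric tables with known injected
group effects, plus small geometric artifacts (labeled voxel grids,
streamline polylines, spherical lesion masks) that exercise the connectome
construction code. Every generator is a pure function of (config, seed):
the master seed spawns a named substream per generator (see ``_rng``).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .connectome import LesionMask, Parcellation, Tractogram
from .errors import ConfigurationError

GROUPS = ("HC", "AOMS", "LOMS")

#: metrics that go through the normative z-scoring path
NORMATIVE_METRICS = (
    "nbv",
    "ngmv",
    "nwmv",
    "density",
    "efficiency",
    "mean_strength",
    "clustering",
    "modularity",
    "commissural_ratio",
    "intra_hemi_efficiency",
    "conservation_ratio",
)

#: disconnection indices (percent scale, quasi-binomial path, patients only)
DISCONNECTION_METRICS = ("inter_disc_pct", "intra_disc_pct")

METRIC_COLUMNS = ("lv_ml",) + NORMATIVE_METRICS + DISCONNECTION_METRICS


@dataclass(frozen=True)
class _MetricParams:
    """Healthy-reference generating model for one raw metric."""

    intercept: float
    sex_beta: float  # male minus female
    age_beta: float  # per year, age centered at 45
    sex_age_beta: float
    sigma: float  # baseline residual SD (center 1)
    lo: float = -np.inf
    hi: float = np.inf


# Plausible raw scales; exact values are irrelevant to the statistics, which
# operate on z-scores, but ranges keep the invariants (ratios in [0,1]).
_BASE_PARAMS: dict[str, _MetricParams] = {
    "nbv": _MetricParams(1500.0, 60.0, -2.2, -0.3, 55.0, lo=0.0),
    "ngmv": _MetricParams(800.0, 30.0, -1.5, -0.2, 35.0, lo=0.0),
    "nwmv": _MetricParams(700.0, 30.0, -0.9, -0.1, 30.0, lo=0.0),
    "density": _MetricParams(0.32, 0.004, -0.0009, -0.0001, 0.018, lo=0.0, hi=1.0),
    "efficiency": _MetricParams(0.42, 0.005, -0.0012, -0.0001, 0.022, lo=0.0, hi=1.0),
    "mean_strength": _MetricParams(28.0, 0.5, -0.08, -0.01, 1.6, lo=0.0),
    "clustering": _MetricParams(0.45, 0.004, -0.0010, -0.0001, 0.020, lo=0.0, hi=1.0),
    "modularity": _MetricParams(0.52, -0.003, 0.0008, 0.0001, 0.025, lo=-0.5, hi=1.0),
    "commissural_ratio": _MetricParams(0.22, 0.002, -0.0005, 0.0, 0.014, lo=0.0, hi=1.0),
    "intra_hemi_efficiency": _MetricParams(0.48, 0.004, -0.0010, -0.0001, 0.020, lo=0.0, hi=1.0),
    "conservation_ratio": _MetricParams(0.46, 0.003, -0.0006, 0.0, 0.022, lo=0.0),
}

# Default injected shifts (HC-SD units) per group, motivated by the target
# study's group-level findings; exposed so tests can inject arbitrary effects.
DEFAULT_EFFECT_PROFILE: dict[str, tuple[float, float]] = {
    "nbv": (-0.523, -0.813),
    "ngmv": (-0.455, -0.746),
    "nwmv": (-0.331, -0.307),
    "density": (-0.979, -1.667),
    "efficiency": (-1.071, -1.136),
    "mean_strength": (-1.299, -1.690),
    "clustering": (-1.050, -1.180),
    "modularity": (0.568, 0.994),
    "commissural_ratio": (-0.705, -0.779),
    "intra_hemi_efficiency": (-0.092, 0.003),
    "conservation_ratio": (-0.590, -0.763),
}

#: default disconnection means on the percent scale, (AOMS, LOMS)
DEFAULT_DISC_MEANS: dict[str, tuple[float, float]] = {
    "inter_disc_pct": (8.38, 11.18),
    "intra_disc_pct": (1.70, 2.41),
}


@dataclass
class SimConfig:
    """Configuration for cohort and metric simulation.

    ``metric_effect_profile`` maps metric name -> (AOMS shift, LOMS shift)
    in healthy-control SD units. ``impairment_model`` is an intercept plus
    log-odds coefficients keyed by predictor column name; predictors may be
    demographic columns or (z-scored) metric columns.
    """

    n_centers: int = 7
    n_hc: int = 519
    n_aoms: int = 294
    n_loms: int = 80
    hc_age_range: tuple[float, float] = (18.0, 77.0)
    aoms_onset_range: tuple[float, float] = (18.0, 45.0)
    loms_onset_range: tuple[float, float] = (45.0, 66.0)
    max_disease_duration: float = 6.0
    female_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.56, "AOMS": 0.65, "LOMS": 0.60}
    )
    education_p: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.83, "AOMS": 0.72, "LOMS": 0.50}
    )
    pms_p: Mapping[str, float] = field(default_factory=lambda: {"AOMS": 0.04, "LOMS": 0.10})
    metric_effect_profile: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PROFILE)
    )
    disc_mean_pct: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DISC_MEANS)
    )
    lv_log_mean: Mapping[str, float] = field(
        default_factory=lambda: {"AOMS": 0.66, "LOMS": 1.07}
    )
    lv_log_sd: float = 1.0
    impairment_model: Mapping[str, float] = field(
        default_factory=lambda: {"intercept": math.log(0.39 / 0.61)}
    )
    center_sigma_multipliers: Sequence[float] = field(
        default_factory=lambda: (1.0,) * 7
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_centers < 1:
            raise ConfigurationError("n_centers must be >= 1")
        for name in ("n_hc", "n_aoms", "n_loms"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_hc + self.n_aoms + self.n_loms == 0:
            raise ConfigurationError("cohort is empty")
        if len(self.center_sigma_multipliers) != self.n_centers:
            raise ConfigurationError(
                "center_sigma_multipliers must have one entry per center"
            )
        if any(m <= 0 for m in self.center_sigma_multipliers):
            raise ConfigurationError("center SD multipliers must be > 0")
        for mapping in (self.female_fraction, self.education_p, self.pms_p):
            for key, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"probability {key}={p} outside [0,1]")
        if self.loms_onset_range[0] < 45.0:
            raise ConfigurationError("LOMS onset must start at >= 45 years")
        if not (18.0 <= self.aoms_onset_range[0] < self.aoms_onset_range[1] <= 45.0):
            raise ConfigurationError("AOMS onset range must lie within (18, 45)")
        if self.max_disease_duration <= 0 or self.max_disease_duration > 6.0:
            raise ConfigurationError("disease duration must be in (0, 6] years")
        for metric in self.metric_effect_profile:
            if metric not in NORMATIVE_METRICS:
                raise ConfigurationError(f"unknown metric in effect profile: {metric!r}")
        for metric in self.disc_mean_pct:
            if metric not in DISCONNECTION_METRICS:
                raise ConfigurationError(f"unknown disconnection metric: {metric!r}")
        if "intercept" not in self.impairment_model:
            raise ConfigurationError("impairment_model requires an 'intercept' key")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def _draw_ages(group: str, n: int, config: SimConfig, rng: np.random.Generator):
    """Return (age_at_mri, age_at_onset, disease_duration); onset NaN for HC."""
    if group == "HC":
        lo, hi = config.hc_age_range
        age = rng.uniform(lo, hi, n)
        return age, np.full(n, np.nan), np.full(n, np.nan)
    lo, hi = config.aoms_onset_range if group == "AOMS" else config.loms_onset_range
    onset = rng.uniform(lo, hi, n)
    duration = rng.uniform(0.0, config.max_disease_duration, n)
    return onset + duration, onset, duration


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate the subject-level table (one row per participant).

    SDMT impairment is drawn here only when every impairment-model predictor
    is a demographic column of the cohort; models that reference (z-scored)
    metric columns are resolved later by :func:`assign_impairment`, once the
    metric table exists.
    """
    config.validate()
    rng = substream(config.seed, "cohort")

    frames = []
    counter = 0
    for group, n in (("HC", config.n_hc), ("AOMS", config.n_aoms), ("LOMS", config.n_loms)):
        if n == 0:
            continue
        age, onset, duration = _draw_ages(group, n, config, rng)
        female = rng.random(n) < config.female_fraction.get(group, 0.5)
        center = rng.integers(1, config.n_centers + 1, n)
        edu = rng.random(n) < config.education_p.get(group, 0.5)
        if group == "HC":
            edss = np.full(n, np.nan)
            phenotype = np.array([""] * n, dtype=object)
        else:
            edss = np.round(np.clip(rng.gamma(2.0, 1.0 if group == "LOMS" else 0.75, n), 0, 9.5) * 2) / 2
            phenotype = np.where(rng.random(n) < config.pms_p.get(group, 0.0), "PMS", "RRMS")
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"S{counter + i:05d}" for i in range(n)],
                    "center_id": [f"C{c}" for c in center],
                    "group": group,
                    "sex": np.where(female, "F", "M"),
                    "age_at_mri": age,
                    "age_at_onset": onset,
                    "disease_duration": duration,
                    "education_ge13": edu,
                    "edss": edss,
                    "phenotype": phenotype,
                }
            )
        )
        counter += n
    cohort = pd.concat(frames, ignore_index=True)
    cohort["sdmt_z"] = np.nan
    cohort["sdmt_impaired"] = pd.array([pd.NA] * len(cohort), dtype="boolean")

    predictors = [k for k in config.impairment_model if k != "intercept"]
    if all(p in cohort.columns or p == "sex_male" for p in predictors):
        cohort = assign_impairment(cohort, None, config)
    return cohort


def _impairment_design(cohort: pd.DataFrame, metrics: pd.DataFrame | None) -> pd.DataFrame:
    df = cohort.copy()
    df["sex_male"] = (df["sex"] == "M").astype(float)
    if metrics is not None:
        extra = metrics.drop(columns=[c for c in metrics.columns if c in df.columns])
        df = pd.concat([df.reset_index(drop=True), extra.reset_index(drop=True)], axis=1)
    return df


def assign_impairment(
    cohort: pd.DataFrame, metrics: pd.DataFrame | None, config: SimConfig
) -> pd.DataFrame:
    """Draw SDMT impairment for patients from the configured logistic model.

    ``sdmt_z`` is filled consistently with the -1.5 SD impairment rule by a
    truncated-normal draw on the matching side of the cutoff.
    """
    rng = substream(config.seed, "impairment")
    design = _impairment_design(cohort, metrics)
    eta = np.full(len(cohort), float(config.impairment_model["intercept"]))
    for name, beta in config.impairment_model.items():
        if name == "intercept":
            continue
        if name not in design.columns:
            raise ConfigurationError(f"impairment predictor {name!r} not available")
        eta = eta + float(beta) * design[name].to_numpy(dtype=float)
    prob = 1.0 / (1.0 + np.exp(-eta))

    out = cohort.copy()
    patients = (out["group"] != "HC").to_numpy()
    impaired = rng.random(len(out)) < prob
    impaired[~patients] = False

    # z consistent with status: impaired strictly below -1.5, else above
    z = np.full(len(out), np.nan)
    below = -1.5 - np.abs(rng.normal(0.7, 0.5, len(out)))
    above = -1.5 + np.abs(rng.normal(1.0, 0.8, len(out)))
    z[patients] = np.where(impaired[patients], below[patients], above[patients])

    out.loc[patients, "sdmt_z"] = z[patients]
    out["sdmt_impaired"] = pd.array(
        [bool(i) if p else pd.NA for i, p in zip(impaired, patients)], dtype="boolean"
    )
    return out


def simulate_metric_table(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Simulate raw per-subject MRI measures with injected group effects.

    Each normative metric is center intercept + sex/age/sex-by-age effects
    + group shift (in units of that subject's center-specific HC SD)
    + heteroscedastic Gaussian noise. LV is log-normal with group-specific
    location (0 for HC); disconnection indices are logit-normal around the
    configured group mean percentages (0 for HC).
    """
    config.validate()
    rng = substream(config.seed, "metrics")
    center_rng = substream(config.seed, "center_effects")
    n = len(cohort)
    mult = np.asarray(config.center_sigma_multipliers, dtype=float)
    center_idx = cohort["center_id"].str.lstrip("C").astype(int).to_numpy() - 1
    if center_idx.min() < 0 or center_idx.max() >= config.n_centers:
        raise ConfigurationError("cohort references centers outside config range")
    male = (cohort["sex"] == "M").to_numpy(dtype=float)
    age_c = cohort["age_at_mri"].to_numpy(dtype=float) - 45.0
    group = cohort["group"].to_numpy()

    out = pd.DataFrame({"subject_id": cohort["subject_id"].to_numpy()})

    # lesion volume: HC have none
    lv = np.zeros(n)
    for g in ("AOMS", "LOMS"):
        mask = group == g
        lv[mask] = np.exp(rng.normal(config.lv_log_mean.get(g, 0.0), config.lv_log_sd, mask.sum()))
    out["lv_ml"] = lv

    for metric in NORMATIVE_METRICS:
        par = _BASE_PARAMS[metric]
        center_offsets = center_rng.normal(0.0, 0.5 * par.sigma, config.n_centers)
        sigma_i = par.sigma * mult[center_idx]
        shift = np.zeros(n)
        profile = config.metric_effect_profile.get(metric)
        if profile is not None:
            aoms_shift, loms_shift = profile
            shift[group == "AOMS"] = aoms_shift
            shift[group == "LOMS"] = loms_shift
        y = (
            par.intercept
            + center_offsets[center_idx]
            + par.sex_beta * male
            + par.age_beta * age_c
            + par.sex_age_beta * male * age_c
            + shift * sigma_i
            + rng.normal(0.0, sigma_i)
        )
        out[metric] = np.clip(y, par.lo, par.hi)

    logit = lambda p: np.log(p / (1.0 - p))  # noqa: E731
    for metric in DISCONNECTION_METRICS:
        aoms_pct, loms_pct = config.disc_mean_pct[metric]
        vals = np.zeros(n)
        for g, pct in (("AOMS", aoms_pct), ("LOMS", loms_pct)):
            mask = group == g
            eta = rng.normal(logit(pct / 100.0), 0.35, mask.sum())
            vals[mask] = 100.0 / (1.0 + np.exp(-eta))
        out[metric] = vals
    return out


def simulate_study(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort + metric table with impairment resolved against both."""
    cohort = simulate_cohort(config)
    metrics = simulate_metric_table(cohort, config)
    cohort = assign_impairment(cohort, metrics, config)
    return cohort, metrics


# ---------------------------------------------------------------------------
# geometric artifacts


def simulate_parcellation(
    n_nodes: int = 253,
    grid_shape: tuple[int, int, int] = (30, 30, 30),
    voxel_size: float = 1.0,
    seed: int = 0,
) -> Parcellation:
    """Build a toy labeled voxel grid with nodes split across hemispheres.

    Nodes are disjoint axis-aligned cells; an odd remainder becomes one
    midline (MID) node straddling the midsagittal plane. Nodes in the bottom
    z-quarter of the grid are flagged infratentorial.
    """
    if n_nodes < 2:
        raise ConfigurationError("n_nodes must be >= 2")
    nx, ny, nz = grid_shape
    labels = np.zeros(grid_shape, dtype=np.int32)
    n_mid = n_nodes % 2
    n_half = n_nodes // 2
    half_x = nx // 2
    if n_mid:
        # reserve the central x slab for the midline node
        left_x = (0, half_x - 1)
        right_x = (half_x + 1, nx)
    else:
        left_x = (0, half_x)
        right_x = (half_x, nx)

    next_label = 1
    rows = []

    def fill_hemisphere(x_range, hemi):
        nonlocal next_label
        x0, x1 = x_range
        span = {"x": x1 - x0, "y": ny, "z": nz}
        k = max(1, math.ceil(n_half ** (1.0 / 3.0)))
        # grow subdivisions until enough cells, bounded by axis lengths
        while True:
            kx, ky, kz = (min(k, span["x"]), min(k, span["y"]), min(k, span["z"]))
            if kx * ky * kz >= n_half:
                break
            if k >= max(span.values()):
                raise ConfigurationError(
                    f"n_nodes={n_nodes} exceeds grid capacity for shape {grid_shape}"
                )
            k += 1
        xs = np.array_split(np.arange(x0, x1), kx)
        ys = np.array_split(np.arange(ny), ky)
        zs = np.array_split(np.arange(nz), kz)
        cells = [(a, b, c) for a in xs for b in ys for c in zs]
        for a, b, c in cells[:n_half]:
            labels[np.ix_(a, b, c)] = next_label
            cx = (a.mean() + 0.5) * voxel_size
            cy = (b.mean() + 0.5) * voxel_size
            cz = (c.mean() + 0.5) * voxel_size
            rows.append((next_label, hemi, cz > 0.25 * nz * voxel_size, cx, cy, cz))
            next_label += 1

    fill_hemisphere(left_x, "L")
    fill_hemisphere(right_x, "R")
    if n_mid:
        xs = np.arange(half_x - 1, half_x + 1)
        labels[np.ix_(xs, np.arange(ny), np.arange(1))] = next_label
        rows.append(
            (next_label, "MID", False, (xs.mean() + 0.5) * voxel_size,
             ny / 2 * voxel_size, 0.5 * voxel_size)
        )
        next_label += 1

    node_table = pd.DataFrame(
        rows,
        columns=["node_id", "hemisphere", "supratentorial", "centroid_x", "centroid_y", "centroid_z"],
    )
    return Parcellation(labels=labels, voxel_size=float(voxel_size), node_table=node_table)


def _polyline(p0: np.ndarray, p1: np.ndarray, rng, jitter: float, step: float) -> np.ndarray:
    length = float(np.linalg.norm(p1 - p0))
    n_pts = max(2, int(math.ceil(length / step)) + 1)
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    pts = p0[None, :] * (1 - t) + p1[None, :] * t
    if n_pts > 2 and jitter > 0:
        pts[1:-1] += rng.normal(0.0, jitter, (n_pts - 2, 3))
    return pts


def simulate_tractogram(
    parcellation: Parcellation,
    n_streamlines: int,
    commissural_fraction: float,
    fa_params: tuple[float, float] = (8.0, 12.0),
    seed: int = 0,
    jitter: float = 0.0,
) -> Tractogram:
    """Generate straight-ish polylines between random voxels of node pairs.

    Each streamline's endpoints are voxel centers inside two distinct node
    regions; the commissural fraction controls the probability that the two
    nodes sit in opposite hemispheres. Per-streamline mean FA ~ Beta(a, b).
    """
    if not 0.0 <= commissural_fraction <= 1.0:
        raise ConfigurationError("commissural_fraction must lie in [0, 1]")
    rng = substream(seed, "tractogram")
    vs = parcellation.voxel_size
    nt = parcellation.node_table
    hemis = {
        h: nt.loc[nt["hemisphere"] == h, "node_id"].to_numpy() for h in ("L", "R")
    }
    if commissural_fraction > 0 and (len(hemis["L"]) == 0 or len(hemis["R"]) == 0):
        raise ConfigurationError("commissural streamlines need nodes in both hemispheres")
    intra_hemis = [h for h in ("L", "R") if len(hemis[h]) >= 2]
    if commissural_fraction < 1 and not intra_hemis:
        raise ConfigurationError("no hemisphere has >= 2 nodes for intra-hemispheric streamlines")

    voxels = {
        int(k): np.argwhere(parcellation.labels == int(k)) for k in nt["node_id"]
    }
    streamlines, fas = [], []
    a, b = fa_params
    for _ in range(n_streamlines):
        if rng.random() < commissural_fraction:
            na = int(rng.choice(hemis["L"]))
            nb = int(rng.choice(hemis["R"]))
        else:
            h = intra_hemis[int(rng.integers(len(intra_hemis)))]
            na, nb = (int(x) for x in rng.choice(hemis[h], size=2, replace=False))
        va = voxels[na][int(rng.integers(len(voxels[na])))]
        vb = voxels[nb][int(rng.integers(len(voxels[nb])))]
        p0 = (va + 0.5) * vs
        p1 = (vb + 0.5) * vs
        streamlines.append(_polyline(p0, p1, rng, jitter, step=vs))
        fas.append(min(1.0, max(1e-6, float(rng.beta(a, b)))))
    return Tractogram(streamlines=streamlines, fa=np.asarray(fas))


def simulate_lesions(
    grid_shape: tuple[int, int, int],
    voxel_size_mm: float,
    target_lv_ml: float,
    n_foci: int = 5,
    seed: int = 0,
    concentration: float = 0.2,
) -> LesionMask:
    """Union of spherical lesion foci biased toward the grid center.

    Foci are added until the achieved volume is within one focus-volume of
    the target. ``concentration`` is the placement SD as a fraction of the
    grid extent (small values cluster foci near the center).
    """
    if target_lv_ml < 0:
        raise ConfigurationError("target_lv_ml must be >= 0")
    shape = tuple(int(s) for s in grid_shape)
    voxel_vol_ml = voxel_size_mm**3 / 1000.0
    grid_vol_ml = voxel_vol_ml * np.prod(shape)
    if target_lv_ml > grid_vol_ml:
        raise ConfigurationError(
            f"target LV {target_lv_ml} mL exceeds grid volume {grid_vol_ml:.3f} mL"
        )
    mask = np.zeros(shape, dtype=bool)
    if target_lv_ml == 0:
        return LesionMask(mask=mask, voxel_size=float(voxel_size_mm))

    rng = substream(seed, "lesions")
    focus_ml = target_lv_ml / max(1, n_foci)
    radius_mm = (3.0 * focus_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    center = (np.asarray(shape) / 2.0) * voxel_size_mm
    sd = concentration * np.asarray(shape) * voxel_size_mm
    coords = (np.indices(shape).reshape(3, -1).T + 0.5) * voxel_size_mm

    placed = 0
    max_foci = 50 * max(1, n_foci)
    while placed < max_foci:
        achieved = mask.sum() * voxel_vol_ml
        if placed >= n_foci and achieved >= target_lv_ml - focus_ml:
            break
        c = rng.normal(center, sd)
        c = np.clip(c, 0.0, np.asarray(shape) * voxel_size_mm)
        inside = np.linalg.norm(coords - c, axis=1) <= radius_mm
        mask |= inside.reshape(shape)
        placed += 1
    return LesionMask(mask=mask, voxel_size=float(voxel_size_mm))
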