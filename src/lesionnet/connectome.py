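"""Connectivity-matrix construction and lesion-based disconnection.

Builds streamline-count and FA-weighted matrices from streamline sets over a
labeled node parcellation, flags streamlines intersecting a lesion mask, and
derives supratentorial intra-/inter-hemispheric disconnection indices plus
the commissural ratio.

Conventions: coordinates are world millimetres, grids are 0-based with the
origin at the grid corner, and a point maps to voxel index
``floor(coord / voxel_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError

HEMISPHERES = ("L", "R", "MID")


@dataclass
class Parcellation:
    """Labeled voxel grid (0 = background, k = node k) plus node metadata."""

    labels: np.ndarray
    voxel_size: float
    node_table: pd.DataFrame

    def __post_init__(self) -> None:
        present = np.unique(self.labels)
        present = set(int(v) for v in present if v != 0)
        ids = set(int(v) for v in self.node_table["node_id"])
        if not present <= ids:
            raise DataError(f"grid labels {sorted(present - ids)} missing from node table")
        n = len(ids)
        if ids != set(range(1, n + 1)):
            raise DataError("node ids must be contiguous 1..N")

    @property
    def n_nodes(self) -> int:
        return len(self.node_table)


@dataclass
class Tractogram:
    """Streamline polylines (mm) with per-streamline mean FA in (0, 1]."""

    streamlines: list
    fa: np.ndarray

    def __post_init__(self) -> None:
        self.fa = np.asarray(self.fa, dtype=float)
        if len(self.streamlines) != len(self.fa):
            raise DataError("one FA value per streamline required")
        if len(self.fa) and not np.all(np.isfinite(self.fa)):
            raise DataError("FA values must be finite")
        for s in self.streamlines:
            if len(s) < 2:
                raise DataError("each streamline needs >= 2 points")

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class LesionMask:
    """Binary lesion voxel grid aligned with a parcellation grid."""

    mask: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def lv_ml(self) -> float:
        return float(self.mask.sum()) * self.voxel_size**3 / 1000.0


@dataclass
class Connectome:
    """Symmetric streamline-count and mean-FA matrices over labeled nodes."""

    count: np.ndarray
    fa: np.ndarray
    node_table: pd.DataFrame

    def __post_init__(self) -> None:
        count, fa = np.asarray(self.count, float), np.asarray(self.fa, float)
        if count.shape != fa.shape or count.shape[0] != count.shape[1]:
            raise DataError("count and FA matrices must be square and same shape")
        if not (np.allclose(count, count.T) and np.allclose(fa, fa.T)):
            raise DataError("connectome matrices must be symmetric")
        if np.any(np.diag(count) != 0) or np.any(np.diag(fa) != 0):
            raise DataError("connectome diagonal must be zero")
        if np.any((count == 0) & (fa != 0)):
            raise DataError("FA entries must be zero where count is zero")

    @property
    def n_nodes(self) -> int:
        return self.count.shape[0]


@dataclass
class DisconnectionResult:
    """Per-class lesioned-streamline tallies and derived indices.

    Indices are percentages; a class with zero streamlines yields a missing
    (NaN) index, never 0. ``commissural_ratio`` is inter-hemispheric
    streamlines over all assigned streamlines.
    """

    s_total: int
    class_counts: dict
    class_lesioned: dict
    intra_disc_pct: float
    inter_disc_pct: float
    commissural_ratio: float
    disconnectivity: np.ndarray = field(repr=False)


def assign_endpoints(
    tractogram: Tractogram, parcellation: Parcellation, search_radius_mm: float = 2.0
) -> pd.DataFrame:
    """Map each streamline's endpoints to nodes.

    An endpoint inside a labeled voxel maps to that node; otherwise to the
    nearest labeled voxel (center-to-point distance, located at voxel
    resolution) within ``search_radius_mm``. Streamlines with an unassigned
    endpoint or with both endpoints in the same node are flagged excluded.
    """
    if search_radius_mm < 0:
        raise DataError("search radius must be >= 0")
    labels = parcellation.labels
    vs = parcellation.voxel_size
    shape = np.asarray(labels.shape)

    background = labels == 0
    if background.all():
        nearest_idx = None
    else:
        nearest_idx = ndimage.distance_transform_edt(
            background, sampling=vs, return_distances=False, return_indices=True
        )

    def node_of(point: np.ndarray) -> int:
        vox = np.floor(np.asarray(point) / vs).astype(int)
        vox = np.clip(vox, 0, shape - 1)
        lab = int(labels[tuple(vox)])
        if lab > 0:
            return lab
        if nearest_idx is None:
            return 0
        near = tuple(nearest_idx[(slice(None),) + tuple(vox)])
        center = (np.asarray(near) + 0.5) * vs
        if np.linalg.norm(center - np.asarray(point)) <= search_radius_mm:
            return int(labels[near])
        return 0

    rows = []
    for s in tractogram.streamlines:
        a = node_of(np.asarray(s[0], dtype=float))
        b = node_of(np.asarray(s[-1], dtype=float))
        excluded = a == 0 or b == 0 or a == b
        rows.append((a, b, excluded))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "excluded"])


def build_connectome(
    assignments: pd.DataFrame, tractogram: Tractogram, node_table: pd.DataFrame
) -> Connectome:
    """Accumulate count and mean-FA matrices from endpoint assignments."""
    if len(assignments) != len(tractogram):
        raise DataError("assignments and tractogram must have equal length")
    n = len(node_table)
    count = np.zeros((n, n))
    fa_sum = np.zeros((n, n))
    keep = ~assignments["excluded"].to_numpy(dtype=bool)
    for a, b, f in zip(
        assignments.loc[keep, "node_a"], assignments.loc[keep, "node_b"], tractogram.fa[keep]
    ):
        i, j = a - 1, b - 1
        count[i, j] += 1
        count[j, i] += 1
        fa_sum[i, j] += f
        fa_sum[j, i] += f
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(count > 0, fa_sum / np.maximum(count, 1), 0.0)
    return Connectome(count=count, fa=fa, node_table=node_table.copy())


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length step."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total == 0:
        return pts[:1]
    targets = np.arange(0.0, total, step)
    targets = np.append(targets, total)
    out = np.empty((len(targets), 3))
    for d in range(3):
        out[:, d] = np.interp(targets, arclen, pts[:, d])
    return out


def intersect_lesions(
    tractogram: Tractogram, lesion_mask: LesionMask, step: float | None = None
) -> np.ndarray:
    """Boolean per streamline: does any resampled point fall in a lesion voxel?

    Polylines are resampled at half the voxel size by default, bounding the
    geometric error of the voxel-membership test by the step length.
    """
    mask = lesion_mask.mask
    vs = lesion_mask.voxel_size
    if step is None:
        step = vs / 2.0
    shape = np.asarray(mask.shape)
    hits = np.zeros(len(tractogram), dtype=bool)
    if not mask.any():
        return hits
    for k, s in enumerate(tractogram.streamlines):
        pts = resample_polyline(np.asarray(s, dtype=float), step)
        vox = np.floor(pts / vs).astype(int)
        inb = np.all((vox >= 0) & (vox < shape), axis=1)
        if inb.any() and mask[tuple(vox[inb].T)].any():
            hits[k] = True
    return hits


def _classify(node_a: int, node_b: int, hemi: dict, supra: dict) -> str:
    ha, hb = hemi[node_a], hemi[node_b]
    if {ha, hb} == {"L", "R"}:
        return "inter"
    if ha == hb and ha in ("L", "R") and supra[node_a] and supra[node_b]:
        return "intra"
    return "other"


def disconnection_indices(
    assignments: pd.DataFrame,
    intersections: np.ndarray,
    node_table: pd.DataFrame,
    class_denominator: bool = True,
) -> DisconnectionResult:
    """Derive disconnection indices and the commissural ratio.

    Classes: *intra* = both endpoints in the same hemisphere and both nodes
    supratentorial; *inter* = endpoints in opposite hemispheres; *other* =
    everything else (midline nodes, infratentorial intra-hemispheric).

    With ``class_denominator=True`` (default) each index is the lesioned
    percentage of that class's streamlines; otherwise the denominator is all
    assigned streamlines. The source text is ambiguous on this point, so both
    conventions are available.
    """
    if len(assignments) != len(intersections):
        raise DataError("assignments and intersections must align per streamline")
    hemi = dict(zip(node_table["node_id"], node_table["hemisphere"]))
    supra = dict(zip(node_table["node_id"], node_table["supratentorial"]))

    keep = ~assignments["excluded"].to_numpy(dtype=bool)
    n = len(node_table)
    totals = np.zeros((n, n))
    lesioned_m = np.zeros((n, n))
    counts = {"intra": 0, "inter": 0, "other": 0}
    lesioned = {"intra": 0, "inter": 0, "other": 0}
    for a, b, hit in zip(
        assignments.loc[keep, "node_a"],
        assignments.loc[keep, "node_b"],
        np.asarray(intersections)[keep],
    ):
        cls = _classify(int(a), int(b), hemi, supra)
        counts[cls] += 1
        i, j = a - 1, b - 1
        totals[i, j] += 1
        totals[j, i] += 1
        if hit:
            lesioned[cls] += 1
            lesioned_m[i, j] += 1
            lesioned_m[j, i] += 1

    s_total = int(keep.sum())

    def pct(cls: str) -> float:
        denom = counts[cls] if class_denominator else s_total
        if denom == 0:
            return float("nan")
        return 100.0 * lesioned[cls] / denom

    cr = float("nan") if s_total == 0 else counts["inter"] / s_total
    with np.errstate(invalid="ignore", divide="ignore"):
        disconnectivity = np.where(totals > 0, lesioned_m / np.maximum(totals, 1), 0.0)
    return DisconnectionResult(
        s_total=s_total,
        class_counts=counts,
        class_lesioned=lesioned,
        intra_disc_pct=pct("intra"),
        inter_disc_pct=pct("inter"),
        commissural_ratio=cr,
        disconnectivity=disconnectivity,
    )
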