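"""Readers/writers for cohort tables (TSV), square matrices (TSV), voxel
grids (NIfTI), streamlines (TCK + a JSON-lines fixture dialect) and YAML
configs. Matrices round-trip at 9 significant digits."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .connectome import LesionMask, Parcellation, Tractogram
from .errors import ConfigurationError, DataError


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed table {path}: {exc}") from exc


def write_matrix(matrix: np.ndarray, path, node_ids=None) -> None:
    m = np.asarray(matrix)
    n = m.shape[0]
    ids = node_ids if node_ids is not None else range(1, n + 1)
    with open(path, "w") as fh:
        fh.write("node\t" + "\t".join(str(i) for i in ids) + "\n")
        for i, row in zip(ids, m):
            fh.write(str(i) + "\t" + "\t".join(f"{v:.9g}" for v in row) + "\n")


def read_matrix(path) -> tuple[np.ndarray, list]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "node":
            raise DataError(f"{path}: line 1: expected header starting with 'node'")
        ids = header[1:]
        n = len(ids)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n + 1:
                raise DataError(
                    f"{path}: line {lineno}: expected {n + 1} fields, got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from exc
    if len(rows) != n:
        raise DataError(f"{path}: expected {n} data rows, got {len(rows)}")
    return np.asarray(rows), ids


# --- voxel grids -----------------------------------------------------------


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def write_parcellation(parc: Parcellation, nifti_path, nodes_path) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int32), _affine(parc.voxel_size))
    nib.save(img, nifti_path)
    write_table(parc.node_table, nodes_path)


def read_parcellation(nifti_path, nodes_path) -> Parcellation:
    img = nib.load(nifti_path)
    vs = float(img.header.get_zooms()[0])
    labels = np.asarray(img.dataobj).astype(np.int32)
    node_table = read_table(nodes_path)
    return Parcellation(labels=labels, voxel_size=vs, node_table=node_table)


def write_lesion_mask(mask: LesionMask, path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.voxel_size))
    nib.save(img, path)


def read_lesion_mask(path, parcellation: Parcellation | None = None) -> LesionMask:
    img = nib.load(path)
    vs = float(img.header.get_zooms()[0])
    mask = np.asarray(img.dataobj).astype(bool)
    if parcellation is not None:
        if mask.shape != parcellation.labels.shape:
            raise DataError(
                f"lesion grid shape {mask.shape} does not match parcellation "
                f"{parcellation.labels.shape}"
            )
        if not np.allclose(img.affine, _affine(parcellation.voxel_size)):
            raise DataError("lesion affine does not match parcellation affine")
    return LesionMask(mask=mask, voxel_size=vs)


# --- streamlines -----------------------------------------------------------


def write_tck(tract: Tractogram, path) -> None:
    """TCK streamlines plus an FA sidecar (TCK has no per-streamline data)."""
    t = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in tract.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(t, str(path))
    pd.DataFrame({"fa": tract.fa}).to_csv(str(path) + ".fa.tsv", sep="\t", index=False)


def read_tck(path) -> Tractogram:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    tck = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s, dtype=float) for s in tck.streamlines]
    fa_path = Path(str(path) + ".fa.tsv")
    if fa_path.exists():
        fa = pd.read_csv(fa_path, sep="\t")["fa"].to_numpy()
    else:
        fa = np.ones(len(streamlines))
    return Tractogram(streamlines=streamlines, fa=fa)


def write_jsonl_tractogram(tract: Tractogram, path) -> None:
    with open(path, "w") as fh:
        for s, f in zip(tract.streamlines, tract.fa):
            fh.write(
                json.dumps({"fa": float(f), "points": np.asarray(s).tolist()}) + "\n"
            )


def read_jsonl_tractogram(path) -> Tractogram:
    streamlines, fa = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                streamlines.append(np.asarray(obj["points"], dtype=float))
                fa.append(float(obj["fa"]))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from exc
    return Tractogram(streamlines=streamlines, fa=np.asarray(fa))


# --- configs ---------------------------------------------------------------


def save_config(config, path) -> None:
    data = dataclasses.asdict(config)

    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    with open(path, "w") as fh:
        yaml.safe_dump(clean(data), fh, sort_keys=False)


def load_config(path, cls):
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such config file: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    # tuple-valued mapping entries arrive from YAML as lists
    for key, val in list(data.items()):
        if isinstance(val, dict):
            data[key] = {
                k: tuple(v) if isinstance(v, list) else v for k, v in val.items()
            }
        elif isinstance(val, list):
            data[key] = tuple(val)
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
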