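"""End-to-end orchestration: simulate -> (geometry) -> zscore -> compare ->
associate -> select, with a run manifest sufficient to reproduce the run."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import associations, compare, connectome, metrics, normative, selection, synthetic
from .errors import LesionnetError
from .io import save_config, write_table
from .synthetic import SimConfig


@dataclass
class PipelineConfig:
    """Analysis settings layered on top of the simulation config."""

    sim: SimConfig = field(default_factory=SimConfig)
    boot_reps: int = 500
    n_per_group: int = 80
    enet_alpha: float = 0.5
    enet_reps: int = 0  # selection-frequency bootstrap reps (0 = skip)
    enet_downsample: int = 80
    sdmt_cutoff: float = -1.5
    fdr_alpha: float = 0.05
    modularity_reps: int = 100
    geometry: bool = False
    geometry_nodes: int = 12
    geometry_streamlines: int = 200
    geometry_grid: int = 16


class PipelineError(LesionnetError):
    def __init__(self, stage: str, cause: Exception, completed: list):
        self.stage = stage
        self.completed = completed
        super().__init__(f"stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _geometry_metrics(cohort: pd.DataFrame, mtable: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Recompute graph/disconnection metric columns from simulated geometry.

    One shared parcellation; per subject a seeded tractogram and (patients
    only) a lesion mask scaled to the subject's simulated lesion volume.
    Volumetric columns are left untouched.
    """
    g = cfg.geometry_grid
    parc = synthetic.simulate_parcellation(
        n_nodes=cfg.geometry_nodes, grid_shape=(g, g, g), seed=cfg.sim.seed
    )
    out = mtable.copy()
    grid_ml = g**3 / 1000.0
    for i, row in cohort.iterrows():
        sid = row["subject_id"]
        sub_seed = cfg.sim.seed * 100003 + i
        tract = synthetic.simulate_tractogram(
            parc, cfg.geometry_streamlines, commissural_fraction=0.25, seed=sub_seed
        )
        assign = connectome.assign_endpoints(tract, parc)
        conn = connectome.build_connectome(assign, tract, parc.node_table)
        lv = float(mtable.loc[mtable["subject_id"] == sid, "lv_ml"].iloc[0])
        lesions = synthetic.simulate_lesions(
            (g, g, g), 1.0, min(lv, 0.3 * grid_ml), seed=sub_seed
        )
        hits = connectome.intersect_lesions(tract, lesions)
        disc = connectome.disconnection_indices(assign, hits, parc.node_table)
        m = metrics.metric_set(
            conn.fa, parc.node_table, commissural_ratio=disc.commissural_ratio,
            n_repetitions=cfg.modularity_reps, seed=sub_seed,
        )
        sel = out["subject_id"] == sid
        for col, val in m.items():
            out.loc[sel, col] = val
        out.loc[sel, "inter_disc_pct"] = disc.inter_disc_pct
        out.loc[sel, "intra_disc_pct"] = disc.intra_disc_pct
    return out


def _table1(cohort: pd.DataFrame) -> pd.DataFrame:
    rows = []
    pairs = [("AOMS", "HC"), ("LOMS", "HC"), ("LOMS", "AOMS")]

    def count_table(flags, g1, g2):
        a = flags[cohort["group"] == g1].astype(bool)
        b = flags[cohort["group"] == g2].astype(bool)
        return np.array([[a.sum(), (~a).sum()], [b.sum(), (~b).sum()]], dtype=int)

    for g1, g2 in pairs:
        if not ((cohort["group"] == g1).any() and (cohort["group"] == g2).any()):
            continue
        t = count_table(cohort["sex"] == "M", g1, g2)
        stat, p = compare.contingency_test(t, "chisq")
        rows.append({"variable": "sex_male", "contrast": f"{g1} vs {g2}", "test": "chisq", "p": p})
        t = count_table(cohort["education_ge13"], g1, g2)
        stat, p = compare.contingency_test(t, "chisq")
        rows.append({"variable": "education_ge13", "contrast": f"{g1} vs {g2}", "test": "chisq", "p": p})
        x = cohort.loc[cohort["group"] == g1, "age_at_mri"]
        y = cohort.loc[cohort["group"] == g2, "age_at_mri"]
        _, p = compare.mann_whitney(x, y)
        rows.append({"variable": "age_at_mri", "contrast": f"{g1} vs {g2}", "test": "mann_whitney", "p": p})

    pat = cohort[cohort["group"] != "HC"]
    if set(pat["group"].unique()) == {"AOMS", "LOMS"}:
        for var in ("disease_duration", "edss"):
            _, p = compare.mann_whitney(
                pat.loc[pat["group"] == "LOMS", var].dropna(),
                pat.loc[pat["group"] == "AOMS", var].dropna(),
            )
            rows.append({"variable": var, "contrast": "LOMS vs AOMS", "test": "mann_whitney", "p": p})
        t = np.array(
            [
                [
                    int((pat.loc[pat["group"] == g, "phenotype"] == "RRMS").sum()),
                    int((pat.loc[pat["group"] == g, "phenotype"] == "PMS").sum()),
                ]
                for g in ("AOMS", "LOMS")
            ]
        )
        if t.min() >= 0 and t.sum(axis=1).min() > 0 and t.sum(axis=0).min() > 0:
            _, p = compare.contingency_test(t, "fisher")
            rows.append({"variable": "phenotype", "contrast": "LOMS vs AOMS", "test": "fisher", "p": p})
        imp = np.array(
            [
                [
                    int(pat.loc[pat["group"] == g, "sdmt_impaired"].astype(bool).sum()),
                    int((~pat.loc[pat["group"] == g, "sdmt_impaired"].astype(bool)).sum()),
                ]
                for g in ("AOMS", "LOMS")
            ]
        )
        _, p = compare.contingency_test(imp, "chisq")
        rows.append({"variable": "sdmt_impaired", "contrast": "LOMS vs AOMS", "test": "chisq", "p": p})
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage, write report files and return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.sim.seed,
        "config": dataclasses.asdict(config),
        "stages": [],
        "files": {},
        "warnings": [],
    }
    completed: list = []
    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fn()
            manifest["warnings"].extend(f"{name}: {w.message}" for w in caught)
        except Exception as exc:
            manifest["stages"].append({"name": name, "status": "failed", "error": str(exc)})
            _write_manifest(manifest, out)
            raise PipelineError(name, exc, completed) from exc
        manifest["stages"].append(
            {"name": name, "status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
        )
        completed.append(name)

    def do_simulate():
        cohort, mtable = synthetic.simulate_study(config.sim)
        if config.geometry:
            mtable = _geometry_metrics(cohort, mtable, config)
            cohort = synthetic.assign_impairment(cohort, mtable, config.sim)
        state["cohort"], state["metrics"] = cohort, mtable
        write_table(cohort, out / "cohort.tsv")
        write_table(mtable, out / "metrics.tsv")
        save_config(config, out / "config.yaml")

    def do_table1():
        t1 = _table1(state["cohort"])
        write_table(t1, out / "table1.tsv")

    def do_zscore():
        z, models = normative.zscore_table(state["cohort"], state["metrics"])
        state["zscores"] = z
        write_table(z, out / "zscores.tsv")
        (out / "reference_models.json").write_text(
            json.dumps(
                {m: normative.serialize_model(mod) for m, mod in models.items()},
                indent=1,
            )
        )

    def do_compare():
        report = compare.group_comparison_report(
            state["cohort"], state["metrics"], state["zscores"]
        )
        write_table(report, out / "table2.tsv")

    def do_associate():
        frame = associations.association_frame(
            state["cohort"], state["metrics"], state["zscores"]
        )
        state["assoc_frame"] = frame
        report = associations.association_report(
            frame,
            n_per_group=config.n_per_group,
            reps=config.boot_reps,
            seed=config.sim.seed,
        )
        write_table(report, out / "table3.tsv")

    def do_select():
        frame = state["assoc_frame"]
        preds = [
            p for p in associations.STANDARD_PREDICTORS
            if p in frame.columns and p != "lv_ml"
        ]
        rows = []
        for g in sorted(frame["group"].unique()):
            sub = frame[frame["group"] == g].dropna(subset=preds + ["impaired"])
            res = selection.elastic_net_select(
                sub[preds], sub["impaired"], sub["center_id"],
                alpha=config.enet_alpha, seed=config.sim.seed,
            )
            freqs = None
            if config.enet_reps > 0:
                freqs = selection.selection_frequencies(
                    sub[preds], sub["impaired"], sub["center_id"],
                    n_subjects=config.enet_downsample, reps=config.enet_reps,
                    alpha=config.enet_alpha, seed=config.sim.seed,
                )
            for pred in preds:
                rows.append(
                    {
                        "group": g, "predictor": pred,
                        "beta": res.beta[pred], "or": res.or_[pred],
                        "selected": pred in res.selected,
                        "selection_pct": np.nan if freqs is None else freqs[pred],
                        "auc_insample": res.auc_insample, "auc_cv": res.auc_cv,
                        "lambda": res.lambda_chosen, "alpha": res.alpha,
                    }
                )
        write_table(pd.DataFrame(rows), out / "table4.tsv")

    stage("simulate", do_simulate)
    stage("table1", do_table1)
    stage("zscore", do_zscore)
    stage("compare", do_compare)
    stage("associate", do_associate)
    stage("select", do_select)

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
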