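"""Reproducible pipeline orchestration.

A run is described by a single YAML/JSON config with a global seed; each
stage receives a seed derived by a fixed counter scheme (seed * 1000 + stage
index, mod 2^31), so stages can be re-run in isolation.  Every stage writes
its artifact into the run directory and the manifest records the effective
parameters and a hash of config + outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import synthetic
from .model import SenescenceTrajectoryModel

__all__ = ["load_config", "stage_seed", "run_all", "DEFAULT_CONFIG"]

_STAGES = ("simulate", "quantify", "embed", "cluster", "lineage", "pstats")

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "out_dir": "senetrace_run",
    "simulate": {"enabled": True, "cells_per_time_point": 300,
                 "sigma_measurement": 0.10},
    "features_csv": None,          # used when simulate.enabled is false
    "control_day": 0,
    "subsample_n": 1200,
    "k_min": 2,
    "k_max": 20,
    "knn": 15,
    "decay": 40.0,
    "compute_embedding": True,
    "pstats_features": ["nuclear_area_px", "p53_nuc_total", "p53_nuc_mean"],
}


def load_config(path: str) -> Dict:
    """Read a YAML or JSON config and fill defaults."""
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    _validate(cfg)
    return cfg


def _validate(cfg: Dict) -> None:
    if not cfg["simulate"]["enabled"] and not cfg.get("features_csv"):
        raise ValueError("config must enable simulate or provide features_csv")
    if cfg["k_min"] < 1 or cfg["k_max"] < cfg["k_min"]:
        raise ValueError("invalid k range")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed: global * 1000 + stage index (mod 2^31)."""
    return (int(global_seed) * 1000 + _STAGES.index(stage)) % (2 ** 31)


def _log(fh, stage: str, msg: str) -> None:
    line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')} [{stage}] {msg}"
    fh.write(line + "\n")
    fh.flush()


def run_all(cfg: Dict, out_dir: Optional[str] = None) -> Path:
    """Execute the configured stages end to end; returns the run directory.

    A stage failure halts the run with the failing stage named; artifacts of
    completed stages are preserved.
    """
    _validate(cfg)
    run_dir = Path(out_dir or cfg["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    log = open(run_dir / "run.log", "a")
    seed = int(cfg["seed"])

    stage = "simulate"
    try:
        if cfg["simulate"]["enabled"]:
            _log(log, stage, "generating synthetic feature table")
            scen = synthetic.default_scenario(
                cells_per_time_point=int(cfg["simulate"]["cells_per_time_point"]),
                rng_seed=stage_seed(seed, "simulate"),
                sigma_measurement=float(cfg["simulate"]["sigma_measurement"]))
            features, truth = synthetic.sample_cells(scen)
            features.to_csv(run_dir / "features.csv", index=False)
            truth.to_csv(run_dir / "ground_truth.csv", index=False)
        else:
            _log(log, stage, f"loading features from {cfg['features_csv']}")
            features = pd.read_csv(cfg["features_csv"])

        stage = "cluster"
        _log(log, stage, "fitting trajectory model (embed+cluster+lineage)")
        model = SenescenceTrajectoryModel(features, control_day=int(cfg["control_day"]))
        res = model.fit(
            seed=stage_seed(seed, "cluster"),
            subsample_n=int(cfg["subsample_n"]),
            k_range=range(int(cfg["k_min"]), int(cfg["k_max"]) + 1),
            knn=int(cfg["knn"]),
            decay=float(cfg["decay"]),
            compute_embedding=bool(cfg["compute_embedding"]),
        )

        labels_df = pd.DataFrame({
            "cell_id": res.feature_matrix.cell_ids,
            "cluster": res.subpop_model.labels,
            "role": res.subpop_model.roles(),
        })
        labels_df.to_csv(run_dir / "labels.csv", index=False)
        res.subpop_model.score_trace.to_csv(run_dir / "k_selection.csv", index=False)
        res.composition.to_csv(run_dir / "composition.csv")

        stage = "embed"
        if res.embedding is not None:
            coords = pd.DataFrame(res.embedding.coordinates,
                                  columns=["phate1", "phate2", "phate3"])
            coords.insert(0, "cell_id",
                          res.feature_matrix.cell_ids[res.subsample_indices])
            coords.insert(1, "day",
                          res.feature_matrix.days[res.subsample_indices])
            coords.to_csv(run_dir / "embedding.csv", index=False)
            with open(run_dir / "embedding_params.json", "w") as fh:
                json.dump({"knn": res.embedding.knn, "decay": res.embedding.decay,
                           "t": res.embedding.t, "seed": res.embedding.seed}, fh)

        stage = "lineage"
        if res.lineage_set is not None:
            topo = {
                "root": int(res.lineage_set.root),
                "node_roles": res.lineage_node_roles,
                "edges": [[int(u), int(v)] for u, v in res.lineage_set.tree.edges],
                "lineages": [[int(c) for c in p] for p in res.lineage_set.lineages],
                "truncations": {str(k): v for k, v in
                                res.lineage_set.truncations.items()},
            }
            with open(run_dir / "lineages.json", "w") as fh:
                json.dump(topo, fh, indent=1)
            res.lineage_set.cell_table.to_csv(run_dir / "pseudotime.csv", index=False)

        stage = "pstats"
        if res.lineage_set is not None and len(res.lineage_set.lineages) >= 2:
            rows = []
            for feat in cfg["pstats_features"]:
                if feat not in features.columns:
                    continue
                for a in range(len(res.lineage_set.lineages)):
                    for b in range(a + 1, len(res.lineage_set.lineages)):
                        c = res.compare(feat, a, b)
                        rows.append({"feature": feat, "lineage_a": a,
                                     "lineage_b": b, "D": c.statistic,
                                     "p": c.pvalue, "log10_p": c.log10_pvalue,
                                     "stars": c.stars, "window": c.window})
            pd.DataFrame(rows).to_csv(run_dir / "comparisons.csv", index=False)

        with open(run_dir / "summary.txt", "w") as fh:
            fh.write(res.summary() + "\n")

        manifest = {
            "config": cfg,
            "stage_seeds": {s: stage_seed(seed, s) for s in _STAGES},
            "artifacts": sorted(p.name for p in run_dir.iterdir()
                                if p.name not in ("run.log", "manifest.json")),
        }
        manifest["hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True).encode()).hexdigest()
        with open(run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        _log(log, "done", f"manifest hash {manifest['hash'][:12]}")
    except Exception as exc:
        _log(log, stage, f"FAILED: {exc}")
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    finally:
        log.close()
    return run_dir
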