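"""Inference and the classifier x regressor x physics hybrid score.

The final score multiplies the interaction probability with the
docking-aware energy and adds a weighted physics docking energy:

    final = p_pred * E_dock + alpha * E_physics      (lower = better)

so a confident "non-binder" verdict from the classifier gates the
regressor toward zero, and the physics term (AutoDock-style energies
consumed from a table) anchors the prediction; alpha defaults to the
grid-searched 0.65.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import structio
from .graphs import ComplexFeaturizer, FeatureSchema
from .nets import GraphBatch, docks_inference_energy, load_model

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.65
DEFAULT_RT = 0.6  # kcal/mol (~302 K); reproduces -5 kcal/mol ~ 240 uM

SCORE_COLUMNS = ["target_id", "molecule_id", "pose_id", "p_pred", "E_dock",
                 "E_physics", "final_score", "label", "R_true"]


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class EnsembleConfig:
    alpha: float = DEFAULT_ALPHA
    dock_model: str = "dockc"              # docks | dockc
    pose_reduction: str = "best_score"     # best_score | first

    def __post_init__(self):
        if self.alpha < 0:
            raise ScoringError("alpha must be >= 0")
        if self.dock_model not in ("docks", "dockc"):
            raise ScoringError("dock_model must be docks or dockc")


def ensemble_score(p_pred, E_dock, E_physics=None,
                   alpha: float = DEFAULT_ALPHA):
    """p_pred * E_dock + alpha * E_physics (vectorized; lower = better)."""
    p = np.asarray(p_pred, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ScoringError("p_pred must lie in [0, 1]")
    e = np.asarray(E_dock, dtype=float)
    if alpha == 0.0:
        return p * e
    if E_physics is None:
        raise ScoringError("alpha > 0 requires a physics score")
    return p * e + alpha * np.asarray(E_physics, dtype=float)


def affinity_to_ic50(E: float, RT: float = DEFAULT_RT) -> float:
    """Convert a binding free energy (kcal/mol) to a concentration in uM.

    Uses dG = RT ln Kd with Kd in mol/L, so Kd = exp(E/RT); -5 kcal/mol
    at RT = 0.6 gives ~240 uM, the inactive-compound threshold.
    """
    if RT <= 0:
        raise ScoringError("RT must be positive")
    return math.exp(E / RT) * 1e6


def ic50_to_affinity(c_uM: float, RT: float = DEFAULT_RT) -> float:
    if c_uM <= 0:
        raise ScoringError("concentration must be positive")
    return RT * math.log(c_uM * 1e-6)


# ---------------------------------------------------------------------------
# physics-score tables
# ---------------------------------------------------------------------------

def read_physics_scores(path) -> Dict[tuple, float]:
    """Read a (target_id, molecule_id, pose_id) -> energy table (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str,
                                            "molecule_id": str})
    required = ["target_id", "molecule_id", "pose_id", "energy"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScoringError(f"physics table missing columns {missing}")
    bad = df[~np.isfinite(pd.to_numeric(df["energy"], errors="coerce"))]
    if len(bad):
        raise ScoringError(
            f"non-numeric energy at row(s) {bad.index.tolist()}")
    keys = list(zip(df["target_id"], df["molecule_id"],
                    df["pose_id"].astype(int)))
    dupes = df[pd.Series(keys).duplicated(keep=False).values]
    if len(dupes):
        raise ScoringError(
            "duplicate physics keys: "
            + ", ".join(map(str, sorted(set(
                zip(dupes["target_id"], dupes["molecule_id"],
                    dupes["pose_id"].astype(int)))))))
    return {k: float(e) for k, e in zip(keys, df["energy"])}


# ---------------------------------------------------------------------------
# rescoring
# ---------------------------------------------------------------------------

def score_records(records, nondock_model, dock_model,
                  physics: Optional[Dict[tuple, float]] = None,
                  cfg: EnsembleConfig = EnsembleConfig(),
                  schema: Optional[FeatureSchema] = None,
                  featurizer: Optional[ComplexFeaturizer] = None,
                  missing_physics: str = "skip",
                  batch_size: int = 64) -> pd.DataFrame:
    """Score ComplexRecords with the model pair; returns a ScoreTable.

    Per pose: p_pred (classifier), E_dock (DockC energy or DockS
    E_pred + R_pred), the joined physics energy, and the final ensemble
    score.  Poses lacking a physics row are skipped with a warning or
    raise, per `missing_physics`.
    """
    fz = featurizer or ComplexFeaturizer(schema)
    rows = []
    kept = []
    for rec in records:
        key = (rec.target_id, rec.molecule_id, rec.pose_id)
        e_phys = None if physics is None else physics.get(key)
        if physics is not None and e_phys is None:
            if missing_physics == "raise":
                raise ScoringError(f"no physics score for {key}")
            logger.warning("no physics score for %s; skipped", key)
            continue
        kept.append((rec, e_phys))
    for start in range(0, len(kept), batch_size):
        chunk = kept[start:start + batch_size]
        recs = [rec for rec, _ in chunk]
        cb = GraphBatch([fz.complex_graph(r) for r in recs])
        pb = GraphBatch([fz.nondock_graphs(r)[0] for r in recs])
        lb = GraphBatch([fz.nondock_graphs(r)[1] for r in recs])
        p = nondock_model.predict_proba(pb, lb)
        if cfg.dock_model == "docks":
            e_pred, r_pred = dock_model.predict(cb)
            e_dock = docks_inference_energy(e_pred, r_pred)
        else:
            e_dock = dock_model.predict(cb)
        for (rec, e_phys), pi, ei in zip(chunk, p, e_dock):
            final = ensemble_score(pi, ei, e_phys, cfg.alpha) \
                if (cfg.alpha > 0 and e_phys is not None) \
                else ensemble_score(pi, ei, alpha=0.0)
            rows.append({
                "target_id": rec.target_id, "molecule_id": rec.molecule_id,
                "pose_id": rec.pose_id, "p_pred": float(pi),
                "E_dock": float(ei),
                "E_physics": math.nan if e_phys is None else float(e_phys),
                "final_score": float(final),
                "label": "active" if rec.set_tag == "native" else (
                    "unknown" if rec.set_tag == "conf_decoy" else "inactive"),
                "R_true": math.nan if rec.R_true is None else rec.R_true})
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    return df.sort_values(["target_id", "molecule_id", "pose_id"],
                          kind="stable").reset_index(drop=True)


def best_poses(table: pd.DataFrame,
               cfg: EnsembleConfig = EnsembleConfig()) -> pd.DataFrame:
    """One row per (target, molecule): the best final-score pose (or the
    first pose when configured so)."""
    if cfg.pose_reduction == "first":
        idx = table.groupby(["target_id", "molecule_id"],
                            sort=False)["pose_id"].idxmin()
    else:
        idx = table.groupby(["target_id", "molecule_id"],
                            sort=False)["final_score"].idxmin()
    return table.loc[idx].reset_index(drop=True)


def rescore(manifest_path, nondock_checkpoint, dock_checkpoint,
            physics_path=None, cfg: EnsembleConfig = EnsembleConfig(),
            pocket_cutoff: float = 5.0, extract_pockets: bool = True,
            missing_physics: str = "skip") -> Tuple[pd.DataFrame, pd.DataFrame]:
    """File-level entry point: manifest + checkpoints + physics table ->
    (per-pose ScoreTable, best-pose table)."""
    nondock_model = load_model(nondock_checkpoint)
    dock_model = load_model(dock_checkpoint)
    from .nets import _BaseModel
    meta_nd = _BaseModel.checkpoint_meta(nondock_checkpoint)
    meta_dk = _BaseModel.checkpoint_meta(dock_checkpoint)
    if meta_nd["schema_version"] != meta_dk["schema_version"] or \
            meta_nd["ablated"] != meta_dk["ablated"]:
        raise ScoringError("checkpoints disagree on the feature schema")
    schema = FeatureSchema(ablated=frozenset(meta_nd["ablated"]),
                           version=meta_nd["schema_version"])
    if dock_model.arch != cfg.dock_model:
        cfg = EnsembleConfig(alpha=cfg.alpha, dock_model=dock_model.arch,
                             pose_reduction=cfg.pose_reduction)
    records = structio.load_complexes(manifest_path, pocket_cutoff,
                                      extract=extract_pockets)
    physics = read_physics_scores(physics_path) if physics_path else None
    table = score_records(records, nondock_model, dock_model, physics, cfg,
                          schema=schema, missing_physics=missing_physics)
    return table, best_poses(table, cfg)
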