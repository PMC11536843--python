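"""Desk-scale end-to-end experiments on the synthetic world.

The full pipeline — generate a world, train the three sub-networks on
the training targets, evaluate parameter recovery and screening power
on held-out targets — sized for a single CPU: small embeddings and few
epochs, with the paper-style training protocol (ratio-stratified
batches, decoy-conditional losses, batch sizes 30/36) kept intact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics, scoring, synthetic, trainer
from .autograd import default_dtype
from .graphs import ComplexFeaturizer, FeatureSchema
from .nets import NetConfig, docks_inference_energy
from .synthetic import SyntheticWorld, WorldSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeskConfig:
    """The desk-scale recipe: architecture and budget for CPU runs."""
    n_targets: int = 200
    embed_dim: int = 48
    attention_heads: int = 4
    epochs_dock: int = 12
    epochs_docks: int = 25       # the RMSD head learns a subtler signal
    epochs_nondock: int = 16
    lr: float = 1e-3
    lr_docks: float = 2e-3
    holdout_fraction: float = 0.1
    n_screen_inactives: int = 39
    alpha: float = scoring.DEFAULT_ALPHA


def split_targets(world: SyntheticWorld, fraction: float,
                  seed: int) -> tuple:
    """(train_targets, held_out_targets), deterministic in the seed."""
    ids = world.target_ids
    rng = np.random.default_rng(seed)
    n_hold = max(1, int(round(fraction * len(ids))))
    perm = rng.permutation(ids)
    return sorted(perm[n_hold:]), sorted(perm[:n_hold])


def net_config(desk: DeskConfig, seed: int) -> NetConfig:
    return NetConfig(embed_dim=desk.embed_dim,
                     attention_heads=desk.attention_heads, seed=seed)


def train_models(world: SyntheticWorld, train_targets: Sequence[str],
                 desk: DeskConfig, seed: int,
                 schema: Optional[FeatureSchema] = None,
                 archs: Sequence[str] = ("nondock", "docks", "dockc"),
                 ) -> Dict[str, object]:
    """Train the requested sub-networks on the given targets."""
    fz = ComplexFeaturizer(schema)
    train_records = [r for r in world.records if r.target_id in
                     set(train_targets)]
    models: Dict[str, object] = {}
    cfg_net = net_config(desk, seed)
    if "nondock" in archs:
        nd_records = [r for r in train_records if r.set_tag != "conf_decoy"]
        nd_samples = trainer.samples_from_records(nd_records, "nondock",
                                                  featurizer=fz)
        model = trainer.make_model("nondock", cfg_net)
        trainer.train(model, nd_samples,
                      trainer.TrainConfig(model="nondock", lr=desk.lr,
                                          epochs=desk.epochs_nondock,
                                          seed=seed))
        models["nondock"] = model
    dock_samples = None
    for arch in ("docks", "dockc"):
        if arch not in archs:
            continue
        if dock_samples is None:
            dock_samples = trainer.samples_from_records(train_records,
                                                        "complex",
                                                        featurizer=fz)
        model = trainer.make_model(arch, cfg_net)
        lr = desk.lr_docks if arch == "docks" else desk.lr
        epochs = desk.epochs_docks if arch == "docks" else desk.epochs_dock
        trainer.train(model, dock_samples,
                      trainer.TrainConfig(model=arch, lr=lr, epochs=epochs,
                                          seed=seed))
        models[arch] = model
    return models


def recovery_metrics(world: SyntheticWorld, models: Dict[str, object],
                     held_out: Sequence[str],
                     schema: Optional[FeatureSchema] = None) -> dict:
    """Parameter recovery on held-out targets: classifier AUC (natives vs
    random decoys), DockC Spearman against planted energies on natives,
    DockS RMSD-head Spearman against true RMSDs on conformational decoys."""
    fz = ComplexFeaturizer(schema)
    held = set(held_out)
    out = {}
    from .nets import GraphBatch

    def in_chunks(samples, fn, size=64):
        parts = [fn(samples[i:i + size])
                 for i in range(0, len(samples), size)]
        return np.concatenate(parts)

    if "nondock" in models:
        recs = [r for r in world.records if r.target_id in held
                and r.set_tag in ("native", "random_decoy")]
        samples = trainer.samples_from_records(recs, "nondock", featurizer=fz)
        p = in_chunks(samples, lambda ch: models["nondock"].predict_proba(
            GraphBatch([s.pocket_graph for s in ch]),
            GraphBatch([s.ligand_graph for s in ch])))
        labels = np.array([s.set_tag == "native" for s in samples])
        out["nondock_auc"] = metrics.roc_auc(p, labels, direction="descending")
    if "dockc" in models:
        recs = [world.natives[t] for t in sorted(held)]
        samples = trainer.samples_from_records(recs, "complex", featurizer=fz)
        e_pred = in_chunks(samples, lambda ch: models["dockc"].predict(
            GraphBatch([s.complex_graph for s in ch])))
        e_true = [world.truth[world.key(r)].planted_energy for r in recs]
        out["dockc_energy_spearman"] = (
            metrics.correlations(e_pred, e_true)[1] if len(recs) >= 3
            else math.nan)
    if "docks" in models:
        recs = [r for r in world.records if r.target_id in held
                and r.set_tag == "conf_decoy"]
        samples = trainer.samples_from_records(recs, "complex", featurizer=fz)
        r_pred = in_chunks(samples, lambda ch: models["docks"].predict(
            GraphBatch([s.complex_graph for s in ch]))[1])
        r_true = [s.R_true for s in samples]
        out["docks_rmsd_spearman"] = (
            metrics.correlations(r_pred, r_true)[1] if len(samples) >= 3
            else math.nan)
    return out


def screening_tables(world: SyntheticWorld, models: Dict[str, object],
                     held_out: Sequence[str], desk: DeskConfig,
                     seed: int, schema: Optional[FeatureSchema] = None,
                     n_inactives: Optional[int] = None,
                     screen_data=None) -> pd.DataFrame:
    """Score a forward-screening task on held-out targets with every
    component and the physics-hybrid ensembles; one row per molecule."""
    fz = ComplexFeaturizer(schema)
    n_inact = desk.n_screen_inactives if n_inactives is None else n_inactives
    if screen_data is None:
        screen_data = synthetic.generate_screening_set(
            world, sorted(held_out), n_inact, seed + 7919)
    records, physics = screen_data
    from .nets import GraphBatch
    rows = []
    batch = 64
    for start in range(0, len(records), batch):
        chunk = records[start:start + batch]
        cb = GraphBatch([fz.complex_graph(r) for r in chunk])
        pb = GraphBatch([fz.nondock_graphs(r)[0] for r in chunk])
        lb = GraphBatch([fz.nondock_graphs(r)[1] for r in chunk])
        p = models["nondock"].predict_proba(pb, lb) \
            if "nondock" in models else np.ones(len(chunk))
        e_c = models["dockc"].predict(cb) if "dockc" in models else None
        if "docks" in models:
            e_s_raw, r_s = models["docks"].predict(cb)
            e_s = docks_inference_energy(e_s_raw, r_s)
        else:
            e_s = None
        for i, rec in enumerate(chunk):
            key = (rec.target_id, rec.molecule_id, rec.pose_id)
            row = {"target_id": rec.target_id,
                   "molecule_id": rec.molecule_id,
                   "active": rec.set_tag == "native",
                   "p_pred": float(p[i]),
                   "E_physics": physics[key]}
            if e_c is not None:
                row["E_dockc"] = float(e_c[i])
                row["akscore_c"] = scoring.ensemble_score(
                    row["p_pred"], row["E_dockc"], row["E_physics"],
                    desk.alpha)
            if e_s is not None:
                row["E_docks"] = float(e_s[i])
                row["akscore_s"] = scoring.ensemble_score(
                    row["p_pred"], row["E_docks"], row["E_physics"],
                    desk.alpha)
            rows.append(row)
    return pd.DataFrame(rows)


SCREEN_DIRECTIONS = {"p_pred": "descending", "E_dockc": "ascending",
                     "E_docks": "ascending", "E_physics": "ascending",
                     "akscore_c": "ascending", "akscore_s": "ascending"}


def screening_efs(table: pd.DataFrame, x_percent: float = 5.0) -> dict:
    """Mean per-target EF at x% for every score column present."""
    out = {}
    for col, direction in SCREEN_DIRECTIONS.items():
        if col not in table.columns:
            continue
        efs = [metrics.enrichment_factor(grp[col].values,
                                         grp["active"].values,
                                         x_percent, direction)
               for _, grp in table.groupby("target_id")]
        out[f"ef{x_percent:g}_{col}"] = float(np.mean(efs))
    return out


@dataclass
class DeskRun:
    """Artifacts of one desk-scale experiment (for follow-up analyses)."""
    seed: int
    desk: DeskConfig
    world: SyntheticWorld
    train_targets: list
    held_out: list
    models: Dict[str, object]
    metrics: dict


def desk_experiment(seed: int, desk: DeskConfig = DeskConfig(),
                    world: Optional[SyntheticWorld] = None) -> DeskRun:
    """The full desk-scale run, keeping its artifacts.

    Runs in float32 (training at this scale is bandwidth-bound).
    """
    with default_dtype(np.float32):
        if world is None:
            world = synthetic.generate_world(
                WorldSpec(n_targets=desk.n_targets), seed)
        train_targets, held_out = split_targets(world, desk.holdout_fraction,
                                                seed)
        models = train_models(world, train_targets, desk, seed)
        out = recovery_metrics(world, models, held_out)
        table = screening_tables(world, models, held_out, desk, seed)
        out.update(screening_efs(table, 5.0))
        out["ef5_product"] = _product_ef(table)
        out["n_targets"] = desk.n_targets
        out["n_held_out"] = len(held_out)
        return DeskRun(seed=seed, desk=desk, world=world,
                       train_targets=list(train_targets),
                       held_out=list(held_out), models=models, metrics=out)


def desk_benchmark(seed: int, desk: DeskConfig = DeskConfig(),
                   world: Optional[SyntheticWorld] = None) -> dict:
    """Recovery and screening metrics of the desk-scale run."""
    return desk_experiment(seed, desk, world).metrics


def ablation_screening(run: DeskRun,
                       groups: Sequence[str] = ("pharmacophore",)
                       ) -> List[dict]:
    """Inference-time feature ablation of the run's trained models.

    Each group is zero-filled when featurizing the held-out screening
    task; the trained weights are untouched.  Returns one row per arm
    with the product-score EF@5% and the ensemble EF@5%.
    """
    desk, seed, world, held_out = run.desk, run.seed, run.world, run.held_out
    screen_data = synthetic.generate_screening_set(
        world, sorted(held_out), desk.n_screen_inactives, seed + 7919)

    def evaluate(models, schema):
        with default_dtype(np.float32):
            table = screening_tables(world, models, held_out, desk, seed,
                                     schema=schema, screen_data=screen_data)
        res = screening_efs(table, 5.0)
        return {"ef5": res.get("ef5_akscore_c", math.nan),
                "ef5_product": _product_ef(table)}

    cfg_net = net_config(desk, seed)
    return trainer.ablation_run(groups, [], evaluate, cfg_net,
                                trainer.TrainConfig(model="dockc"),
                                models=run.models)


def ablation_benchmark(seed: int, groups: Sequence[str] = ("pharmacophore",),
                       desk: Optional[DeskConfig] = None) -> List[dict]:
    """Standalone feature-ablation check: train the classifier + DockC
    pair once on a synthetic world, then compare held-out screening
    EF@5% with each feature group zeroed at inference."""
    desk = desk or DeskConfig(n_targets=60, holdout_fraction=0.15,
                              n_screen_inactives=19, epochs_dock=10,
                              epochs_nondock=12)
    run = desk_experiment(seed, desk)
    return ablation_screening(run, groups)


def _product_ef(table: pd.DataFrame, x_percent: float = 5.0) -> float:
    """EF@x% of the pure ML product score p_pred * E_dockc (alpha = 0)."""
    if "E_dockc" not in table.columns:
        return math.nan
    prod = scoring.ensemble_score(table["p_pred"].values,
                                  table["E_dockc"].values, alpha=0.0)
    efs = [metrics.enrichment_factor(
        prod[grp.index.values], grp["active"].values, x_percent, "ascending")
        for _, grp in table.groupby("target_id")]
    return float(np.mean(efs))
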