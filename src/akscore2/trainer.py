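"""Ratio-stratified training of the three sub-networks.

Every batch contains an exact per-set composition (1:4:2:2 for the
complex regressors, 1:2:2 natives:cross:random for the classifier):
samples are drawn without replacement within an epoch and smaller sets
cycle with a reshuffle when exhausted, so natives repeat while the
larger decoy sets are consumed.  Optimization is Adam; the run is
deterministic given the seed and data order.  Validation holds out a
fraction of targets (by target id, so no pose of a held-out target
leaks into training); the best-validation weights are retained.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import losses
from .autograd import Tensor, no_grad
from .graphs import ComplexFeaturizer, FeatureSchema, MolecularGraph
from .nets import (DockCModel, DockSModel, GraphBatch, NetConfig,
                   NonDockModel)
from .structio import ComplexRecord

logger = logging.getLogger(__name__)

DOCK_RATIO = {"native": 1, "conf_decoy": 4, "cross_decoy": 2,
              "random_decoy": 2}
NONDOCK_RATIO = {"native": 1, "cross_decoy": 2, "random_decoy": 2}


class ConfigurationError(ValueError):
    pass


@dataclass
class TrainConfig:
    model: str = "dockc"                     # nondock | docks | dockc
    ratio: Optional[Dict[str, int]] = None   # defaults per model
    batch_size: int = 0                      # defaults per model (30 / 36)
    lr: float = 1e-4
    epochs: int = 1000
    seed: int = 0
    val_fraction: float = 0.1
    budget_seconds: Optional[float] = None   # wall-clock cap for desk runs

    def __post_init__(self):
        if self.ratio is None:
            self.ratio = dict(NONDOCK_RATIO if self.model == "nondock"
                              else DOCK_RATIO)
        if self.batch_size == 0:
            self.batch_size = 30 if self.model == "nondock" else 36
        total = sum(self.ratio.values())
        if self.batch_size % total:
            raise ConfigurationError(
                f"batch_size {self.batch_size} not divisible by the ratio "
                f"total {total}")

    @property
    def per_batch_counts(self) -> Dict[str, int]:
        unit = self.batch_size // sum(self.ratio.values())
        return {k: unit * r for k, r in self.ratio.items()}


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

@dataclass
class TrainingSample:
    """One featurized complex plus the labels its set tag permits."""
    target_id: str
    set_tag: str
    E_true: float = math.nan
    R_true: float = math.nan
    complex_graph: Optional[MolecularGraph] = None
    pocket_graph: Optional[MolecularGraph] = None
    ligand_graph: Optional[MolecularGraph] = None
    molecule_id: str = ""
    pose_id: int = 0


def samples_from_records(records: Sequence[ComplexRecord], mode: str,
                         schema: Optional[FeatureSchema] = None,
                         featurizer: Optional[ComplexFeaturizer] = None
                         ) -> List[TrainingSample]:
    """Featurize ComplexRecords into TrainingSamples (`complex` or
    `nondock` mode); perception failures are logged and skipped."""
    fz = featurizer or ComplexFeaturizer(schema)
    out = []
    for rec in records:
        try:
            sample = TrainingSample(
                target_id=rec.target_id, set_tag=rec.set_tag,
                E_true=math.nan if rec.E_true is None else rec.E_true,
                R_true=math.nan if rec.R_true is None else rec.R_true,
                molecule_id=rec.molecule_id, pose_id=rec.pose_id)
            if mode == "complex":
                sample.complex_graph = fz.complex_graph(rec)
            elif mode == "nondock":
                sample.pocket_graph, sample.ligand_graph = \
                    fz.nondock_graphs(rec)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            out.append(sample)
        except Exception as exc:  # noqa: BLE001 - report-and-skip policy
            logger.warning("skipping %s/%s pose %s: %s", rec.target_id,
                           rec.molecule_id, rec.pose_id, exc)
    return out


# ---------------------------------------------------------------------------
# ratio-stratified batches
# ---------------------------------------------------------------------------

class _CyclingPool:
    """Without-replacement sampling that reshuffles when exhausted."""

    def __init__(self, items: list, rng: np.random.Generator):
        self.items = list(items)
        self.rng = rng
        self.queue: list = []

    def draw(self, k: int) -> list:
        out = []
        while len(out) < k:
            if not self.queue:
                self.queue = list(self.rng.permutation(len(self.items)))
            out.append(self.items[self.queue.pop()])
        return out


def ratio_batches(dataset: Sequence[TrainingSample],
                  ratio: Dict[str, int], batch_size: int,
                  seed: int) -> Iterable[List[TrainingSample]]:
    """Yield one epoch of batches with exact per-set composition.

    The epoch covers the largest set once (ceil); smaller sets cycle.
    """
    total = sum(ratio.values())
    if batch_size % total:
        raise ConfigurationError(
            f"batch_size {batch_size} not divisible by ratio total {total}")
    unit = batch_size // total
    by_set: Dict[str, list] = {k: [] for k in ratio}
    for s in dataset:
        if s.set_tag in by_set:
            by_set[s.set_tag].append(s)
    for k, members in by_set.items():
        if ratio[k] > 0 and not members:
            raise ConfigurationError(f"required set {k!r} is empty")
    rng = np.random.default_rng(seed)
    pools = {k: _CyclingPool(v, rng) for k, v in by_set.items()}
    counts = {k: unit * r for k, r in ratio.items()}
    n_batches = max(math.ceil(len(by_set[k]) / counts[k])
                    for k in ratio if counts[k] > 0)
    for _ in range(n_batches):
        batch: List[TrainingSample] = []
        for k in ratio:
            batch.extend(pools[k].draw(counts[k]))
        yield batch


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: List[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def split_by_target(samples: Sequence[TrainingSample], val_fraction: float,
                    seed: int) -> Tuple[list, list]:
    """Hold out whole targets (all their poses) for validation."""
    targets = sorted({s.target_id for s in samples})
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(val_fraction * len(targets)))) \
        if val_fraction > 0 and len(targets) > 1 else 0
    val_targets = set(rng.permutation(targets)[:n_val].tolist())
    train = [s for s in samples if s.target_id not in val_targets]
    val = [s for s in samples if s.target_id in val_targets]
    return train, val


def _batch_loss(model, cfg: TrainConfig, batch: List[TrainingSample],
                training: bool, rng) -> Tuple[Tensor, losses.LossBreakdown]:
    tags = [s.set_tag for s in batch]
    if cfg.model == "nondock":
        pb = GraphBatch([s.pocket_graph for s in batch])
        lb = GraphBatch([s.ligand_graph for s in batch])
        logits = model.forward(pb, lb, training=training, rng=rng)
        total = losses.nondock_loss(logits, tags)
        bd = losses.LossBreakdown(terms={"L_ND": float(total.data)},
                                  total=float(total.data),
                                  routing={"L_ND": list(range(len(batch)))})
        return total, bd
    cb = GraphBatch([s.complex_graph for s in batch])
    E_true = np.array([s.E_true for s in batch])
    R_true = np.array([s.R_true for s in batch])
    if cfg.model == "docks":
        E, R = model.forward(cb, training=training, rng=rng)
        return losses.routed_dock_loss("docks", tags, E, E_true, R_true,
                                       R_pred=R)
    E = model.forward(cb, training=training, rng=rng)
    return losses.routed_dock_loss("dockc", tags, E, E_true, R_true)


@dataclass
class TrainResult:
    model: object
    log: List[dict] = field(default_factory=list)
    best_val_loss: float = math.inf
    best_epoch: int = -1
    epochs_run: int = 0


def train(model, dataset: Sequence[TrainingSample], cfg: TrainConfig,
          log_path=None) -> TrainResult:
    """Optimize `model` on `dataset`; returns the best-validation weights.

    Deterministic for a fixed seed and data order.  A NaN loss aborts
    with a diagnostic of the offending batch.
    """
    train_set, val_set = split_by_target(dataset, cfg.val_fraction, cfg.seed)
    params = model.parameters()
    opt = Adam(params, lr=cfg.lr)
    drop_rng = np.random.default_rng(cfg.seed + 1)
    result = TrainResult(model=model)
    best_weights = [p.data.copy() for p in params]
    t0 = time.monotonic()
    stop = False
    for epoch in range(cfg.epochs):
        epoch_terms: Dict[str, list] = {}
        for bi, batch in enumerate(ratio_batches(train_set, cfg.ratio,
                                                 cfg.batch_size,
                                                 seed=cfg.seed + 1000 + epoch)):
            total, bd = _batch_loss(model, cfg, batch, True, drop_rng)
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} batch {bi}; "
                    f"terms={bd.terms}; samples="
                    f"{[(s.target_id, s.set_tag, s.pose_id) for s in batch]}")
            opt.zero_grad()
            total.backward()
            opt.step()
            for k, v in bd.as_record().items():
                epoch_terms.setdefault(k, []).append(v)
            if cfg.budget_seconds and time.monotonic() - t0 > cfg.budget_seconds:
                stop = True
                break
        entry = {"epoch": epoch,
                 **{k: float(np.mean(v)) for k, v in epoch_terms.items()}}
        if val_set:
            chunk_size = 4 * cfg.batch_size
            tot, n = 0.0, 0
            with no_grad():
                for ci in range(0, len(val_set), chunk_size):
                    chunk = list(val_set[ci:ci + chunk_size])
                    val_total, _ = _batch_loss(model, cfg, chunk, False, None)
                    tot += float(val_total.data) * len(chunk)
                    n += len(chunk)
            entry["val_loss"] = tot / n
            if entry["val_loss"] < result.best_val_loss:
                result.best_val_loss = entry["val_loss"]
                result.best_epoch = epoch
                best_weights = [p.data.copy() for p in params]
        result.log.append(entry)
        result.epochs_run = epoch + 1
        if stop:
            break
    if val_set:
        for p, w in zip(params, best_weights):
            p.data = w
    if log_path is not None:
        with open(log_path, "w") as fh:
            for entry in result.log:
                fh.write(json.dumps(entry) + "\n")
    return result


def make_model(arch: str, net_cfg: NetConfig):
    return {"nondock": NonDockModel, "docks": DockSModel,
            "dockc": DockCModel}[arch](net_cfg)


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

def ablation_run(feature_groups: Sequence[str],
                 train_records: Sequence[ComplexRecord],
                 evaluate, net_cfg: NetConfig, cfg_dock: TrainConfig,
                 cfg_nondock: Optional[TrainConfig] = None,
                 models: Optional[dict] = None,
                 include_baseline: bool = True):
    """Score a trained baseline under inference-time feature ablation.

    A baseline model (pair) is trained once on full features — or
    supplied via `models` — and each requested group is then zero-filled
    at evaluation time, measuring how much the trained model relies on
    it.  Zero-filling keeps tensor shapes, so the same weights apply
    across arms.  `evaluate(models: dict, schema) -> dict of metrics` is
    supplied by the caller (typically held-out forward-screening EF and
    affinity correlation); one metric row is returned per group (plus
    the baseline row when asked).
    """
    from .graphs import GROUP_ALIASES, _EDGE_SLICES, _NODE_SLICES
    valid = set(_NODE_SLICES) | set(_EDGE_SLICES) | set(GROUP_ALIASES)
    unknown = [g for g in feature_groups if g not in valid]
    if unknown:
        raise ValueError(f"unknown feature group(s) {unknown}; "
                         f"valid: {sorted(valid)}")
    if models is None:
        fz = ComplexFeaturizer(FeatureSchema())
        models = {}
        dock_samples = samples_from_records(train_records, "complex",
                                            featurizer=fz)
        dock_model = make_model(cfg_dock.model, net_cfg)
        train(dock_model, dock_samples, cfg_dock)
        models[cfg_dock.model] = dock_model
        if cfg_nondock is not None:
            nd_samples = samples_from_records(
                [r for r in train_records if r.set_tag != "conf_decoy"],
                "nondock", featurizer=fz)
            nd_model = make_model("nondock", net_cfg)
            train(nd_model, nd_samples, cfg_nondock)
            models["nondock"] = nd_model
    rows = []
    arms = ([None] if include_baseline else []) + list(feature_groups)
    for group in arms:
        schema = FeatureSchema(ablated=frozenset([group] if group else []))
        metrics = evaluate(models, schema)
        rows.append({"ablated": group or "none", **metrics})
    return rows
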