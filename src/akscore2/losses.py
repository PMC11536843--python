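"""Decoy-conditional loss terms and their set-tag routing.

The classifier is trained with binary cross-entropy (natives are
positives; cross-docked and random decoys are negatives; conformational
decoys are excluded since the classifier never sees poses).  The
regressors combine: MSE to the experimental affinity on natives, a
hinge pushing decoy affinities above -5 kcal/mol (weighted by 5 in the
total), MSE RMSD terms (DockS), and an RMSD-penalized affinity target
E_true + R_true on conformational decoys (DockC).

All functions accept autodiff Tensors (for training) or plain
numbers/arrays; each returns a scalar Tensor (use float() on it).
Batch reduction is the mean over the samples eligible for a term, so
term scales stay comparable across the 1:4:2:2 batch composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .autograd import Tensor, as_tensor

DECOY_ENERGY_THRESHOLD = -5.0  # kcal/mol; decoys must predict above this

NONDOCK_SETS = ("native", "cross_decoy", "random_decoy")
RMSD_SETS = ("native", "conf_decoy")


class RoutingError(ValueError):
    """A sample reached a loss term its set_tag does not permit."""


def _as_1d(x) -> Tensor:
    t = x if isinstance(x, Tensor) else as_tensor(np.atleast_1d(np.asarray(x, dtype=float)))
    if t.ndim == 0:
        t = t.reshape(1)
    return t


def _mse(pred: Tensor, target) -> Tensor:
    return (pred - as_tensor(target)).square().mean()


# ---------------------------------------------------------------------------
# individual terms
# ---------------------------------------------------------------------------

def nondock_loss(p_logit, set_tag) -> Tensor:
    """BCE on the interaction logit; p_true = 1 for natives, 0 for
    cross/random decoys. Conformational decoys are rejected."""
    tags = [set_tag] if isinstance(set_tag, str) else list(set_tag)
    bad = [t for t in tags if t not in NONDOCK_SETS]
    if bad:
        raise RoutingError(
            f"set tag(s) {sorted(set(bad))} not allowed in the NonDock BCE "
            f"(conformational decoys are never shown to the classifier)")
    logit = _as_1d(p_logit)
    target = np.array([1.0 if t == "native" else 0.0 for t in tags])
    if target.shape[0] != logit.shape[0]:
        raise ValueError("logit/tag length mismatch")
    # BCE on logits: softplus(z) - y*z  (numerically stable)
    return (logit.softplus() - logit * as_tensor(target)).mean()


def native_energy_loss(E_pred, E_true) -> Tensor:
    """MSE between predicted and experimental affinity (natives)."""
    return _mse(_as_1d(E_pred), np.atleast_1d(np.asarray(E_true, dtype=float)))


def cross_random_energy_loss(E_pred,
                             threshold: float = DECOY_ENERGY_THRESHOLD
                             ) -> Tensor:
    """Hinge max(-E_pred + threshold_shift, 0): zero when the decoy is
    predicted weaker than the threshold, linear below it."""
    e = _as_1d(E_pred)
    return (-e + threshold).relu().mean()


def rmsd_losses(R_pred, R_true, set_tag) -> Tensor:
    """MSE(R_pred, 0) for natives; MSE(R_pred, R_true) for
    conformational decoys. Cross/random decoys have no true pose."""
    tags = [set_tag] if isinstance(set_tag, str) else list(set_tag)
    bad = [t for t in tags if t not in RMSD_SETS]
    if bad:
        raise RoutingError(
            f"set tag(s) {sorted(set(bad))} have no true binding pose, "
            f"so no RMSD loss is defined for them")
    pred = _as_1d(R_pred)
    target = np.array([0.0 if t == "native" else r
                       for t, r in zip(tags, np.atleast_1d(
                           np.asarray(R_true, dtype=float)))])
    return _mse(pred, target)


def conf_energy_loss(E_pred, E_true, R_true) -> Tensor:
    """DockC target for conformational decoys: affinity penalized by the
    pose's deviation, E_true + R_true."""
    target = (np.atleast_1d(np.asarray(E_true, dtype=float))
              + np.atleast_1d(np.asarray(R_true, dtype=float)))
    return _mse(_as_1d(E_pred), target)


# ---------------------------------------------------------------------------
# totals
# ---------------------------------------------------------------------------

TERM_NAMES = ("L_ND", "L_native_E", "L_cross_random_E", "L_native_RMSD",
              "L_conf_RMSD", "L_conf_E")

DOCKS_WEIGHTS = {"L_native_E": 1.0, "L_cross_random_E": 5.0,
                 "L_native_RMSD": 1.0, "L_conf_RMSD": 1.0}
DOCKC_WEIGHTS = {"L_native_E": 1.0, "L_conf_E": 1.0,
                 "L_cross_random_E": 5.0}


@dataclass
class LossBreakdown:
    """Per-term values plus the routing record for one batch."""
    terms: Dict[str, float] = field(default_factory=dict)
    total: float = 0.0
    routing: Dict[str, list] = field(default_factory=dict)

    def as_record(self) -> dict:
        rec = dict(self.terms)
        rec["L_total"] = self.total
        return rec


def total_loss(terms: Dict[str, object], model: str) -> Tensor:
    """Weighted sum of the active terms.

    DockS: L_native_E + 5 L_cross_random_E + L_native_RMSD + L_conf_RMSD.
    DockC: L_native_E + L_conf_E + 5 L_cross_random_E.
    Terms absent from the batch contribute exactly zero.
    """
    weights = {"docks": DOCKS_WEIGHTS, "dockc": DOCKC_WEIGHTS}.get(model)
    if weights is None:
        raise ValueError(f"unknown model {model!r} (docks or dockc)")
    total = as_tensor(0.0)
    for name, w in weights.items():
        term = terms.get(name)
        if term is None:
            continue
        total = total + w * (term if isinstance(term, Tensor)
                             else as_tensor(float(term)))
    return total


def routed_dock_loss(model: str, set_tags: Sequence[str],
                     E_pred: Tensor, E_true: np.ndarray,
                     R_true: np.ndarray,
                     R_pred: Optional[Tensor] = None
                     ) -> "tuple[Tensor, LossBreakdown]":
    """Route a mixed batch through the set-conditional terms.

    `E_pred` (and `R_pred` for DockS) are per-sample predictions aligned
    with `set_tags`; labels may be NaN where absent.  Returns the total
    loss Tensor and a breakdown with the per-term routing record.
    """
    tags = np.asarray(set_tags)
    terms: Dict[str, Tensor] = {}
    routing: Dict[str, list] = {}

    def rows(mask):
        return np.nonzero(mask)[0]

    nat = rows(tags == "native")
    conf = rows(tags == "conf_decoy")
    neg = rows((tags == "cross_decoy") | (tags == "random_decoy"))

    if nat.size:
        terms["L_native_E"] = native_energy_loss(
            E_pred.take_rows(nat), E_true[nat])
        routing["L_native_E"] = nat.tolist()
    if neg.size:
        terms["L_cross_random_E"] = cross_random_energy_loss(
            E_pred.take_rows(neg))
        routing["L_cross_random_E"] = neg.tolist()
    if model == "docks":
        if R_pred is None:
            raise ValueError("DockS routing needs the RMSD head output")
        if nat.size:
            terms["L_native_RMSD"] = rmsd_losses(
                R_pred.take_rows(nat), np.zeros(nat.size), ["native"] * nat.size)
            routing["L_native_RMSD"] = nat.tolist()
        if conf.size:
            terms["L_conf_RMSD"] = rmsd_losses(
                R_pred.take_rows(conf), R_true[conf],
                ["conf_decoy"] * conf.size)
            routing["L_conf_RMSD"] = conf.tolist()
    elif model == "dockc":
        if conf.size:
            terms["L_conf_E"] = conf_energy_loss(
                E_pred.take_rows(conf), E_true[conf], R_true[conf])
            routing["L_conf_E"] = conf.tolist()
    else:
        raise ValueError(f"unknown model {model!r}")

    total = total_loss(terms, model)
    breakdown = LossBreakdown(
        terms={k: float(v.data) for k, v in terms.items()},
        total=float(total.data), routing=routing)
    return total, breakdown
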