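"""CASF-style screening, docking, scoring and ranking metrics.

Conventions: `direction="ascending"` means lower scores are better
(energies); `"descending"` means higher is better (probabilities).
Top-x% cutoffs use ceil(x% * n) molecules; ties are broken by stable
sort on input order (a deterministic jitter can be requested).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DIRECTIONS = ("ascending", "descending")


class MetricError(ValueError):
    pass


def _order(scores: np.ndarray, direction: str,
           jitter_seed: Optional[int] = None) -> np.ndarray:
    if direction not in DIRECTIONS:
        raise MetricError(f"direction must be one of {DIRECTIONS}")
    scores = np.asarray(scores, dtype=float)
    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        span = np.ptp(scores) or 1.0
        scores = scores + rng.uniform(-1e-9, 1e-9, size=scores.shape) * span
    keys = scores if direction == "ascending" else -scores
    return np.argsort(keys, kind="stable")


def top_k(n: int, x_percent: float) -> int:
    """Number of molecules in the top x%: ceil(x% * n), at least 1."""
    if not (0.0 < x_percent <= 100.0):
        raise MetricError("x_percent must lie in (0, 100]")
    return max(1, math.ceil(n * x_percent / 100.0))


def enrichment_factor(scores, labels, x_percent: float,
                      direction: str = "ascending",
                      jitter_seed: Optional[int] = None) -> float:
    """EF = N_hits_in_top_x% / (N_active * x%/100).

    EF = 1 is random selection; the maximum is min(100/x, n/n_active).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_active = int(labels.sum())
    if n_active == 0:
        raise MetricError("EF undefined: no active label present")
    k = top_k(len(scores), x_percent)
    order = _order(scores, direction, jitter_seed)
    n_exp = int(labels[order[:k]].sum())
    return n_exp / (n_active * x_percent / 100.0)


def forward_success_rate(per_target: Dict[str, tuple], x_percent: float,
                         direction: str = "ascending") -> float:
    """% of targets with at least one active in the top x% of their screen.

    `per_target` maps target id -> (scores, labels).
    """
    if not per_target:
        raise MetricError("no targets")
    hits = 0
    for scores, labels in per_target.values():
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels).astype(bool)
        k = top_k(len(scores), x_percent)
        order = _order(scores, direction)
        if labels[order[:k]].any():
            hits += 1
    return 100.0 * hits / len(per_target)


def reverse_success_rate(per_ligand: Sequence[tuple], x_percent: float,
                         direction: str = "ascending") -> float:
    """% of active ligands whose true target ranks in the top x% of targets.

    `per_ligand` is a sequence of (scores_over_targets, true_target_index).
    """
    if not per_ligand:
        raise MetricError("no ligands")
    hits = 0
    for scores, true_idx in per_ligand:
        scores = np.asarray(scores, dtype=float)
        k = top_k(len(scores), x_percent)
        order = _order(scores, direction)
        if true_idx in order[:k]:
            hits += 1
    return 100.0 * hits / len(per_ligand)


def docking_success(per_target: Dict[str, tuple], top_n: int = 1,
                    direction: str = "ascending",
                    rmsd_cutoff: float = 2.0) -> float:
    """% of targets whose top-n scored poses include one with RMSD < 2 A.

    `per_target` maps target id -> (scores, rmsds).  The cutoff is
    strict: exactly 2 A does not count as near-native.
    """
    if not per_target:
        raise MetricError("no targets")
    hits = 0
    for scores, rmsds in per_target.values():
        order = _order(np.asarray(scores, dtype=float), direction)
        best = np.asarray(rmsds, dtype=float)[order[:top_n]]
        if (best < rmsd_cutoff).any():
            hits += 1
    return 100.0 * hits / len(per_target)


def correlations(pred, truth) -> tuple:
    """(Pearson r, Spearman rho); NaN with a warning on degenerate input."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size < 3:
        raise MetricError("need at least 3 points for a correlation")
    if np.ptp(pred) == 0.0 or np.ptp(truth) == 0.0:
        warnings.warn("constant input: correlation undefined",
                      RuntimeWarning, stacklevel=2)
        return (math.nan, math.nan)
    r = stats.pearsonr(pred, truth).statistic
    rho = stats.spearmanr(pred, truth).statistic
    return (float(r), float(rho))


def ranking_power(df: pd.DataFrame, pred_col: str, truth_col: str,
                  cluster_col: Optional[str] = None) -> float:
    """Spearman rho, optionally averaged over per-target clusters."""
    if cluster_col is None:
        return correlations(df[pred_col], df[truth_col])[1]
    rhos = []
    for _, grp in df.groupby(cluster_col):
        if len(grp) >= 3 and np.ptp(grp[truth_col].values) > 0:
            rhos.append(stats.spearmanr(grp[pred_col],
                                        grp[truth_col]).statistic)
    return float(np.mean(rhos)) if rhos else math.nan


def hit_rate(n_active: int, n_tested: int) -> float:
    """Experimental hit rate in %, reported to one decimal."""
    if n_tested <= 0 or not (0 <= n_active <= n_tested):
        raise MetricError("need 0 <= n_active <= n_tested, n_tested > 0")
    return round(100.0 * n_active / n_tested, 1)


def roc_auc(scores, labels, direction: str = "ascending") -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC needs both classes present")
    keys = -scores if direction == "ascending" else scores
    ranks = stats.rankdata(keys)  # midranks for ties
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


@dataclass
class ScreeningResult:
    """Per-target EFs and success flags with dataset-level averages."""
    per_target_ef: Dict[str, Dict[float, float]] = field(default_factory=dict)
    thresholds: tuple = (0.5, 1.0, 5.0)
    direction: str = "ascending"

    @classmethod
    def from_tables(cls, per_target: Dict[str, tuple],
                    thresholds=(0.5, 1.0, 5.0),
                    direction: str = "ascending") -> "ScreeningResult":
        res = cls(thresholds=tuple(thresholds), direction=direction)
        for tid, (scores, labels) in per_target.items():
            res.per_target_ef[tid] = {
                x: enrichment_factor(scores, labels, x, direction)
                for x in thresholds}
        return res

    def average_ef(self, x_percent: float) -> float:
        """Mean of per-target EFs (the 'Average EF' column convention)."""
        vals = [efs[x_percent] for efs in self.per_target_ef.values()]
        if not vals:
            raise MetricError("no targets")
        return float(np.mean(vals))

    def as_frame(self) -> pd.DataFrame:
        rows = [{"target_id": t, **{f"EF{x:g}%": v for x, v in efs.items()}}
                for t, efs in self.per_target_ef.items()]
        return pd.DataFrame(rows)
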