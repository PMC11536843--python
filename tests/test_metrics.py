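"""Screening metrics against brute-force oracles and closed forms."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from akscore2 import metrics
from akscore2.metrics import (MetricError, correlations, docking_success,
                              enrichment_factor, forward_success_rate,
                              hit_rate, reverse_success_rate, roc_auc)


def brute_force_ef(scores, labels, x_percent, direction):
    """Independent oracle: explicit sort, count, normalize."""
    order = np.argsort(np.asarray(scores) if direction == "ascending"
                       else -np.asarray(scores), kind="stable")
    k = max(1, math.ceil(len(scores) * x_percent / 100.0))
    hits = int(np.asarray(labels)[order[:k]].sum())
    return hits / (int(np.sum(labels)) * x_percent / 100.0)


class TestEnrichmentFactor:
    def test_five_actives_in_top_decile(self):
        # 100 molecules, 10 actives, 5 of them in the top 10%
        scores = np.arange(100, dtype=float)
        labels = np.zeros(100, dtype=bool)
        labels[:5] = True     # in top 10 by ascending score
        labels[50:55] = True  # below the cutoff
        assert enrichment_factor(scores, labels, 10.0) == pytest.approx(5.0)

    def test_perfect_ranking_hits_ceiling(self):
        scores = np.arange(1000, dtype=float)
        labels = np.zeros(1000, dtype=bool)
        labels[:10] = True
        assert enrichment_factor(scores, labels, 1.0) == pytest.approx(100.0)

    def test_no_actives_is_undefined(self):
        with pytest.raises(MetricError):
            enrichment_factor([1.0, 2.0], [False, False], 1.0)

    def test_equals_brute_force_oracle_on_random_instances(self):
        """Exact agreement with sort-and-count on 1000 random instances."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            n = int(rng.integers(5, 500))
            scores = rng.normal(size=n)
            labels = rng.random(n) < rng.uniform(0.05, 0.5)
            if not labels.any():
                labels[int(rng.integers(n))] = True
            x = float(rng.choice([0.5, 1.0, 5.0, 10.0, 25.0]))
            direction = str(rng.choice(["ascending", "descending"]))
            assert enrichment_factor(scores, labels, x, direction) == \
                brute_force_ef(scores, labels, x, direction)

    def test_mean_ef_under_label_permutation_is_one(self):
        """Random ranking gives EF ~ 1 (within 3 standard errors)."""
        rng = np.random.default_rng(7)
        n, n_active, x = 200, 20, 10.0
        labels = np.zeros(n, dtype=bool)
        labels[:n_active] = True
        efs = []
        for _ in range(1000):
            perm = rng.permutation(labels)
            efs.append(enrichment_factor(np.arange(n, dtype=float), perm, x))
        mean = np.mean(efs)
        sem = np.std(efs) / math.sqrt(len(efs))
        assert abs(mean - 1.0) <= 3 * sem + 1e-9

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.2
        labels[0] = True
        base = enrichment_factor(scores, labels, 5.0)
        assert enrichment_factor(np.exp(scores), labels, 5.0) == base
        assert enrichment_factor(3 * scores - 7, labels, 5.0) == base


class TestSuccessRates:
    def test_forward_half_of_targets_hit(self):
        per_target = {
            "A": (np.arange(100, dtype=float),
                  np.eye(1, 100, 0, dtype=bool).ravel()),   # active ranked 1st
            "B": (np.arange(100, dtype=float),
                  np.eye(1, 100, 99, dtype=bool).ravel()),  # active ranked last
        }
        assert forward_success_rate(per_target, 1.0) == pytest.approx(50.0)
        assert forward_success_rate(per_target, 100.0) == pytest.approx(100.0)

    def test_reverse_ceiling_rule(self):
        # 57 targets, true target ranked first: ceil(0.57) = 1 -> success
        scores = np.arange(57, dtype=float)
        assert reverse_success_rate([(scores, 0)], 1.0) == pytest.approx(100.0)
        assert reverse_success_rate([(scores, 56)], 1.0) == pytest.approx(0.0)
        assert reverse_success_rate([(scores, 56)], 100.0) == pytest.approx(100.0)


class TestDockingSuccess:
    def test_strict_two_angstrom_cutoff(self):
        ok = {"T": (np.array([1.0, 2.0]), np.array([1.9, 8.0]))}
        edge = {"T": (np.array([1.0, 2.0]), np.array([2.0, 8.0]))}
        assert docking_success(ok, top_n=1) == 100.0
        assert docking_success(edge, top_n=1) == 0.0

    def test_top3_generalization(self):
        per_target = {"T": (np.array([1.0, 2.0, 3.0, 4.0]),
                            np.array([5.0, 6.0, 1.5, 0.5]))}
        assert docking_success(per_target, top_n=1) == 0.0
        assert docking_success(per_target, top_n=3) == 100.0


class TestCorrelations:
    def test_perfect_and_inverted(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert correlations(x, x) == pytest.approx((1.0, 1.0))
        r, rho = correlations(x, -x)
        assert (r, rho) == pytest.approx((-1.0, -1.0))

    def test_constant_input_warns_and_returns_nan(self):
        with pytest.warns(RuntimeWarning):
            r, rho = correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(r) and math.isnan(rho)


class TestHitRate:
    def test_experimental_campaign_rate(self):
        assert hit_rate(23, 63) == 36.5

    def test_extremes(self):
        assert hit_rate(0, 63) == 0.0
        assert hit_rate(63, 63) == 100.0

    def test_invalid_counts(self):
        with pytest.raises(MetricError):
            hit_rate(5, 0)
        with pytest.raises(MetricError):
            hit_rate(7, 3)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([-9.0, -8.0, -1.0, 0.0])
        labels = np.array([True, True, False, False])
        assert roc_auc(scores, labels, "ascending") == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc(np.ones(10), np.arange(10) < 5) == 0.5

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.3
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_matches_sklearn_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            scores = rng.integers(0, 6, size=60).astype(float)  # heavy ties
            labels = rng.random(60) < 0.4
            if labels.all() or not labels.any():
                continue
            ours = roc_auc(scores, labels, "descending")
            ref = roc_auc_score(labels, scores)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            roc_auc([1.0, 2.0], [True, True])


class TestScreeningResult:
    def test_average_ef_is_mean_of_per_target_efs(self):
        rng = np.random.default_rng(2)
        per_target = {}
        for t in "ABCD":
            scores = rng.normal(size=40)
            labels = rng.random(40) < 0.25
            labels[0] = True
            per_target[t] = (scores, labels)
        res = metrics.ScreeningResult.from_tables(per_target, (1.0, 5.0))
        expect = np.mean([enrichment_factor(s, l, 5.0)
                          for s, l in per_target.values()])
        assert res.average_ef(5.0) == pytest.approx(expect)
        frame = res.as_frame()
        assert len(frame) == 4 and "EF5%" in frame.columns


class TestRankingPower:
    def test_per_cluster_average(self):
        import pandas as pd
        df = pd.DataFrame({
            "target": ["A"] * 4 + ["B"] * 4,
            "pred": [1.0, 2, 3, 4, 4, 3, 2, 1],
            "truth": [1.0, 2, 3, 4, 1, 2, 3, 4]})
        # cluster A perfectly ordered, B inverted -> mean rho = 0
        rho = metrics.ranking_power(df, "pred", "truth", cluster_col="target")
        assert rho == pytest.approx(0.0, abs=1e-12)
        # global spearman without clusters
        g = metrics.ranking_power(df, "pred", "truth")
        assert -1.0 <= g <= 1.0
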