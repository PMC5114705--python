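"""Screening, collinearity filtering, AICc bookkeeping and CV-AUC."""

import itertools
import math

import numpy as np
import pytest

import nicheshift as ns
from nicheshift.maxent_core import FeatureConfig
from nicheshift.model_selection import (
    ModelScore,
    SelectionConfig,
    aicc,
    auc_mann_whitney,
    collinearity_filter,
    cv_auc,
    jackknife_screen,
    rank_models,
    score_subsets,
)

LIGHT = SelectionConfig(feature_config=FeatureConfig(("linear", "quadratic")))


def _score(variables, aicc_value, valid=True):
    return ModelScore(
        variables=tuple(variables), log_likelihood=0.0, k=1, n=100,
        aicc=aicc_value, valid=valid,
    )


class TestRanking:
    def test_delta_from_published_pairs(self):
        # two independently published AICc pairs reproduce their printed deltas
        scores = rank_models([_score("a", 3420.533), _score("b", 3423.026)])
        assert scores[1].delta_aicc == pytest.approx(2.493, abs=1e-9)
        scores = rank_models([_score("a", 2719.672), _score("b", 2720.673)])
        assert scores[1].delta_aicc == pytest.approx(1.001, abs=1e-9)

    def test_closed_form_weights(self):
        scores = rank_models([_score("a", 100.0), _score("b", 102.0), _score("c", 104.0)])
        w = [s.weight for s in scores]
        assert w == pytest.approx([0.6652, 0.2447, 0.0900], abs=5e-5)

    def test_single_model_and_equal_pair(self):
        (only,) = rank_models([_score("a", 10.0)])
        assert only.delta_aicc == 0.0 and only.weight == 1.0
        pair = rank_models([_score("a", 5.0), _score("b", 5.0)])
        assert [s.weight for s in pair] == pytest.approx([0.5, 0.5])

    def test_weights_sum_to_one_random_sets(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(2, 12)
            scores = [_score(f"v{i}", float(rng.uniform(100, 200))) for i in range(n)]
            ranked = rank_models(scores)
            assert sum(s.weight for s in ranked) == pytest.approx(1.0, abs=1e-12)
            # brute-force sort oracle
            assert [s.aicc for s in ranked] == sorted(s.aicc for s in scores)

    def test_all_invalid_raises(self):
        with pytest.raises(ValueError):
            rank_models([_score("a", math.inf, valid=False)])


class TestAICc:
    def test_approaches_aic_for_large_n(self):
        k, ll = 5, -120.0
        aic = 2 * k - 2 * ll
        assert abs(aicc(ll, k, 10**7) - aic) < 1e-4
        assert aicc(ll, k, 50) > aic

    def test_small_sample_guard(self):
        assert aicc(-10.0, k=10, n=11) == math.inf


class TestAUC:
    def test_exhaustive_pair_counting(self):
        pos = np.array([0.9, 0.8, 0.4])
        neg = np.array([0.7, 0.5, 0.3])
        # brute force over all 9 pairs: 3 + 3 + 1 wins
        wins = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p, n in itertools.product(pos, neg)
        )
        assert wins == 7.0
        assert auc_mann_whitney(pos, neg) == pytest.approx(7 / 9)

    def test_perfect_separation(self):
        assert auc_mann_whitney([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_label_free_scores_near_half(self):
        rng = np.random.default_rng(2024)
        scores = rng.uniform(size=4000)
        assert 0.45 < auc_mann_whitney(scores[:2000], scores[2000:]) < 0.55

    def test_ties_count_half(self):
        assert auc_mann_whitney([0.5], [0.5]) == 0.5

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        pos, neg = rng.uniform(size=50), rng.uniform(size=80)
        base = auc_mann_whitney(pos, neg)
        assert auc_mann_whitney(np.exp(5 * pos), np.exp(5 * neg)) == pytest.approx(base)
        assert auc_mann_whitney(np.log(pos), np.log(neg)) == pytest.approx(base)

    def test_random_instances_match_pair_counting(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            pos = rng.choice(np.linspace(0, 1, 11), size=rng.integers(2, 8))
            neg = rng.choice(np.linspace(0, 1, 11), size=rng.integers(2, 8))
            brute = np.mean(
                [1.0 if p > n else 0.5 if p == n else 0.0
                 for p, n in itertools.product(pos, neg)]
            )
            assert auc_mann_whitney(pos, neg) == pytest.approx(brute)


class TestCollinearity:
    def test_duplicate_dropped_and_strict_threshold(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=500)
        env = np.column_stack([a, a.copy(), rng.normal(size=500)])
        kept = collinearity_filter(env, ["A", "B", "C"], 0.8, {"A": 2.0, "B": 1.0, "C": 0.5})
        assert kept == ["A", "C"]  # duplicate pair loses its lower-gain member

    def test_just_below_threshold_kept(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=20000)
        target = 0.79
        b = target * a + math.sqrt(1 - target**2) * rng.normal(size=20000)
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 0.8
        kept = collinearity_filter(np.column_stack([a, b]), ["A", "B"], 0.8, {})
        assert kept == ["A", "B"]

    def test_constant_dropped(self):
        env = np.column_stack([np.ones(50), np.arange(50.0)])
        assert collinearity_filter(env, ["K", "X"], 0.8, {}) == ["X"]

    def test_matches_greedy_oracle_on_known_matrix(self):
        # 4 variables with a planted correlation structure
        rng = np.random.default_rng(7)
        z = rng.normal(size=(20000, 2))
        a = z[:, 0]
        b = 0.95 * z[:, 0] + math.sqrt(1 - 0.95**2) * rng.normal(size=20000)
        c = z[:, 1]
        d = 0.9 * z[:, 1] + math.sqrt(1 - 0.9**2) * rng.normal(size=20000)
        env = np.column_stack([a, b, c, d])
        names = ["A", "B", "C", "D"]
        gains = {"A": 3.0, "B": 1.0, "C": 0.5, "D": 2.0}

        # independent greedy oracle
        def oracle(env, names, gains, thr=0.8):
            keep = list(names)
            while True:
                idx = [names.index(v) for v in keep]
                r = np.corrcoef(env[:, idx], rowvar=False)
                np.fill_diagonal(r, 0)
                pairs = [
                    (abs(r[i, j]), tuple(sorted((keep[i], keep[j]))))
                    for i in range(len(keep)) for j in range(i + 1, len(keep))
                    if abs(r[i, j]) > thr
                ]
                if not pairs:
                    return keep
                pairs.sort(key=lambda t: (-t[0], t[1]))
                x, y = pairs[0][1]
                keep.remove(x if gains[x] < gains[y] else y)

        assert collinearity_filter(env, names, 0.8, gains) == oracle(env, names, gains)


class TestScreenAndSubsets:
    def test_true_driver_has_highest_isolation_gain(self, recovery_bundle):
        occ = ns.thin_to_grid(recovery_bundle.presences, recovery_bundle.config.grid, seed=1)
        report = jackknife_screen(
            recovery_bundle.current, occ, LIGHT,
            candidates=["BIO1", "NOISE1", "NOISE2"],
        )
        t = report.table.set_index("variable")
        assert t["gain_isolation"].idxmax() == "BIO1"
        # pure-noise variable barely moves the full-model gain
        assert abs(t.loc["NOISE1", "gain_drop"]) < 0.05

    def test_single_candidate_skips_screening(self, recovery_bundle):
        occ = ns.thin_to_grid(recovery_bundle.presences, recovery_bundle.config.grid, seed=1)
        report = jackknife_screen(recovery_bundle.current, occ, LIGHT, candidates=["BIO1"])
        assert report.retained == ["BIO1"]
        assert "skipped" in report.note

    def test_score_subsets_enumerates_and_ranks(self, recovery_bundle):
        occ = ns.thin_to_grid(recovery_bundle.presences, recovery_bundle.config.grid, seed=1)
        scores = score_subsets(["BIO1", "NOISE1"], occ, recovery_bundle.current, LIGHT)
        assert len(scores) == 3  # {BIO1}, {NOISE1}, {BIO1,NOISE1}
        assert scores[0].delta_aicc == 0.0
        assert sum(s.weight for s in scores if s.valid) == pytest.approx(1.0, abs=1e-9)
        assert "BIO1" in scores[0].variables

    def test_cv_auc_on_informative_model(self, recovery_bundle):
        occ = ns.thin_to_grid(recovery_bundle.presences, recovery_bundle.config.grid, seed=1)
        mean, sd = cv_auc(["BIO1", "BIO12"], occ, recovery_bundle.current,
                          folds=5, seed=3, config=LIGHT)
        assert mean > 0.8
        assert sd < 0.1
        # deterministic for identical seed
        again = cv_auc(["BIO1", "BIO12"], occ, recovery_bundle.current,
                       folds=5, seed=3, config=LIGHT)
        assert (mean, sd) == again

    def test_too_few_presences_for_folds(self, recovery_bundle):
        occ = ns.thin_to_grid(recovery_bundle.presences, recovery_bundle.config.grid, seed=1)
        small = ns.OccurrenceSet(occ.species, occ.records.head(5), 5, 5)
        with pytest.raises(ValueError, match="folds"):
            cv_auc(["BIO1"], small, recovery_bundle.current, folds=10, config=LIGHT)
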