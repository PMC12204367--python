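import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abrkit import (AugmentConfig, EarlyStopSpec, EarlyStopper, SplitSpec,
                    augment, augment_dataset, compare_proportions,
                    evaluate_classifier, evaluate_peaks,
                    fit_with_early_stopping, source_balanced_weights,
                    split_by_subject, within_k_db)


class _Item:
    def __init__(self, subject, source="lab"):
        self.subject_id = subject
        self.source_label = source


def _items(n, source="lab", per_subject=3):
    return [_Item(f"{source}-s{i}", source)
            for i in range(n) for _ in range(per_subject)]


class TestSplitBySubject:
    def test_ten_subjects_split_6_2_2(self):
        train, val, test = split_by_subject(_items(10), SplitSpec(seed=1))
        subs = lambda part: {i.subject_id for i in part}
        assert (len(subs(train)), len(subs(val)), len(subs(test))) == (6, 2, 2)

    def test_no_subject_spans_partitions_and_split_is_exhaustive(self):
        items = _items(13)
        parts = split_by_subject(items, SplitSpec(seed=3))
        seen = [i.subject_id for p in parts for i in p]
        assert len(seen) == len(items)
        sets = [{i.subject_id for i in p} for p in parts]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])

    def test_per_source_splits_are_independent(self):
        items = _items(10, "A") + _items(5, "B")
        train, val, test = split_by_subject(items, SplitSpec(seed=0))
        for src, n_total, n_test in (("A", 10, 2), ("B", 5, 1)):
            test_subs = {i.subject_id for i in test if i.source_label == src}
            assert len(test_subs) == n_test

    def test_same_seed_reproduces_split(self):
        items = _items(20)
        a = split_by_subject(items, SplitSpec(seed=7))
        b = split_by_subject(items, SplitSpec(seed=7))
        for pa, pb in zip(a, b):
            assert [i.subject_id for i in pa] == [i.subject_id for i in pb]

    def test_tiny_source_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_by_subject(_items(2), SplitSpec())


class TestSourceBalancedWeights:
    def test_stated_formula_on_100_vs_300(self):
        labels = ["A"] * 100 + ["B"] * 300
        w = source_balanced_weights(labels)
        np.testing.assert_allclose(w[:100], 2.0)
        np.testing.assert_allclose(w[100:], 2 / 3)
        assert w[:100].sum() == pytest.approx(200)
        assert w[100:].sum() == pytest.approx(200)

    def test_single_source_and_equal_sources_give_unit_weights(self):
        np.testing.assert_allclose(source_balanced_weights(["A"] * 7), 1.0)
        np.testing.assert_allclose(
            source_balanced_weights(["A"] * 5 + ["B"] * 5), 1.0)

    @given(sizes=st.lists(st.integers(1, 400), min_size=1, max_size=6))
    @settings(max_examples=30, deadline=None)
    def test_per_source_sums_equal(self, sizes):
        labels = [f"src{i}" for i, n in enumerate(sizes) for _ in range(n)]
        w = source_balanced_weights(labels)
        sums = [w[np.asarray(labels) == f"src{i}"].sum()
                for i in range(len(sizes))]
        np.testing.assert_allclose(sums, sums[0], atol=1e-12)
        assert w.sum() == pytest.approx(len(labels), abs=1e-9)


class TestAugment:
    def test_doubling_contract(self, rng):
        X = rng.normal(size=(40, 244))
        Xd, yd, wd = augment_dataset(X, np.arange(40), np.ones(40), rng=1)
        assert Xd.shape == (80, 244)
        np.testing.assert_array_equal(yd[:40], yd[40:])

    def test_zero_magnitudes_give_exact_copies(self, rng):
        X = rng.normal(size=(30, 100))
        cfg = AugmentConfig(noise_sd=0.0, elastic_jitter_samples=0.0,
                            shift_max_samples=0)
        np.testing.assert_allclose(augment(X, cfg, rng=2), X, atol=1e-9)

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(25, 100))
        np.testing.assert_array_equal(augment(X, rng=5), augment(X, rng=5))

    def test_augmented_rows_differ_from_originals(self, rng):
        X = rng.normal(size=(30, 100))
        Xa = augment(X, rng=3)
        assert not np.allclose(Xa, X)


class _ScriptedModel:
    """Replays a fixed validation-loss sequence; epoch index is the state."""

    def __init__(self, val_losses):
        self.val_losses = val_losses
        self.epoch = 0

    def train_epoch(self, train):
        self.epoch += 1
        return 1.0

    def val_loss(self, val):
        return self.val_losses[self.epoch - 1]

    def snapshot(self):
        return self.epoch

    def restore(self, state):
        self.restored_epoch = state


class TestEarlyStopping:
    def test_thirty_improvements_then_flat_stops_at_55(self):
        losses = [1.0 - 0.01 * e for e in range(30)] + [0.71] * 100
        model = _ScriptedModel(losses)
        _, hist = fit_with_early_stopping(model, None, None,
                                          EarlyStopSpec(patience=25,
                                                        max_epochs=200))
        assert hist.stopped_epoch == 55
        assert hist.best_epoch == 30
        assert model.restored_epoch == 30

    def test_always_improving_runs_to_max_epochs(self):
        model = _ScriptedModel([1.0 / (e + 1) for e in range(50)])
        _, hist = fit_with_early_stopping(model, None, None,
                                          EarlyStopSpec(patience=25,
                                                        max_epochs=50))
        assert hist.stopped_epoch == 50 and hist.best_epoch == 50

    def test_patience_one_textbook_sequence(self):
        model = _ScriptedModel([1.0, 0.9, 0.95])
        _, hist = fit_with_early_stopping(model, None, None,
                                          EarlyStopSpec(patience=1,
                                                        max_epochs=10))
        assert hist.stopped_epoch == 3 and hist.best_epoch == 2

    def test_plateau_at_equal_loss_is_not_improvement(self):
        stop = EarlyStopper(patience=2)
        assert stop.update(1.0) and not stop.update(1.0)
        stop.update(1.0)
        assert stop.should_stop and stop.best_epoch == 1

    def test_non_finite_loss_aborts(self):
        model = _ScriptedModel([1.0, float("nan")])
        with pytest.raises(RuntimeError, match="non-finite"):
            fit_with_early_stopping(model, None, None,
                                    EarlyStopSpec(patience=5, max_epochs=10))

    def test_invalid_patience_rejected(self):
        with pytest.raises(ValueError):
            EarlyStopSpec(patience=0)


def auc_concordance(labels, scores):
    """Pairwise concordance with half credit for ties (independent oracle)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestEvaluateClassifier:
    def test_perfect_separation(self):
        r = evaluate_classifier([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], n_boot=0)
        assert r.aucroc == 1.0 and r.aucpr == 1.0 and r.accuracy == 1.0
        assert r.tnr == pytest.approx(1 - r.fpr)

    def test_textbook_concordance_example(self):
        r = evaluate_classifier([0.9, 0.8, 0.4, 0.1], [1, 0, 1, 0], n_boot=0)
        assert r.aucroc == pytest.approx(0.75, abs=1e-12)

    def test_matches_concordance_oracle_on_random_instances(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            r = evaluate_classifier(scores, labels, n_boot=0)
            assert r.aucroc == pytest.approx(
                auc_concordance(labels, scores), abs=1e-12)

    def test_all_tied_scores_give_half(self):
        r = evaluate_classifier([0.5] * 10, [1, 0] * 5, n_boot=0)
        assert r.aucroc == pytest.approx(0.5)

    def test_single_class_has_undefined_aucs(self):
        r = evaluate_classifier([0.9, 0.8], [1, 1], n_boot=0)
        assert r.aucroc is None and r.aucpr is None

    def test_bootstrap_cis_bracket_point_estimates(self, rng):
        n = 200
        labels = rng.integers(0, 2, n)
        scores = np.clip(labels * 0.6 + rng.random(n) * 0.4, 0, 1)
        r = evaluate_classifier(scores, labels, n_boot=200, seed=1)
        for k in ("accuracy", "aucroc"):
            lo, hi = r.ci[k]
            assert lo <= getattr(r, k) <= hi


class TestEvaluatePeaks:
    def test_identical_predictions_have_zero_error(self):
        r = evaluate_peaks([1.0, 2.0], [1.0, 2.0], n_boot=0)
        assert r.rmse == 0 and r.mae == 0 and r.mean_error == 0

    def test_symmetric_errors(self):
        r = evaluate_peaks([1.1, 1.9], [1.0, 2.0], n_boot=0)
        assert r.mae == pytest.approx(0.1)
        assert r.mean_error == pytest.approx(0.0)
        assert r.rmse == pytest.approx(0.1)

    def test_matches_direct_formulas(self, rng):
        pred, truth = rng.normal(size=50), rng.normal(size=50)
        r = evaluate_peaks(pred, truth, n_boot=0)
        e = pred - truth
        assert r.rmse == pytest.approx(np.sqrt(np.mean(e ** 2)), abs=1e-12)
        assert r.mae == pytest.approx(np.mean(np.abs(e)), abs=1e-12)
        assert r.sem == pytest.approx(np.std(e, ddof=1) / np.sqrt(50), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_peaks([1.0], [1.0, 2.0])


class TestWithinKdb:
    def test_identical_vectors_hit_for_all_k(self):
        assert within_k_db([30.0, 40.0], [30.0, 40.0], 5) == 1.0
        assert within_k_db([30.0, 40.0], [30.0, 40.0], 0) == 1.0

    def test_graded_differences(self):
        pred = [30.0, 35.0, 40.0, 50.0]
        true = [30.0, 30.0, 30.0, 30.0]
        assert within_k_db(pred, true, 5) == 0.5
        assert within_k_db(pred, true, 100) == 1.0

    def test_no_response_pairs(self):
        assert within_k_db([None, None], [None, 30.0], 10) == 0.5
        assert within_k_db([None], [None], 10) == 1.0


class TestCompareProportions:
    def test_identical_proportions(self):
        r = compare_proportions(80, 100, 80, 100)
        assert r.difference == 0 and r.p_value == 1.0

    def test_z_matches_pooled_textbook_formula(self):
        r = compare_proportions(90, 100, 80, 100)
        p = (90 + 80) / 200
        z_hand = (0.9 - 0.8) / math.sqrt(p * (1 - p) * (1 / 100 + 1 / 100))
        assert r.z == pytest.approx(z_hand, abs=1e-10)
        assert r.ci[0] < 0.1 < r.ci[1]

    def test_bonferroni_multiplies_and_caps(self):
        base = compare_proportions(55, 100, 45, 100)
        adj = compare_proportions(55, 100, 45, 100, bonferroni_m=6)
        assert adj.p_value == pytest.approx(min(1.0, base.p_value * 6))
        capped = compare_proportions(50, 100, 50, 100, bonferroni_m=6)
        assert capped.p_value == 1.0

    def test_degenerate_all_hits(self):
        r = compare_proportions(10, 10, 10, 10)
        assert r.p_value == 1.0 and r.ci == (0.0, 0.0)
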