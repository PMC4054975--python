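"""Cross-validation schemes, majority-vote fusion, chance level, and the
behavioral statistic."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cogload as cl
from cogload.evaluation import _fb_fold_features

from conftest import make_epochs


def _fold_specs():
    return {
        "general": cl.SchemeSpec("general", seed=1),
        "within": cl.SchemeSpec("within", train_context="relax", seed=1),
        "across": cl.SchemeSpec("across", train_context="relax", seed=1),
        "combined": cl.SchemeSpec("combined", test_context="relax", seed=1),
        "halves_within": cl.SchemeSpec("halves_within", seed=1),
        "halves_across": cl.SchemeSpec("halves_across", seed=1),
    }


class TestMakeFolds:
    def test_general_fold_sizes(self, default_epochs):
        folds = cl.make_folds(default_epochs, _fold_specs()["general"])
        assert len(folds) == 6
        for fold in folds:
            assert len(fold.train_blocks) == 20 and len(fold.test_blocks) == 4
            assert fold.train_index.size == 900 and fold.test_index.size == 180
            # workload and context balanced in the test set
            test = default_epochs.select(fold.test_index)
            for context in ("relax", "stress"):
                for level in ("low", "high"):
                    assert np.sum((test.context == context)
                                  & (test.workload == level)) == 45

    def test_general_partitions_blocks(self, default_epochs):
        folds = cl.make_folds(default_epochs, _fold_specs()["general"])
        seen = [b for fold in folds for b in fold.test_blocks]
        assert sorted(seen) == sorted(np.unique(default_epochs.block))
        for fold in folds:
            assert not set(fold.train_blocks) & set(fold.test_blocks)

    def test_within_fold_sizes(self, default_epochs):
        folds = cl.make_folds(default_epochs, _fold_specs()["within"])
        assert len(folds) == 6
        for fold in folds:
            assert fold.train_index.size == 450 and fold.test_index.size == 90
            blocks = np.concatenate([fold.train_blocks, fold.test_blocks])
            assert np.all(np.isin(default_epochs.context[
                np.isin(default_epochs.block, blocks)], "relax"))

    def test_across_trains_and_tests_in_different_contexts(self, default_epochs):
        folds = cl.make_folds(default_epochs, _fold_specs()["across"])
        assert len(folds) == 6
        for fold in folds:
            train = default_epochs.select(fold.train_index)
            test = default_epochs.select(fold.test_index)
            assert set(train.context) == {"relax"}
            assert set(test.context) == {"stress"}
            assert fold.train_index.size == 450 and fold.test_index.size == 90

    def test_combined_matches_within_training_size(self, default_epochs):
        folds = cl.make_folds(default_epochs, _fold_specs()["combined"])
        assert len(folds) == 6
        for fold in folds:
            assert abs(fold.train_index.size - 450) <= 2
            train = default_epochs.select(fold.train_index)
            # both contexts contribute equally; classes near-balanced
            assert np.sum(train.context == "relax") == np.sum(train.context == "stress")
            n_low = np.sum(train.workload == "low")
            n_high = np.sum(train.workload == "high")
            assert abs(n_low - n_high) <= 2
            test = default_epochs.select(fold.test_index)
            assert set(test.context) == {"relax"}
            assert not set(fold.test_blocks) & set(fold.train_blocks)

    def test_halves_fold_sizes(self, default_epochs):
        for name in ("halves_within", "halves_across"):
            folds = cl.make_folds(default_epochs, _fold_specs()[name])
            assert len(folds) == 12  # 2 contexts x 2 halves x 3 folds
            for fold in folds:
                assert fold.train_index.size == 180  # 4 blocks
                assert fold.test_index.size == 90    # 2 blocks
                train = default_epochs.select(fold.train_index)
                test = default_epochs.select(fold.test_index)
                assert len(set(train.context)) == 1
                assert set(test.context) == set(train.context)
                if name == "halves_within":
                    assert set(test.half) == set(train.half)
                    assert not set(fold.train_blocks) & set(fold.test_blocks)
                else:
                    assert set(test.half) != set(train.half)

    def test_missing_blocks_fall_back_with_warning(self, small_config):
        rec = cl.generate_session(small_config)
        epochs = cl.discard_targets(cl.segment_epochs(rec))
        with pytest.warns(UserWarning, match="fold"):
            folds = cl.make_folds(epochs, _fold_specs()["within"])
        assert len(folds) == 1

    def test_deterministic_under_seed(self, default_epochs):
        a = cl.make_folds(default_epochs, _fold_specs()["combined"])
        b = cl.make_folds(default_epochs, _fold_specs()["combined"])
        for fa, fb in zip(a, b):
            assert fa.train_blocks == fb.train_blocks
            assert np.array_equal(fa.train_index, fb.train_index)


class TestRunScheme:
    def test_training_ignores_test_labels(self, default_epochs, fb_cache):
        """Permuting the test-fold workload labels must leave the fitted
        selection and features bit-identical (no leakage)."""
        spec = cl.SchemeSpec("within", train_context="relax", seed=2)
        fold = cl.make_folds(default_epochs, spec)[0]
        train_a, _, models_a, sel_a = _fb_fold_features(
            fb_cache, fold.train_index, fold.test_index, 18)
        permuted = default_epochs.select(np.arange(default_epochs.n_trials))
        rng = np.random.default_rng(0)
        permuted.workload = permuted.workload.copy()
        permuted.workload[fold.test_index] = rng.permutation(
            permuted.workload[fold.test_index])
        cache_b = cl.FeatureCache.build(permuted, variety="fb")
        train_b, _, models_b, sel_b = _fb_fold_features(
            cache_b, fold.train_index, fold.test_index, 18)
        assert np.array_equal(sel_a.selected_indices, sel_b.selected_indices)
        assert np.array_equal(train_a.values, train_b.values)
        for band in models_a:
            assert np.array_equal(models_a[band].filters, models_b[band].filters)

    def test_block_fusion_beats_trial_accuracy(self, default_epochs, fb_cache):
        """Majority voting over a block's 45 trials amplifies a better-than-
        chance trial accuracy."""
        result = cl.run_scheme(default_epochs,
                               cl.SchemeSpec("general", seed=3), cache=fb_cache)
        assert result.mean_accuracy > 0.5
        truth = {int(b): default_epochs.workload[default_epochs.block == b][0]
                 for b in np.unique(default_epochs.block)}
        fused_acc = np.mean([lab == truth[b]
                             for b, lab in result.per_block_fused_label.items()])
        assert len(result.per_block_fused_label) == 24
        assert fused_acc >= result.mean_accuracy

    def test_low_band_restriction_loses_little(self, default_epochs):
        """With the planted low-band effects, restricting the bank to
        delta/theta/alpha costs < 5 accuracy points versus the full bank."""
        full = cl.run_scheme(default_epochs, cl.SchemeSpec("general", seed=4))
        low_bands = tuple(b for b in cl.default_filter_bank()
                          if b.name in ("delta", "theta", "alpha"))
        low = cl.run_scheme(default_epochs,
                            cl.SchemeSpec("general", seed=4, bands=low_bands))
        assert full.mean_accuracy - low.mean_accuracy < 0.05


class TestMajorityVote:
    def test_unanimous_and_simple_majority(self):
        assert cl.majority_vote(np.array(["high"] * 45)) == "high"
        labels = np.array(["high"] * 23 + ["low"] * 22)
        assert cl.majority_vote(labels) == "high"

    def test_even_tie_uses_mean_score(self):
        labels = np.array(["high", "low"])
        assert cl.majority_vote(labels, np.array([2.0, -1.0])) == "high"
        assert cl.majority_vote(labels, np.array([0.5, -1.0])) == "low"

    def test_tie_without_scores_uses_documented_rule(self):
        assert cl.majority_vote(np.array(["high", "low"])) == "high"

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            cl.majority_vote(np.array([]))


class TestChanceLevel:
    def test_printed_reference_values(self):
        assert cl.chance_level(1080, 0.05) == 53.1
        assert round(cl.chance_level(24, 0.05)) == 71

    def test_large_n_limit_and_monotonicity(self):
        values = [cl.chance_level(n) for n in (24, 90, 1080, 10 ** 6, 10 ** 8)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert values[-1] == 50.0

    def test_exact_binomial_variant_close_to_normal(self):
        assert abs(cl.chance_level(1080, method="binomial")
                   - cl.chance_level(1080)) < 0.5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            cl.chance_level(100, alpha=0.0)
        with pytest.raises(ValueError, match="n_trials"):
            cl.chance_level(0)
        with pytest.raises(cl.ConfigError, match="method"):
            cl.chance_level(100, method="bootstrap")


class TestNbackPerformance:
    def test_perfect_block(self):
        assert cl.nback_performance(cl.BehavioralCounts(45, 15, 0, 0)) == 1.0

    def test_mixed_block(self):
        assert cl.nback_performance(cl.BehavioralCounts(40, 50, 5, 5)) == 0.9

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            cl.nback_performance(cl.BehavioralCounts(0, 0, 0, 0))
        with pytest.raises(ValueError, match="non-negative"):
            cl.BehavioralCounts(-1, 0, 0, 0)


class TestStudyRunner:
    def test_tidy_table_schema(self, default_epochs):
        specs = [cl.SchemeSpec("within", train_context=c, seed=5)
                 for c in ("relax", "stress")]
        table = cl.evaluate_study([default_epochs], specs)
        assert set(table.columns) >= {"subject", "scheme", "variety", "fold",
                                      "accuracy", "n_train", "n_test"}
        assert len(table) == 12
        assert table.accuracy.between(0, 1).all()
        assert (table.n_train == 450).all() and (table.n_test == 90).all()


class TestChanceLevelProperties:

    @given(n=st.integers(1, 10 ** 6), alpha=st.floats(0.001, 0.4))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_threshold_is_achievable_and_above_half(self, n, alpha):
        value = cl.chance_level(n, alpha)
        assert 50.0 <= value <= 100.0
        k = round(value * n / 100.0)  # the underlying correct count
        assert k >= n / 2.0

    @given(n_high=st.integers(0, 45), n_low=st.integers(0, 45))
    @settings(deadline=None, derandomize=True)
    def test_majority_vote_matches_count_comparison(self, n_high, n_low):
        if n_high + n_low == 0:
            return
        labels = np.array(["high"] * n_high + ["low"] * n_low)
        result = cl.majority_vote(labels, scores=np.ones(n_high + n_low))
        if n_high > n_low:
            assert result == "high"
        elif n_low > n_high:
            assert result == "low"
        else:
            assert result == "high"  # positive mean score resolves the tie
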