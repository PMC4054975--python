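"""mRMR selection, feature-variety assembly, and shrinkage LDA."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import mutual_info_score

import cogload as cl
from cogload.model import (
    discretize_equal_frequency,
    mutual_information,
    mrmr_select,
)


def _feature_matrix(values, workload):
    n, p = values.shape
    return cl.FeatureMatrix(
        values=values,
        provenance=[{"branch": "fb", "band": "alpha", "filter": j} for j in range(p)],
        workload=np.asarray(workload),
        context=np.array(["relax"] * n),
        block=np.zeros(n, dtype=int),
        half=np.ones(n, dtype=int),
    )


def _mrmr_oracle(values, workload, k, n_bins=8):
    """Independent greedy mRMR using sklearn's mutual_info_score."""
    n, p = values.shape
    y = (np.asarray(workload) == "low").astype(int)
    codes = [discretize_equal_frequency(values[:, j], n_bins) for j in range(p)]
    rel = [mutual_info_score(codes[j], y) for j in range(p)]
    picked: list[int] = []
    for _ in range(k):
        best, best_score = None, -np.inf
        for j in range(p):
            if j in picked:
                continue
            red = np.mean([mutual_info_score(codes[j], codes[s]) for s in picked]) if picked else 0.0
            score = rel[j] - red
            if score > best_score + 1e-15:
                best, best_score = j, score
        picked.append(best)
    return picked


class TestMutualInformation:
    def test_matches_sklearn_contingency_estimator(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.integers(0, 8, size=200)
            b = rng.integers(0, 4, size=200)
            assert abs(mutual_information(a, b) - mutual_info_score(a, b)) < 1e-12

    def test_constant_feature_has_zero_relevance(self):
        y = np.array([0, 1] * 50)
        assert mutual_information(np.zeros(100, dtype=int), y) == 0.0


class TestMrmr:
    def test_copy_of_informative_feature_is_penalized(self):
        """Toy {X informative, copy of X, noise A, noise B}: the second pick
        must be a noise column, not the redundant copy."""
        rng = np.random.default_rng(1)
        n = 400
        workload = np.array(["low", "high"] * (n // 2))
        x = (workload == "high") + 0.1 * rng.standard_normal(n)
        values = np.column_stack([x, x.copy(),
                                  rng.standard_normal(n), rng.standard_normal(n)])
        sel = mrmr_select(_feature_matrix(values, workload), k=2)
        assert sel.selected_indices[0] == 0
        assert sel.selected_indices[1] in (2, 3)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        n, p = 300, 7
        workload = np.array(["low", "high"] * (n // 2))
        signal = (workload == "high").astype(float)
        values = rng.standard_normal((n, p))
        values[:, 1] += 1.5 * signal
        values[:, 4] += 1.0 * signal
        values[:, 6] = values[:, 1] + 0.05 * rng.standard_normal(n)
        sel = mrmr_select(_feature_matrix(values, workload), k=5)
        assert list(sel.selected_indices) == _mrmr_oracle(values, workload, 5)

    def test_first_pick_maximizes_relevance(self):
        rng = np.random.default_rng(3)
        n, p = 200, 9
        workload = np.array(["low", "high"] * (n // 2))
        values = rng.standard_normal((n, p))
        values[:, 5] += 2.0 * (workload == "high")
        sel = mrmr_select(_feature_matrix(values, workload), k=3)
        y = (workload == "low").astype(int)
        rel = [mutual_info_score(discretize_equal_frequency(values[:, j], 8), y)
               for j in range(p)]
        assert sel.selected_indices[0] == int(np.argmax(rel))

    def test_k_equals_all_columns_gives_full_ordering(self):
        rng = np.random.default_rng(4)
        values = rng.standard_normal((100, 5))
        workload = np.array(["low", "high"] * 50)
        sel = mrmr_select(_feature_matrix(values, workload), k=5)
        assert sorted(sel.selected_indices) == [0, 1, 2, 3, 4]

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(5)
        fm = _feature_matrix(rng.standard_normal((40, 3)), ["low", "high"] * 20)
        with pytest.raises(ValueError, match="k=4"):
            mrmr_select(fm, k=4)

    def test_constant_feature_is_harmless(self):
        rng = np.random.default_rng(6)
        values = rng.standard_normal((60, 4))
        values[:, 2] = 7.0  # constant
        workload = np.array(["low", "high"] * 30)
        sel = mrmr_select(_feature_matrix(values, workload), k=4)
        assert len(sel.selected_indices) == 4


class TestAssembleVariety:
    def _pair(self, n=10):
        rng = np.random.default_rng(7)
        workload = np.array(["low", "high"] * (n // 2))
        fb = _feature_matrix(rng.standard_normal((n, 18)), workload)
        erp = cl.FeatureMatrix(
            values=rng.standard_normal((n, 18)),
            provenance=[{"branch": "erp", "filter": 0, "sample": j} for j in range(18)],
            workload=workload, context=np.array(["relax"] * n),
            block=np.zeros(n, dtype=int), half=np.ones(n, dtype=int),
        )
        return fb, erp

    def test_both_concatenates_fb_first(self):
        fb, erp = self._pair()
        out = cl.assemble_variety(fb, erp, "both")
        assert out.n_features == 36
        assert [p["branch"] for p in out.provenance] == ["fb"] * 18 + ["erp"] * 18
        assert np.array_equal(out.values[:, :18], fb.values)

    def test_single_variety_passthrough(self):
        fb, erp = self._pair()
        assert cl.assemble_variety(fb, None, "fb") is fb
        assert cl.assemble_variety(None, erp, "erp") is erp

    def test_trial_mismatch_rejected(self):
        fb, _ = self._pair(10)
        _, erp = self._pair(10)
        erp = erp.select_trials(np.arange(8))
        with pytest.raises(ValueError, match="mismatch"):
            cl.assemble_variety(fb, erp, "both")


class TestShrinkageLda:
    def _gaussian_pair(self, rng, n_per_class, d, separation):
        mean = np.zeros(d)
        mean_high = np.full(d, separation / np.sqrt(d))
        x = np.vstack([
            rng.standard_normal((n_per_class, d)) + mean,
            rng.standard_normal((n_per_class, d)) + mean_high,
        ])
        workload = np.array(["low"] * n_per_class + ["high"] * n_per_class)
        return _feature_matrix(x, workload)

    def test_separable_clouds_classified_perfectly(self):
        rng = np.random.default_rng(8)
        fm = self._gaussian_pair(rng, 50, 4, separation=30.0)
        model = cl.train_lda(fm)
        labels, _ = cl.predict(model, fm)
        assert np.all(labels == fm.workload)

    def test_gamma_one_gives_mean_difference_weights(self):
        rng = np.random.default_rng(9)
        fm = self._gaussian_pair(rng, 40, 5, separation=3.0)
        model = cl.train_lda(fm, gamma=1.0)
        mu_low = fm.values[fm.workload == "low"].mean(axis=0)
        mu_high = fm.values[fm.workload == "high"].mean(axis=0)
        diff = mu_high - mu_low
        # identity-covariance limit: weights proportional to the mean difference
        scale = model.weights @ diff / (diff @ diff)
        assert np.allclose(model.weights, scale * diff, atol=1e-10)

    def test_matches_sklearn_lda_direction(self):
        """Unshrunk (gamma=0) weights are parallel to sklearn's lsqr LDA
        coefficient vector."""
        rng = np.random.default_rng(10)
        fm = self._gaussian_pair(rng, 500, 6, separation=2.0)
        model = cl.train_lda(fm, gamma=0.0)
        ref = LinearDiscriminantAnalysis(solver="lsqr", priors=[0.5, 0.5])
        ref.fit(fm.values, fm.workload == "high")
        cos = (model.weights @ ref.coef_[0]) / (
            np.linalg.norm(model.weights) * np.linalg.norm(ref.coef_[0]))
        assert np.arccos(np.clip(cos, -1, 1)) < 1e-6

    def test_shrinkage_intensity_grows_in_small_samples(self):
        """On data with a fixed anisotropic covariance, the Ledoit-Wolf
        intensity approaches 1 when trials barely exceed the dimension and
        0 as trials grow."""
        rng = np.random.default_rng(11)
        d = 12
        scale = np.linspace(0.2, 3.0, d)  # markedly non-spherical

        def fm(n_per_class):
            x = rng.standard_normal((2 * n_per_class, d)) * scale
            x[n_per_class:] += 1.0
            workload = np.array(["low"] * n_per_class + ["high"] * n_per_class)
            return _feature_matrix(x, workload)

        small = cl.train_lda(fm(8))
        large = cl.train_lda(fm(5000))
        assert small.gamma > 0.3
        assert large.gamma < 0.05
        assert small.gamma > large.gamma

    def test_single_class_rejected(self):
        rng = np.random.default_rng(12)
        fm = _feature_matrix(rng.standard_normal((10, 3)), ["low"] * 10)
        with pytest.raises(ValueError, match="class"):
            cl.train_lda(fm)


class TestPredict:
    def _model(self, weights, bias=0.0):
        return cl.LdaModel(weights=np.asarray(weights, dtype=float),
                           bias=bias, gamma=0.0)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(13)
        fm = _feature_matrix(rng.standard_normal((20, 3)), ["low", "high"] * 10)
        model = self._model([1.0, -2.0, 0.5], bias=0.3)
        flipped = self._model([-1.0, 2.0, -0.5], bias=-0.3)
        la, sa = cl.predict(model, fm)
        lb, sb = cl.predict(flipped, fm)
        assert np.allclose(sa, -sb)
        off_boundary = sa != 0
        assert np.all(la[off_boundary] != lb[off_boundary])

    def test_boundary_tie_goes_to_second_class(self):
        fm = _feature_matrix(np.zeros((1, 2)), ["low"])
        labels, scores = cl.predict(self._model([1.0, 1.0]), fm)
        assert scores[0] == 0.0
        assert labels[0] == "high"  # documented tie rule: class_order[1]

    def test_dimension_mismatch_rejected(self):
        fm = _feature_matrix(np.zeros((2, 3)), ["low", "high"])
        with pytest.raises(ValueError, match="dimension"):
            cl.predict(self._model([1.0, 1.0]), fm)
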