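"""Linear-SVM classification, dimensional scores, behavior correlations."""
import numpy as np
import pandas as pd
import pytest

from modconn.mvpa import (behavior_block_correlations, classifier_weights,
                          correlate_dimensional_scores, fit_classifier_cv)


def _features(rng, n_per_group=12, n_features=10, shift=0.0):
    X = rng.standard_normal((2 * n_per_group, n_features))
    X[:n_per_group, 0] += shift
    idx = [f"sub-{k:02d}" for k in range(2 * n_per_group)]
    features = pd.DataFrame(X, index=idx)
    features.columns = [f"f{j}" for j in range(n_features)]
    labels = pd.Series([1] * n_per_group + [2] * n_per_group, index=idx)
    return features, labels


class TestFitClassifierCv:
    def test_separable_groups_perfect_accuracy(self, rng):
        X, y = _features(rng, n_features=4, shift=10.0)
        res = fit_classifier_cv(X, y, seed=0)
        assert res.cv_accuracy == 1.0
        # dimensional score sign determines the predicted group
        full_pred = np.where(res.dimensional_scores > 0, 2, 1)
        assert (full_pred == y.to_numpy()).all()

    def test_group_score_means_have_opposite_signs(self, rng):
        X, y = _features(rng, shift=3.0)
        res = fit_classifier_cv(X, y, seed=0)
        m1 = res.dimensional_scores[y == 1].mean()
        m2 = res.dimensional_scores[y == 2].mean()
        assert m1 * m2 < 0

    def test_folds_partition_subjects(self, rng):
        X, y = _features(rng, shift=1.0)
        res = fit_classifier_cv(X, y, n_folds=4, seed=3)
        folds = pd.Series(res.folds)
        assert sorted(folds.index) == sorted(X.index)
        assert set(folds) == {0, 1, 2, 3}
        # stratified: 3 per group per fold for 12 + 12
        counts = folds.groupby([folds, y.reindex(folds.index)]).size()
        assert set(counts) == {3}

    def test_permutation_null_accuracy_near_chance(self, rng):
        X, y = _features(rng, shift=2.0)
        accs = []
        for p in range(60):
            perm = rng.permutation(y.to_numpy())
            accs.append(fit_classifier_cv(
                X, pd.Series(perm, index=y.index), seed=p).cv_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_duplicate_feature_keeps_accuracy_splits_weight(self, rng):
        X, y = _features(rng, shift=2.5)
        res1 = fit_classifier_cv(X, y, seed=1)
        X2 = X.copy()
        X2["f0_dup"] = X["f0"]
        res2 = fit_classifier_cv(X2, y, seed=1)
        assert res2.cv_accuracy == pytest.approx(res1.cv_accuracy, abs=0.1)
        # the feature's weight mass splits equally across the duplicates,
        # keeping the original sign
        assert res2.weights["f0"] == pytest.approx(res2.weights["f0_dup"],
                                                   rel=1e-6)
        assert np.sign(res2.weights["f0"]) == np.sign(res1.weights["f0"])

    def test_accuracy_invariant_to_feature_affine_and_order(self, rng):
        X, y = _features(rng, shift=2.0)
        base = fit_classifier_cv(X, y, seed=5).cv_accuracy
        scaled = X.copy()
        scaled["f0"] = 10.0 * scaled["f0"] - 3.0  # standardization absorbs it
        assert fit_classifier_cv(scaled, y, seed=5).cv_accuracy == base
        permuted = X[list(X.columns[::-1])]
        assert fit_classifier_cv(permuted, y, seed=5).cv_accuracy == base

    def test_deterministic_given_seed(self, rng):
        X, y = _features(rng, shift=1.0)
        a = fit_classifier_cv(X, y, seed=7)
        b = fit_classifier_cv(X, y, seed=7)
        assert a.cv_accuracy == b.cv_accuracy
        pd.testing.assert_series_equal(a.dimensional_scores,
                                       b.dimensional_scores)

    def test_too_few_subjects_per_group_raises(self, rng):
        X, y = _features(rng, n_per_group=3)
        with pytest.raises(ValueError, match="per group"):
            fit_classifier_cv(X, y, n_folds=4)

    def test_missing_features_raise(self, rng):
        X, y = _features(rng)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_classifier_cv(X, y)


class TestClassifierWeights:
    def test_informative_feature_ranks_first(self, rng):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            X, y = _features(r, shift=3.0)
            res = fit_classifier_cv(X, y, seed=seed)
            if classifier_weights(res, top_k=1).index[0] == "f0":
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_full_ranking_when_topk_is_nfeatures(self, rng):
        X, y = _features(rng, shift=1.0)
        res = fit_classifier_cv(X, y, seed=0)
        ranked = classifier_weights(res, top_k=X.shape[1])
        assert set(ranked.index) == set(X.columns)
        assert (ranked.abs().diff().dropna() <= 1e-12).all()

    def test_nonlinear_kernel_weights_undefined(self, rng):
        X, y = _features(rng, shift=2.0)
        res = fit_classifier_cv(X, y, seed=0, kernel="rbf")
        with pytest.raises(ValueError, match="nonlinear"):
            classifier_weights(res)


class TestScoreCorrelation:
    def test_proportional_scores_r_one(self):
        a = pd.Series([1.0, -2.0, 0.5, 3.0], index=list("wxyz"))
        r, p = correlate_dimensional_scores(a, 2.0 * a)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_hand_computed_pair(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        b = pd.Series([2.0, 1.0, 4.0, 3.0, 6.0])
        ac, bc = a - a.mean(), b - b.mean()
        r_hand = (ac * bc).sum() / np.sqrt((ac ** 2).sum() * (bc ** 2).sum())
        r, _ = correlate_dimensional_scores(a, b)
        assert r == pytest.approx(r_hand, abs=1e-12)

    def test_independent_noise_small_on_average(self):
        rs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = pd.Series(rng.standard_normal(24))
            b = pd.Series(rng.standard_normal(24))
            rs.append(correlate_dimensional_scores(a, b)[0])
        assert abs(np.mean(rs)) < 0.1

    def test_zero_variance_raises(self):
        a = pd.Series([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="zero-variance"):
            correlate_dimensional_scores(a, pd.Series([1.0, 2.0, 3.0]))


class TestBehaviorBlockCorrelations:
    def _coords(self, rng, n=24, blocks=5):
        idx = [f"sub-{k:02d}" for k in range(n)]
        return pd.DataFrame(rng.standard_normal((n, blocks)), index=idx,
                            columns=[f"b{j}" for j in range(blocks)])

    def test_coupled_block_flagged(self, rng):
        coords = self._coords(rng)
        behavior = pd.DataFrame(
            {"rvip": coords["b2"] + 0.3 * rng.standard_normal(24)})
        table = behavior_block_correlations(coords, behavior)
        row = table.set_index("block").loc["b2"]
        assert row["selected"] and abs(row["r"]) > 0.5

    def test_threshold_above_one_flags_nothing(self, rng):
        coords = self._coords(rng)
        behavior = pd.DataFrame({"m": coords["b0"]})
        table = behavior_block_correlations(coords, behavior,
                                            r_threshold=1.01)
        assert not table["selected"].any()

    def test_missing_values_excluded_pairwise(self, rng, caplog):
        coords = self._coords(rng)
        b = coords["b1"].copy()
        b.iloc[:3] = np.nan
        with caplog.at_level("INFO"):
            table = behavior_block_correlations(coords,
                                                pd.DataFrame({"m": b}))
        assert any("missing" in rec.message for rec in caplog.records)
        row = table.set_index("block").loc["b1"]
        assert row["r"] == pytest.approx(1.0)

    def test_constant_measure_raises(self, rng):
        coords = self._coords(rng)
        with pytest.raises(ValueError, match="constant"):
            behavior_block_correlations(
                coords, pd.DataFrame({"m": np.ones(24)},
                                     index=coords.index))


def test_mvpa_result_json_roundtrip(tmp_path, rng):
    X, y = _features(rng, shift=2.0)
    res = fit_classifier_cv(X, y, seed=0)
    path = tmp_path / "mvpa.json"
    res.to_json(path)
    import json

    payload = json.loads(path.read_text())
    assert payload["cv_accuracy"] == res.cv_accuracy
    assert len(payload["weights"]) == X.shape[1]
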