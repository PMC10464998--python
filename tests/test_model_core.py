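import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from protacable.embedding import embed_dataset
from protacable.model_core import (CurveSet, EnsembleModel, HyperParams,
                                   average_precision, calibrate_threshold,
                                   consensus_predict, fpr_threshold_curve,
                                   grid_search, repeated_stratified_cv,
                                   roc_auc, scan_proteome,
                                   sensitivity_at_threshold, soft_vote)
from protacable.seq_io import Dataset, ProteinRecord
from protacable.synthetic import make_synthetic_embedder, simulate_dataset


@pytest.fixture(scope="module")
def planted_xy(small_config_module):
    ds, _ = simulate_dataset(small_config_module)
    X = embed_dataset(make_synthetic_embedder(small_config_module), ds)
    return X, ds.labels()


@pytest.fixture(scope="module")
def small_config_module():
    from protacable.synthetic import SimulationConfig
    return SimulationConfig(n_positive=30, n_negative=35,
                            length_range=(80, 140), embed_dim=32,
                            signal_dims=(1, 2, 3, 4), seed=7)


class TestMetrics:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert average_precision([0.9, 0.8, 0.2], [1, 1, 0]) == 1.0

    def test_hand_computed_auc(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == pytest.approx(0.5)

    def test_hand_computed_ap(self):
        assert average_precision([0.9, 0.1], [0, 1]) == pytest.approx(0.5)

    def test_single_positive_sample(self):
        assert average_precision([0.3], [1]) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            average_precision([0.1, 0.2], [0, 0])

    def test_brute_force_oracles_100_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(4, 31))
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 1, 0
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            assert roc_auc(scores, labels) == pytest.approx(
                oracles.roc_auc_naive(scores, labels), abs=1e-12)
            assert average_precision(scores, labels) == pytest.approx(
                oracles.average_precision_naive(list(scores), list(labels)),
                abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(0.01, 0.99), min_size=4, max_size=20))
    def test_ap_invariant_under_monotone_transform(self, raw):
        scores = np.array(raw)
        labels = (np.arange(len(scores)) % 2).astype(int)
        base = average_precision(scores, labels)
        assert average_precision(3 * scores + 1, labels) == pytest.approx(base)
        assert average_precision(np.exp(scores), labels) == pytest.approx(base)


class TestFprThresholdCurve:
    def test_extremes(self):
        c = fpr_threshold_curve([0.9, 0.4, 0.2], [1, 0, 0])
        assert c.fpr_at(0.95) == 0.0     # above max score
        assert c.fpr_at(0.1) == 1.0      # below min score
        assert np.all(np.diff(c.fpr) >= 0)   # monotone along descending t

    def test_one_of_241_negatives(self):
        # one negative above the cutoff among 241 negatives
        scores = np.concatenate([[0.95, 0.9], np.linspace(0.0, 0.5, 240)])
        labels = np.concatenate([[1, 0], np.zeros(240, dtype=int)])
        c = fpr_threshold_curve(scores, labels)
        assert round(c.fpr_at(0.85), 3) == 0.004

    def test_needs_negatives(self):
        with pytest.raises(ValueError):
            fpr_threshold_curve([0.1, 0.9], [1, 1])


class TestCalibrateThreshold:
    def test_zero_fpr_everywhere_returns_zero(self):
        c = fpr_threshold_curve([0.9, 0.1], [1, 0])
        # single negative scores 0.1; fpr is 0 for t > 0.1 but 1 at/below;
        # use a curve with fpr 0 everywhere on the grid via high positive only
        c = CurveSet(np.array([0.9]), np.array([1.0]), np.array([0.0]),
                     np.array([1.0]), np.array([1.0]))
        assert calibrate_threshold([c], 0.05) == 0.0

    def test_target_one_returns_zero(self):
        c = fpr_threshold_curve([0.9, 0.1], [1, 0])
        assert calibrate_threshold([c], 1.0) == 0.0

    def test_two_fold_average_hand_computed(self):
        f1 = fpr_threshold_curve([0.9, 0.6, 0.2], [1, 0, 0])
        f2 = fpr_threshold_curve([0.9, 0.8, 0.4], [1, 0, 0])
        # averaged step FPR drops to 0.25 first at grid t = 0.61
        assert calibrate_threshold([f1, f2], 0.3) == pytest.approx(0.61)

    def test_unattainable_warns_and_returns_one(self):
        c = CurveSet(np.array([1.0]), np.array([1.0]), np.array([0.5]),
                     np.array([0.5]), np.array([1.0]))
        with pytest.warns(UserWarning, match="unattainable"):
            assert calibrate_threshold([c], 0.01) == 1.0

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            calibrate_threshold([], 0.0)


class TestGridSearch:
    def test_single_point_identity(self, planted_xy):
        X, y = planted_xy
        grid = {"n_estimators": [50], "max_depth": [5],
                "min_samples_split": [2], "min_samples_leaf": [1]}
        params = grid_search(X, y, "rf", grid=grid, seed=0)
        assert params == HyperParams("rf", 50, 5, 2, 1)

    def test_more_trees_win_on_noisy_signal(self, planted_xy):
        X, y = planted_xy
        grid = {"n_estimators": [5, 200], "max_depth": [None],
                "min_samples_split": [2], "min_samples_leaf": [1]}
        assert grid_search(X, y, "rf", grid=grid, seed=0).n_estimators == 200

    def test_tie_broken_by_fewer_trees(self):
        # perfectly separable 1-D data: every grid point reaches AUC 1.0
        X = np.r_[np.zeros((10, 1)), np.ones((10, 1))]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        grid = {"n_estimators": [10, 100], "max_depth": [3],
                "min_samples_split": [2], "min_samples_leaf": [1]}
        assert grid_search(X, y, "rf", grid=grid, seed=0).n_estimators == 10

    def test_empty_grid_and_small_class(self, planted_xy):
        X, y = planted_xy
        with pytest.raises(ValueError):
            grid_search(X, y, "rf", grid={"n_estimators": []})
        with pytest.raises(ValueError, match="at least"):
            grid_search(X[:6], np.array([1, 0, 0, 0, 0, 0]), "rf",
                        grid={"n_estimators": [10]})


@pytest.fixture(scope="module")
def report(planted_xy):
    return repeated_stratified_cv(
        planted_xy[0], planted_xy[1], HyperParams("rf", n_estimators=50),
        seed=7)


class TestRepeatedStratifiedCV:
    def test_ten_fold_models_at_defaults(self, report):
        assert len(report.fold_models) == 10

    def test_stratification_within_one_sample(self, planted_xy, report):
        _, y = planted_xy
        for va in report.fold_val_indices[:5]:
            pos_frac = y[va].mean()
            assert abs(pos_frac * len(va) - y.mean() * len(va)) <= 1.0

    def test_partition_property_per_repeat(self, planted_xy, report):
        X, y = planted_xy
        first_repeat = np.concatenate(report.fold_val_indices[:5])
        assert sorted(first_repeat) == list(range(len(y)))
        second_repeat = np.concatenate(report.fold_val_indices[5:])
        assert sorted(second_repeat) == list(range(len(y)))

    def test_same_seed_reproduces_everything(self, planted_xy, report):
        X, y = planted_xy
        again = repeated_stratified_cv(
            X, y, HyperParams("rf", n_estimators=50), seed=7)
        np.testing.assert_array_equal(report.fold_roc_auc, again.fold_roc_auc)
        for a, b in zip(report.fold_val_indices, again.fold_val_indices):
            np.testing.assert_array_equal(a, b)

    def test_exact_stratification_balanced_100(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        rep = repeated_stratified_cv(X, y, HyperParams("rf", n_estimators=10),
                                     repeats=1, seed=1)
        # 100 samples over 5 folds: 20 validation samples, 10 per class
        for va in rep.fold_val_indices:
            assert len(va) == 20 and y[va].sum() == 10


class TestEnsembles:
    def _members(self, planted_xy, n=2):
        X, y = planted_xy
        rep = repeated_stratified_cv(X, y, HyperParams("rf", n_estimators=20),
                                     repeats=1, seed=3)
        return rep.fold_models[:n], X

    def test_soft_vote_is_mean(self, planted_xy):
        members, X = self._members(planted_xy)
        ens = EnsembleModel(members, mode="soft")
        x = X[0]
        expected = np.mean([m.predict_proba(x.reshape(1, -1))[0]
                            for m in members])
        assert soft_vote(ens, x) == pytest.approx(expected)

    def test_soft_vote_single_member_identity(self, planted_xy):
        members, X = self._members(planted_xy, n=1)
        ens = EnsembleModel(members, mode="soft")
        assert soft_vote(ens, X[0]) == pytest.approx(
            members[0].predict_proba(X[:1])[0])

    def test_consensus_requires_all_members(self, planted_xy):
        members, X = self._members(planted_xy)
        ens = EnsembleModel(members, mode="consensus")
        probs = ens.member_probabilities(X[:1])[:, 0]
        t_all = probs.min()          # both members agree at their minimum
        assert consensus_predict(ens, X[0], t_all) == "positive"
        t_above = probs.min() + 1e-9
        if probs.max() < t_above:
            assert consensus_predict(ens, X[0], t_above) == "negative"

    def test_consensus_monotone_in_threshold(self, planted_xy):
        members, X = self._members(planted_xy)
        ens = EnsembleModel(members, mode="consensus")
        for x in X[:5]:
            if consensus_predict(ens, x, 0.95) == "positive":
                assert consensus_predict(ens, x, 0.5) == "positive"

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            EnsembleModel([], mode="soft")

    def test_save_load_roundtrip(self, planted_xy, tmp_path):
        members, X = self._members(planted_xy)
        ens = EnsembleModel(members, mode="soft", threshold=0.8)
        ens.save(tmp_path / "bundle")
        back = EnsembleModel.load(tmp_path / "bundle")
        assert back.threshold == 0.8 and back.mode == "soft"
        np.testing.assert_allclose(back.predict_proba(X[:5]),
                                   ens.predict_proba(X[:5]), atol=1e-12)


class TestScanProteome:
    def _scored_setup(self, planted_xy):
        X, y = planted_xy
        rep = repeated_stratified_cv(X, y, HyperParams("rf", n_estimators=20),
                                     repeats=1, seed=3)
        return rep.to_ensemble(), X

    def test_threshold_inclusive_hits(self, planted_xy):
        ens, X = self._scored_setup(planted_xy)
        ds = Dataset([ProteinRecord(f"q{i}", "A") for i in range(len(X))])
        df, hits = scan_proteome(ens, ds, X, threshold=0.5)
        assert set(hits) == set(df[df.score >= 0.5]["id"])
        scores = df.set_index("id")["score"]
        assert all(scores[a] >= scores[b] for a, b in zip(hits, hits[1:]))

    def test_empty_dataset(self, planted_xy):
        ens, X = self._scored_setup(planted_xy)
        df, hits = scan_proteome(ens, Dataset([]), np.empty((0, X.shape[1])))
        assert len(df) == 0 and hits == []

    def test_raising_threshold_never_adds_hits(self, planted_xy):
        ens, X = self._scored_setup(planted_xy)
        ds = Dataset([ProteinRecord(f"q{i}", "A") for i in range(len(X))])
        _, lo = scan_proteome(ens, ds, X, threshold=0.5)
        _, hi = scan_proteome(ens, ds, X, threshold=0.9)
        assert set(hi) <= set(lo)

    def test_dimension_mismatch(self, planted_xy):
        ens, X = self._scored_setup(planted_xy)
        ds = Dataset([ProteinRecord("q0", "A")])
        with pytest.raises(ValueError, match="dimension"):
            scan_proteome(ens, ds, np.zeros((1, X.shape[1] + 1)))


def test_sensitivity_at_threshold():
    assert sensitivity_at_threshold([0.95, 0.9, 0.3], [1, 1, 1], 0.9) \
        == pytest.approx(2 / 3)
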