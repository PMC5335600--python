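"""Descriptor filtering, cluster balancing, grid-searched SVM and evaluation."""

import numpy as np
import pytest

from admeprofiler.svm import (
    AllRejected,
    DegenerateLabels,
    DescriptorFilter,
    LabelledDataset,
    RBFGridSearchSVM,
    SchemaMismatch,
    TargetTooLarge,
    cluster_balance,
    cluster_centres,
    evaluate_external,
    f_score,
    filter_descriptors,
    synthesize_dataset,
    tanimoto_distance_matrix,
)

# a fast grid for unit tests; the default multi-step search is exercised in
# the acceptance suite
FAST = dict(C_exp_range=(-3, 7), gamma_exp_range=(-9, 1), coarse_step=4, folds=5)


def brute_force_filter(X, y, min_nonzero=0.20, min_cv=0.03, max_r=0.90):
    """Literal re-application of the three rejection rules."""
    n, p = X.shape
    surviving = []
    for j in range(p):
        col = X[:, j]
        if (col != 0).mean() < min_nonzero:
            continue
        sd = col.std(ddof=1)
        mean = col.mean()
        cv = np.inf if mean == 0 and sd > 0 else (0.0 if sd == 0 else sd / abs(mean))
        if cv < min_cv:
            continue
        surviving.append(j)
    scores = {j: f_score(X[:, j], y) for j in surviving}
    kept = []
    for j in sorted(surviving, key=lambda j: (-scores[j], j)):
        if all(
            abs(np.corrcoef(X[:, j], X[:, k])[0, 1]) <= max_r
            for k in kept
            if X[:, j].std() > 0 and X[:, k].std() > 0
        ):
            kept.append(j)
    return sorted(kept)


class TestDescriptorFilter:
    def test_sparse_column_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(1.0, 1.0, size=(100, 2))
        X[:85, 1] = 0.0  # non-zero in 15% of rows
        y = (rng.random(100) < 0.5).astype(int)
        assert filter_descriptors(X, y) == [0]

    def test_constant_column_rejected(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.normal(2, 1, 50), np.full(50, 3.0)])
        y = (rng.random(50) < 0.5).astype(int)
        assert filter_descriptors(X, y) == [0]

    def test_correlated_pair_resolved_by_f_score(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 50)
        informative = y * 3.0 + rng.normal(0, 1, 100)
        shadow = informative + rng.normal(0, 0.1, 100)  # r > 0.95, noisier class signal
        noise = rng.normal(5, 1, 100)
        X = np.column_stack([informative, shadow, noise])
        kept = filter_descriptors(X, y)
        assert 2 in kept
        assert (0 in kept) != (1 in kept)  # exactly one of the correlated pair
        assert f_score(X[:, 0], y) > f_score(X[:, 1], y) * 0.9

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n, p = int(rng.integers(20, 60)), int(rng.integers(3, 12))
            X = rng.normal(rng.uniform(-2, 2), rng.uniform(0.01, 2), size=(n, p))
            X[:, rng.integers(0, p)] *= rng.random(n) < 0.1  # sparsify one column
            if rng.random() < 0.5:
                X[:, 0] = X[:, -1] * 1.01 + 0.001  # near-duplicate pair
            y = (rng.random(n) < 0.5).astype(int)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            try:
                got = filter_descriptors(X, y)
            except AllRejected:
                assert brute_force_filter(X, y) == []
                continue
            assert got == brute_force_filter(X, y)

    def test_idempotent_and_column_order_invariant(self):
        rng = np.random.default_rng(3)
        X = rng.normal(1, 1, size=(60, 8))
        X[:, 3] = X[:, 2] * 1.001
        y = (rng.random(60) < 0.5).astype(int)
        kept = filter_descriptors(X, y)
        # idempotent: filtering the filtered matrix keeps everything
        assert filter_descriptors(X[:, kept], y) == list(range(len(kept)))
        # column order invariance up to relabeling
        perm = rng.permutation(8)
        kept_perm = filter_descriptors(X[:, perm], y)
        assert sorted(perm[kept_perm]) == kept

    def test_all_rejected_raises(self):
        X = np.zeros((10, 3))
        y = np.array([0, 1] * 5)
        with pytest.raises(AllRejected):
            filter_descriptors(X, y)


class TestClusterBalance:
    def test_centre_matches_brute_force_on_toy_distances(self):
        # 5 points, printed distances: two tight pairs + an outlier
        D = np.array(
            [
                [0.0, 0.1, 0.9, 0.95, 0.8],
                [0.1, 0.0, 0.85, 0.9, 0.75],
                [0.9, 0.85, 0.0, 0.05, 0.7],
                [0.95, 0.9, 0.05, 0.0, 0.72],
                [0.8, 0.75, 0.7, 0.72, 0.0],
            ]
        )
        centres = cluster_centres(D, target_size=2)
        assert len(centres) == 2
        # brute force: within each cluster the centre minimizes summed distance
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        labels = fcluster(linkage(squareform(D, checks=False), "ward"), 2, "maxclust")
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            sums = D[np.ix_(members, members)].sum(axis=1)
            best = members[sums == sums.min()]
            assert any(b in centres for b in best)

    def test_identical_members_tie_breaks_to_lowest_index(self):
        D = np.zeros((3, 3))
        assert cluster_centres(D, target_size=1) == [0]

    def test_target_equal_to_class_size_is_identity(self):
        ds = synthesize_dataset(10, 20, n_features=5, seed=0)
        out = cluster_balance(ds, target_size=20)
        assert out.X.shape == ds.X.shape
        assert np.array_equal(np.sort(out.y), np.sort(ds.y))

    def test_larger_class_reduced_smaller_untouched(self):
        ds = synthesize_dataset(12, 40, n_features=5, effect_size=1.0, seed=1)
        out = cluster_balance(ds, target_size=12)
        assert (out.y == 0).sum() == 12 and (out.y == 1).sum() == 12

    def test_target_too_large_raises(self):
        ds = synthesize_dataset(5, 8, n_features=4, seed=2)
        with pytest.raises(TargetTooLarge):
            cluster_balance(ds, target_size=9)

    def test_tanimoto_distance_properties(self):
        rng = np.random.default_rng(4)
        fps = rng.random((20, 64)) < 0.3
        D = tanimoto_distance_matrix(fps)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)
        assert (D >= -1e-12).all() and (D <= 1.0 + 1e-12).all()


class TestGridSearchSVM:
    def test_separable_classes_recovered(self):
        ds = synthesize_dataset(100, 100, effect_size=3.0, seed=0)
        model = RBFGridSearchSVM(random_state=0, **FAST).fit(ds.X, ds.y)
        assert model.acc_cv_ >= 0.95
        assert model.auc_cv_ >= 0.95

    def test_permuted_labels_give_chance_auc(self):
        # averaged over seeds: single fits fluctuate by the winner's-curse of
        # grid selection, the mean sits at chance
        aucs = []
        for seed in range(3):
            ds = synthesize_dataset(100, 100, effect_size=3.0, seed=seed)
            rng = np.random.default_rng(seed)
            y_perm = rng.permutation(ds.y)
            model = RBFGridSearchSVM(random_state=seed, **FAST).fit(ds.X, y_perm)
            aucs.append(model.auc_cv_)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_duplicated_consistent_rows_are_memorized(self):
        X = np.repeat(np.arange(10, dtype=float)[:, None], 4, axis=1)
        X = np.vstack([X] * 6) + 0.0
        y = np.tile((np.arange(10) >= 5).astype(int), 6)
        model = RBFGridSearchSVM(random_state=0, **FAST).fit(X, y)
        assert model.acc_cv_ == pytest.approx(1.0)

    def test_single_class_raises(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(DegenerateLabels):
            RBFGridSearchSVM(**FAST).fit(X, np.zeros(20, dtype=int))

    def test_normalization_from_training_only(self):
        ds = synthesize_dataset(60, 60, effect_size=2.0, seed=3)
        model = RBFGridSearchSVM(random_state=0, **FAST).fit(ds.X, ds.y)
        Xs = (ds.X - model.mean_) / model.scale_
        assert np.allclose(Xs.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(Xs.std(axis=0), 1.0, atol=1e-9)
        test = synthesize_dataset(40, 40, effect_size=2.0, seed=99, role="test")
        Xt = (test.X - model.mean_) / model.scale_
        # test set normalized with training parameters is not itself centred
        assert not np.allclose(Xt.mean(axis=0), 0.0, atol=1e-3)

    def test_json_round_trip_preserves_decision_function(self, tmp_path):
        ds = synthesize_dataset(50, 50, effect_size=2.0, seed=5)
        model = RBFGridSearchSVM(random_state=0, **FAST).fit(ds.X, ds.y)
        path = tmp_path / "model.json"
        model.save(path)
        back = RBFGridSearchSVM.load(path)
        probe = synthesize_dataset(10, 10, effect_size=2.0, seed=6).X
        assert np.allclose(back.decision_function(probe), model.decision_function(probe), atol=1e-8)
        assert np.array_equal(back.predict(probe), model.predict(probe))


class TestExternalEvaluation:
    def _toy(self, y, pred, dec):
        class Stub:
            n_features_in_ = 1

            def predict(self, X):
                return np.asarray(pred)

            def decision_function(self, X):
                return np.asarray(dec)

        return Stub(), LabelledDataset(X=np.zeros((len(y), 1)), y=np.asarray(y), role="test")

    def test_perfect_predictions(self):
        model, ds = self._toy([0, 0, 1, 1], [0, 0, 1, 1], [-2.0, -1.0, 1.0, 2.0])
        stats = evaluate_external(model, ds)
        assert stats == {
            "acc_ext": 1.0,
            "auc_ext": 1.0,
            "sensitivity": 1.0,
            "specificity": 1.0,
        }

    def test_all_positive_predictions_on_balanced_set(self):
        model, ds = self._toy([0, 0, 1, 1], [1, 1, 1, 1], [1.0, 1.0, 1.0, 1.0])
        stats = evaluate_external(model, ds)
        assert stats["sensitivity"] == 1.0
        assert stats["specificity"] == 0.0
        assert stats["acc_ext"] == 0.5

    def test_auc_equals_pairwise_concordance(self):
        rng = np.random.default_rng(8)
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 0])
        dec = rng.normal(size=10) + y * 0.8
        model, ds = self._toy(y, (dec > 0).astype(int), dec)
        auc = evaluate_external(model, ds)["auc_ext"]
        pos, neg = dec[y == 1], dec[y == 0]
        concordant = sum(
            1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
        )
        assert auc == pytest.approx(concordant / (len(pos) * len(neg)))

    def test_schema_mismatch_raises(self):
        ds = synthesize_dataset(10, 10, n_features=5, seed=0)
        model = RBFGridSearchSVM(random_state=0, **FAST).fit(ds.X, ds.y)
        bad = LabelledDataset(X=np.zeros((4, 3)), y=np.array([0, 1, 0, 1]), role="test")
        with pytest.raises(SchemaMismatch):
            evaluate_external(model, bad)


class TestSyntheticGenerator:
    def test_same_seed_reproduces_exactly(self):
        a = synthesize_dataset(30, 40, effect_size=1.5, seed=9)
        b = synthesize_dataset(30, 40, effect_size=1.5, seed=9)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)
        assert np.array_equal(a.fingerprints, b.fingerprints)

    def test_zero_effect_is_chance_level(self):
        ds = synthesize_dataset(80, 80, effect_size=0.0, seed=10)
        model = RBFGridSearchSVM(random_state=0, **FAST).fit(ds.X, ds.y)
        assert 0.4 <= model.auc_cv_ <= 0.6

    def test_class_sizes_and_labels(self):
        ds = synthesize_dataset(17, 23, seed=11)
        assert (ds.y == 1).sum() == 17 and (ds.y == 0).sum() == 23
        assert ds.fingerprints.shape == (40, 1024)
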