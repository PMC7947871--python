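import numpy as np
import pytest
from sklearn.svm import SVC

from lpifuse.evaluation import roc_pr
from lpifuse.io import InteractionNetwork, ValidationError
from lpifuse.model import (
    CvPlan,
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    ModelBundle,
    SvmConfig,
    cross_validate,
    grid_search,
    make_pair_dataset,
    train,
)
from lpifuse.fusion import MinMax
from lpifuse.synth import SynthSpec, gen_planted_benchmark
import lpifuse as lp


def _net(adj):
    n, m = adj.shape
    return InteractionNetwork(
        [f"l{i}" for i in range(n)], [f"p{j}" for j in range(m)], adj
    )


class TestMakePairDataset:
    def test_all_policy_complement_counts(self):
        adj = np.zeros((3, 3), dtype=np.int8)
        adj[0, 0] = adj[0, 1] = adj[1, 2] = adj[2, 0] = 1
        pairs, labels = make_pair_dataset(_net(adj), "all")
        assert labels.sum() == 4 and (labels == 0).sum() == 5

    def test_balanced_policy_reproducible(self):
        adj = np.zeros((3, 3), dtype=np.int8)
        adj[0, 0] = adj[0, 1] = adj[1, 2] = adj[2, 0] = 1
        p1, l1 = make_pair_dataset(_net(adj), "balanced", seed=5)
        p2, l2 = make_pair_dataset(_net(adj), "balanced", seed=5)
        assert p1 == p2 and l1.sum() == 4 and (l1 == 0).sum() == 4

    def test_survey_scale_negative_complement(self):
        rng = np.random.default_rng(0)
        adj = np.zeros(990 * 27, dtype=np.int8)
        adj[rng.choice(990 * 27, size=4158, replace=False)] = 1
        adj = adj.reshape(990, 27)
        pairs, labels = make_pair_dataset(_net(adj), "all")
        assert labels.sum() == 4158
        assert (labels == 0).sum() == 990 * 27 - 4158 == 22572

    def test_no_positives_rejected(self):
        with pytest.raises(ValidationError):
            make_pair_dataset(_net(np.zeros((2, 2), dtype=np.int8)), "all")


def _blobs(n=60, seed=1, sep=4.0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, 2)) + sep * y[:, None]
    return X, y


class TestGridSearch:
    def test_singleton_grid_returned_directly(self):
        X, y = _blobs()
        config = grid_search(X, y, C_grid=[256.0], gamma_grid=[0.002])
        assert (config.C, config.gamma) == (256.0, 0.002)

    def test_defaults_contain_published_optimum(self):
        assert 256.0 in DEFAULT_C_GRID
        assert 0.002 in DEFAULT_GAMMA_GRID

    def test_choice_maximises_inner_auc_exhaustively(self):
        X, y = _blobs(n=80, seed=0)
        plan = CvPlan(n_folds=3, seed=0)
        C_grid, gamma_grid = [1.0, 16.0, 256.0], [0.01, 0.1, 1.0]
        chosen = grid_search(X, y, plan, C_grid, gamma_grid)
        # independent exhaustive evaluation of the same grid
        fold = plan.assign(y)
        best = None
        for C in C_grid:
            for gamma in gamma_grid:
                aucs = []
                for f in range(3):
                    svc = SVC(kernel="rbf", C=C, gamma=gamma).fit(
                        X[fold != f], y[fold != f]
                    )
                    _, _, auc, _ = roc_pr(svc.decision_function(X[fold == f]), y[fold == f])
                    aucs.append(auc)
                key = (-np.mean(aucs), C, gamma)
                if best is None or key < best:
                    best = key
        assert (chosen.C, chosen.gamma) == (best[1], best[2])


class TestTrain:
    def test_separable_blobs_fit_perfectly(self):
        X, y = _blobs(seed=1)
        svc = train(X, y, SvmConfig(C=16.0, gamma=0.1))
        assert (svc.predict(X) == y).all()

    def test_conflicting_duplicate_rows_do_not_crash(self):
        X = np.zeros((10, 2))
        y = np.array([0, 1] * 5)
        svc = train(X, y, SvmConfig())
        assert np.isfinite(svc.decision_function(X)).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            train(np.zeros((5, 2)), np.ones(5, dtype=int), SvmConfig())

    def test_bundle_roundtrip_scores_identical(self, tmp_path):
        X, y = _blobs(seed=2)
        scaler = MinMax().fit(X)
        svc = train(scaler.transform(X), y, SvmConfig(C=16.0, gamma=0.1))
        bundle = ModelBundle(svc, scaler, None, SvmConfig(C=16.0, gamma=0.1), ("SEQ",))
        bundle.save(tmp_path / "m")
        probe = np.random.default_rng(3).normal(size=(20, 2))
        reloaded = ModelBundle.load(tmp_path / "m")
        np.testing.assert_array_equal(bundle.score(probe), reloaded.score(probe))


class TestCvPlan:
    def test_assignment_is_seeded_partition(self):
        labels = np.random.default_rng(0).integers(0, 2, 103)
        plan = CvPlan(n_folds=5, seed=9)
        f1, f2 = plan.assign(labels), plan.assign(labels)
        np.testing.assert_array_equal(f1, f2)
        assert set(f1) == set(range(5))
        counts = np.bincount(f1)
        assert counts.sum() == 103 and counts.min() >= 103 // 5

    def test_stratification_keeps_positives_in_every_fold(self):
        labels = np.array([1] * 10 + [0] * 90)
        fold = CvPlan(n_folds=5, seed=1).assign(labels)
        for f in range(5):
            assert labels[fold == f].sum() == 2


class TestCrossValidate:
    def test_deterministic_and_partitioned(self, small_bundle, small_node_features):
        kwargs = dict(
            plan=CvPlan(3, 7), negative_policy="balanced", rfe_params=None,
            C_grid=[16.0], gamma_grid=[0.0078], inner_folds=2,
        )
        r1 = cross_validate(small_bundle.net, small_node_features, **kwargs)
        r2 = cross_validate(small_bundle.net, small_node_features, **kwargs)
        np.testing.assert_array_equal(r1.fold_assignment, r2.fold_assignment)
        np.testing.assert_allclose(r1.oof_scores, r2.oof_scores)
        assert set(r1.fold_assignment) == {0, 1, 2}

    def test_scores_invariant_to_test_row_order(self, small_bundle, small_node_features):
        """SVM scoring is row-wise: permuting the probe rows permutes scores."""
        b = small_bundle
        pairs, labels = make_pair_dataset(b.net, "balanced", 0)
        from lpifuse.model import assemble_blocks
        from lpifuse.fusion import fuse

        fused = fuse(assemble_blocks(b.net, pairs, small_node_features), labels)
        scaler = MinMax().fit(fused.matrix)
        X = scaler.transform(fused.matrix)
        svc = train(X, labels, SvmConfig(C=16.0, gamma=0.01))
        perm = np.random.default_rng(1).permutation(len(labels))
        np.testing.assert_allclose(
            svc.decision_function(X)[perm], svc.decision_function(X[perm])
        )

    def test_null_signal_gives_chance_level_auc(self):
        """With signal_strength=0 labels are independent of every feature."""
        bundle = gen_planted_benchmark(SynthSpec(signal_strength=0.0, seed=3))
        nf = lp.extract_node_features(
            bundle.lncrna_records, bundle.pssms, bundle.expression
        )
        res = cross_validate(
            bundle.net, nf, plan=CvPlan(5, 0), negative_policy="all",
            rfe_params=None, C_grid=[16.0, 256.0], gamma_grid=[0.002, 0.0078],
            inner_folds=3,
        )
        assert len(res.labels) == 2000
        assert 0.45 <= res.pooled.auc <= 0.55

    def test_fit_ignores_test_fold_rows(self, small_bundle, small_node_features):
        """Leakage audit: scaler parameters depend on training rows only."""
        b = small_bundle
        pairs, labels = make_pair_dataset(b.net, "balanced", 0)
        from lpifuse.model import assemble_blocks
        from lpifuse.fusion import fuse

        fused = fuse(assemble_blocks(b.net, pairs, small_node_features), labels)
        fold = CvPlan(3, 0).assign(labels)
        tr = fold != 0
        scaler = MinMax().fit(fused.matrix[tr])
        corrupted = fused.matrix.copy()
        corrupted[~tr] = np.random.default_rng(0).normal(size=corrupted[~tr].shape)
        scaler2 = MinMax().fit(corrupted[tr])
        np.testing.assert_array_equal(
            scaler.transform(fused.matrix[tr]), scaler2.transform(fused.matrix[tr])
        )
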