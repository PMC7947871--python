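import numpy as np
import pytest
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVC

from lpifuse.fusion import (
    FusedDataset,
    MinMax,
    RfeParams,
    apply_minmax,
    fit_minmax,
    fuse,
    select_top,
    svm_rfe_cbr,
)
from lpifuse.io import ValidationError
from lpifuse.network import FeatureBlock, PairIndex


def _block(name, dim, n_pairs=4, seed=0):
    rng = np.random.default_rng(seed)
    pairs = [PairIndex(i, 0) for i in range(n_pairs)]
    return FeatureBlock(name, pairs, rng.normal(size=(n_pairs, dim)), dim)


class TestFuse:
    def test_spans_cover_and_order(self):
        a, b = _block("LDNet", 3), _block("SEQ", 4)
        fused = fuse([b, a], np.array([0, 1, 0, 1]))
        assert fused.block_spans == {"LDNet": (0, 3), "SEQ": (3, 7)}
        assert fused.matrix.shape == (4, 7)
        np.testing.assert_array_equal(fused.matrix[:, :3], a.matrix)

    def test_single_block_identity(self):
        a = _block("CTD", 5)
        fused = fuse([a], np.array([1, 0, 1, 0]))
        np.testing.assert_array_equal(fused.matrix, a.matrix)

    def test_mismatched_pair_lists_rejected(self):
        a = _block("LDNet", 3, n_pairs=4)
        b = _block("SEQ", 4, n_pairs=5)
        with pytest.raises(ValidationError):
            fuse([a, b], np.zeros(4, dtype=int))

    def test_block_dims_at_survey_scale_sum_to_1747(self):
        dims = {"LDNet": 1015, "KPSSM": 400, "CTD": 273, "SEQ": 35, "EXPR": 24}
        blocks = [_block(name, d, n_pairs=2) for name, d in dims.items()]
        fused = fuse(blocks, np.array([0, 1]))
        assert fused.n_features == 1747


class TestMinMax:
    def test_binary_column_maps_to_unit_interval(self):
        scaler = fit_minmax(np.array([[0.0], [10.0]]))
        np.testing.assert_allclose(
            apply_minmax(scaler, np.array([[0.0], [10.0], [5.0]])),
            [[0.0], [1.0], [0.5]],
        )

    def test_constant_column_maps_to_zero(self):
        scaler = fit_minmax(np.full((5, 1), 7.0))
        np.testing.assert_allclose(apply_minmax(scaler, np.full((3, 1), 7.0)), 0.0)

    def test_train_extrema_hit_0_and_1_exactly(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 6))
        scaled = fit_minmax(X).transform(X)
        np.testing.assert_allclose(scaled.min(axis=0), 0.0, atol=1e-15)
        np.testing.assert_allclose(scaled.max(axis=0), 1.0, atol=1e-15)

    def test_apply_before_fit_rejected(self):
        with pytest.raises(ValidationError):
            MinMax().transform(np.zeros((2, 2)))

    def test_test_rows_may_leave_unit_interval(self):
        scaler = fit_minmax(np.array([[0.0], [1.0]]))
        assert apply_minmax(scaler, np.array([[2.0]]))[0, 0] == 2.0


def _planted_xy(n=200, seed=1, n_noise=1):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    informative = y + 0.3 * rng.normal(size=n)
    noise = rng.normal(size=(n, n_noise))
    X = np.column_stack([informative, noise])
    return X, y


def _oracle_dj(X, y, params):
    """Independent DJ computation via sklearn kernel evaluations."""
    svc = SVC(kernel="rbf", C=params.rfe_C, gamma=params.rfe_gamma).fit(X, y)
    sv = X[svc.support_]
    a = svc.dual_coef_.ravel()
    K = rbf_kernel(sv, sv, gamma=params.rfe_gamma)
    out = []
    for f in range(X.shape[1]):
        Km = rbf_kernel(np.delete(sv, f, axis=1), np.delete(sv, f, axis=1),
                        gamma=params.rfe_gamma)
        out.append(0.5 * (a @ K @ a - a @ Km @ a))
    return np.array(out)


class TestSvmRfeCbr:
    def test_planted_informative_feature_ranked_first(self):
        X, y = _planted_xy(seed=1)
        ranked = svm_rfe_cbr(None, RfeParams(use_cbr=False), X=X, y=y)
        assert ranked.ranking[0] == 0

    def test_two_feature_instance_agrees_with_exhaustive_oracle(self):
        params = RfeParams(step=1, use_cbr=False)
        for seed in range(5):
            X, y = _planted_xy(n=120, seed=seed)
            dj = _oracle_dj(X, y, params)
            expected_first = int(np.argmax(dj)) if dj[0] != dj[1] else 0
            ranked = svm_rfe_cbr(None, params, X=X, y=y)
            assert ranked.ranking[0] == expected_first

    def test_cbr_eliminates_noise_before_duplicated_informative_pair(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 150)
        informative = y + 0.4 * rng.normal(size=150)
        X = np.column_stack([informative, informative, rng.normal(size=150)])
        ranked = svm_rfe_cbr(None, RfeParams(step=1, use_cbr=True, r_th=0.9), X=X, y=y)
        assert ranked.ranking[-1] == 2  # noise eliminated first -> worst rank

    def test_cbr_removes_at_most_one_group_member_per_iteration(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        base = rng.normal(size=100)
        X = np.column_stack([base, base, base, rng.normal(size=(100, 3))])
        ranked = svm_rfe_cbr(
            None, RfeParams(step=3, use_cbr=True, r_th=0.99), X=X, y=y
        )
        # the three exact copies (columns 0-2) must leave in distinct iterations
        survivor_sets = [set(cols.tolist()) for cols, _ in ranked.criteria_trace]
        survivor_sets.append(set())
        dups = {0, 1, 2}
        removed_per_iter = [
            len(dups & survivor_sets[t]) - len(dups & survivor_sets[t + 1])
            for t in range(len(survivor_sets) - 1)
        ]
        assert max(removed_per_iter) <= 1

    def test_ranking_is_permutation(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 12))
        y = rng.integers(0, 2, 60)
        ranked = svm_rfe_cbr(None, RfeParams(step=1, use_cbr=False), X=X, y=y)
        assert sorted(ranked.ranking.tolist()) == list(range(12))

    def test_trace_length_is_ceil_d_over_step(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 7))
        y = rng.integers(0, 2, 50)
        ranked = svm_rfe_cbr(None, RfeParams(step=3, use_cbr=False), X=X, y=y)
        assert len(ranked.criteria_trace) == 3  # ceil(7/3)
        for cols, crit in ranked.criteria_trace:
            assert np.isfinite(crit).all()

    def test_duplicating_informative_never_helps_noise_under_cbr(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 120)
            inf = y + 0.5 * rng.normal(size=120)
            noise = rng.normal(size=120)
            X_plain = np.column_stack([inf, noise])
            X_dup = np.column_stack([inf, inf.copy(), noise])
            params = RfeParams(step=1, use_cbr=True, r_th=0.9)
            rank_plain = svm_rfe_cbr(None, params, X=X_plain, y=y)
            rank_dup = svm_rfe_cbr(None, params, X=X_dup, y=y)
            # relative position of the noise column (1.0 = worst)
            pos_plain = np.where(rank_plain.ranking == 1)[0][0] / 1
            pos_dup = np.where(rank_dup.ranking == 2)[0][0] / 2
            assert pos_dup >= pos_plain - 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            svm_rfe_cbr(None, RfeParams(), X=np.zeros((10, 3)), y=np.zeros(10))

    def test_scaled_dataset_input(self):
        X, y = _planted_xy(n=80, seed=2, n_noise=2)
        fused = FusedDataset(X, y, {"B": (0, 3)})
        ranked = svm_rfe_cbr(fused, RfeParams(use_cbr=False))
        assert len(ranked.ranking) == 3


class TestSelectTop:
    def test_nesting_and_bounds(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6))
        y = rng.integers(0, 2, 40)
        ranked = svm_rfe_cbr(None, RfeParams(step=1, use_cbr=False), X=X, y=y)
        prev: set = set()
        for n in range(1, 7):
            cur = set(select_top(ranked, n).tolist())
            assert len(cur) == n and prev <= cur
            prev = cur
        np.testing.assert_array_equal(np.sort(select_top(ranked, 6)), np.arange(6))
        with pytest.raises(ValidationError):
            select_top(ranked, 7)
        with pytest.raises(ValidationError):
            select_top(ranked, 0)
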