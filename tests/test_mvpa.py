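import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import avmvpa as m
from avmvpa.mvpa import (
    MvpaError,
    crossvalidated_mvpa,
    fisher_ratio_map,
    pair_indices,
    reproducibility,
    searchlight_offsets,
    select_top_k,
)
from conftest import make_pattern_set


class TestSearchlight:
    def test_cardinalities(self):
        assert len(searchlight_offsets(np.sqrt(2)).offsets) == 19
        assert len(searchlight_offsets(0).offsets) == 1
        assert len(searchlight_offsets(1).offsets) == 7

    def test_contains_origin_and_sorted(self):
        offs = searchlight_offsets(np.sqrt(2)).offsets
        assert [0, 0, 0] in offs.tolist()
        assert offs.tolist() == sorted(offs.tolist())

    def test_negative_radius_errors(self):
        with pytest.raises(MvpaError):
            searchlight_offsets(-1)


def _grid_patterns(rng, n, shape=(5, 5, 3)):
    coords = np.argwhere(np.ones(shape, bool))
    X = rng.standard_normal((n, len(coords)))
    return X, coords, shape


class TestFisherRatio:
    def test_one_dimensional_closed_form(self):
        # 0-radius searchlight on one voxel: J = (m1 - m2)^2 / s^2_pooled
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(2.0, 1.0, 12), rng.normal(-1.0, 1.5, 12)])
        y = np.repeat([0, 1], 12)
        fmap = fisher_ratio_map(
            x[:, None], y, spec=searchlight_offsets(0),
            voxel_index=np.array([[0, 0, 0]]), mask_shape=(1, 1, 1),
        )
        m1, m2 = x[y == 0].mean(), x[y == 1].mean()
        s2 = (x[y == 0].var(ddof=1) * 11 + x[y == 1].var(ddof=1) * 11) / 22
        assert fmap.values[0] == pytest.approx((m1 - m2) ** 2 / s2, rel=1e-5)

    def test_matches_dense_direct_solve_oracle(self):
        """J from the engine equals the textbook w = S_W^-1 (m1-m2),
        J = (w'S_B w)/(w'S_W w) evaluated per searchlight by brute force."""
        rng = np.random.default_rng(7)
        X, coords, shape = _grid_patterns(rng, 24)
        y = np.repeat([0, 1], 12)
        spec = searchlight_offsets(np.sqrt(2))
        fmap = fisher_ratio_map(X, y, spec=spec, voxel_index=coords,
                                mask_shape=shape, ridge_scale=0.0)
        lookup = {tuple(c): i for i, c in enumerate(coords)}
        for ci, center in enumerate(coords[::7]):
            nb = [lookup[tuple(center + o)] for o in spec.offsets
                  if tuple(center + o) in lookup]
            Z = X[:, nb]
            d = Z[y == 0].mean(0) - Z[y == 1].mean(0)
            Zc = Z.copy()
            Zc[y == 0] -= Z[y == 0].mean(0)
            Zc[y == 1] -= Z[y == 1].mean(0)
            S_W = Zc.T @ Zc / (len(y) - 2)
            S_B = np.outer(d, d)
            w = np.linalg.solve(S_W, d)
            J = (w @ S_B @ w) / (w @ S_W @ w)
            assert fmap.values[lookup[tuple(center)]] == pytest.approx(J, rel=1e-6)

    def test_identical_class_means_give_zero(self):
        rng = np.random.default_rng(3)
        X, coords, shape = _grid_patterns(rng, 16)
        X[8:] = X[:8]  # class 1 duplicates class 0 -> equal means
        y = np.repeat([0, 1], 8)
        fmap = fisher_ratio_map(X, y, voxel_index=coords, mask_shape=shape)
        assert np.all(fmap.values < 1e-8)

    def test_trial_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X, coords, shape = _grid_patterns(rng, 20)
        y = np.repeat([0, 1], 10)
        perm = rng.permutation(20)
        a = fisher_ratio_map(X, y, voxel_index=coords, mask_shape=shape)
        b = fisher_ratio_map(X[perm], y[perm], voxel_index=coords, mask_shape=shape)
        assert np.allclose(a.values, b.values, rtol=1e-6, atol=1e-9)

    def test_degenerate_constant_neighbourhood_flagged(self):
        coords = np.argwhere(np.ones((3, 1, 1), bool))
        X = np.ones((8, 3))
        y = np.repeat([0, 1], 4)
        fmap = fisher_ratio_map(X, y, voxel_index=coords, mask_shape=(3, 1, 1))
        assert np.all(fmap.values == 0)
        assert fmap.degenerate.all()


class TestTopK:
    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.random(200)  # unique with probability 1
        coords = np.argwhere(np.ones((10, 10, 2), bool))
        sel = select_top_k(values, 30, voxel_index=coords)
        want = np.sort(np.argsort(-values)[:30])
        assert np.array_equal(sel, want)

    def test_whole_mask_and_overflow(self):
        values = np.arange(10.0)
        coords = np.argwhere(np.ones((10, 1, 1), bool))
        assert len(select_top_k(values, 10, voxel_index=coords)) == 10
        with pytest.raises(MvpaError):
            select_top_k(values, 11, voxel_index=coords)

    def test_ties_broken_lexicographically(self):
        values = np.zeros(8)
        coords = np.argwhere(np.ones((2, 2, 2), bool))
        sel = select_top_k(values, 3, voxel_index=coords)
        assert coords[sel].tolist() == [[0, 0, 0], [0, 0, 1], [0, 1, 0]]


class TestReproducibility:
    labels = np.repeat([0, 1], 4)

    def test_pair_counts(self):
        within, between = pair_indices(self.labels)
        assert len(within) == 12 and len(between) == 16

    def test_identical_patterns(self):
        X = np.tile(np.array([1.0, 2.0, 3.0]), (8, 1))
        r = reproducibility(X, self.labels)
        assert (r.r_within, r.r_between, r.ratio) == (1.0, 1.0, 1.0)

    def test_antipodal_classes(self):
        u = np.array([1.0, -2.0, 0.5])
        X = np.vstack([np.tile(u, (4, 1)), np.tile(-u, (4, 1))])
        r = reproducibility(X, self.labels)
        assert r.r_within == pytest.approx(1.0)
        assert r.r_between == pytest.approx(-1.0)
        assert r.ratio == pytest.approx(-1.0)

    def test_matches_bruteforce_pair_enumeration(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((8, 5))
        r = reproducibility(X, self.labels)
        cos = lambda a, b: a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        w, b = [], []
        for i in range(8):
            for j in range(i + 1, 8):
                (w if self.labels[i] == self.labels[j] else b).append(cos(X[i], X[j]))
        assert len(w) == 12 and len(b) == 16
        assert r.r_within == pytest.approx(np.mean(w), abs=1e-12)
        assert r.r_between == pytest.approx(np.mean(b), abs=1e-12)
        assert r.ratio == pytest.approx(np.mean(w) / np.mean(b), abs=1e-12)

    def test_difference_form(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((8, 5))
        r = reproducibility(X, self.labels, form="difference")
        assert r.ratio == pytest.approx(r.r_within - r.r_between)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(c=st.floats(0.01, 100.0), row=st.integers(0, 7))
    def test_scale_invariance(self, c, row):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((8, 6))
        r0 = reproducibility(X, self.labels)
        X2 = X.copy()
        X2[row] *= c
        r1 = reproducibility(X2, self.labels)
        assert r1.ratio == pytest.approx(r0.ratio, rel=1e-9)

    def test_zero_norm_errors_and_near_zero_between_flagged(self):
        X = np.ones((8, 3))
        X[0] = 0.0
        with pytest.raises(MvpaError):
            reproducibility(X, self.labels)
        # orthogonal classes: all between-class cosines are zero -> undefined
        Y = np.zeros((8, 4))
        Y[:4, 0] = Y[4:, 1] = 1.0
        r = reproducibility(Y, self.labels)
        assert r.undefined and np.isnan(r.ratio)

    def test_unbalanced_fold_errors(self):
        with pytest.raises(MvpaError):
            reproducibility(np.ones((8, 2)), np.array([0] * 5 + [1] * 3))


class TestCrossvalidation:
    def test_training_partition_size(self, gender_av_patterns):
        eng = m.CvEngine(gender_av_patterns, K=50)
        for cache in eng._caches.values():
            assert cache["n"] == 72

    def test_perfectly_separable_patterns_decode_fully(self):
        rng = np.random.default_rng(4)
        ps = make_pattern_set(rng, n_voxels=40, signal=0.0)
        ps.patterns[:, :20] = (1 - 2 * ps.gender_labels)[:, None]  # noiseless code
        rep, dec = crossvalidated_mvpa(ps, "gender", K=20)
        assert dec.mean_accuracy == 1.0

    def test_weight_map_support_within_selection(self, gender_av_patterns):
        _, dec = crossvalidated_mvpa(gender_av_patterns, "gender", K=60)
        for w, sel in zip(dec.weight_maps, dec.selected):
            support = np.flatnonzero(w)
            assert len(support) <= 60
            assert np.isin(support, sel).all()

    def test_selection_leakage_inflates_null_accuracy(self):
        """Anti-pattern check: selecting voxels on all 80 trials before
        testing must inflate accuracy on pure-noise data."""
        rng = np.random.default_rng(99)
        fold_acc, leak_acc = [], []
        for _ in range(15):
            ps = make_pattern_set(rng, n_voxels=120, signal=0.0)
            _, d_fold = crossvalidated_mvpa(ps, "gender", K=12)
            _, d_leak = crossvalidated_mvpa(ps, "gender", K=12,
                                            selection_scope="all")
            fold_acc.append(d_fold.mean_accuracy)
            leak_acc.append(d_leak.mean_accuracy)
        assert np.mean(leak_acc) > np.mean(fold_acc) + 0.03
        assert abs(np.mean(fold_acc) - 0.5) < 0.1

    def test_attended_ordering_stable_across_k(self, small_phantom, default_model):
        """The AV > max(V, A) ordering of the attended feature's ratio holds
        across a range of selected-voxel counts."""
        ratios = {}
        for cond in ("AV", "V", "A"):
            d = m.build_run_design("gender", cond, seed=77)
            run = m.simulate_run(d, small_phantom, default_model, seed=88)
            ps = m.extract_patterns(m.preprocess_run(run))
            for K in (25, 100, 400):
                eng = m.CvEngine(ps, K=K)
                rep, _ = eng.run(ps.labels("gender"))
                ratios[(cond, K)] = rep.mean_ratio
        for K in (25, 100, 400):
            assert ratios[("AV", K)] > max(ratios[("V", K)], ratios[("A", K)])
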