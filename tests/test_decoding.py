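"""Feature construction, cross-validated SVM, resampling analyses, merging."""

import numpy as np
import pytest

import microsep as m
from microsep.decoding import (
    DEFAULT_C_GRID,
    MERGE_WINDOW,
    ChannelGroups,
    SEPDecoder,
    crossval_svm,
    default_merge_levels,
    fold_indices,
    linear_gram,
)


class TestBuildFeatures:
    def test_full_length_dimension(self, small_decode_epochs):
        fm = m.build_features(small_decode_epochs)
        assert fm.X.shape == (300, 94 * 200)

    def test_single_timepoint_dimension(self, small_decode_epochs):
        fm = m.build_features(small_decode_epochs, t_start=50, t_end=51)
        assert fm.n_features == 94

    def test_minimal_one_channel_one_sample(self, small_decode_epochs):
        ch = int(small_decode_epochs.channel_ids[0])
        fm = m.build_features(small_decode_epochs, channels=[ch],
                              t_start=100, t_end=101)
        assert fm.n_features == 1

    def test_window_outside_marks_rejected(self, small_decode_epochs):
        with pytest.raises(ValueError):
            m.build_features(small_decode_epochs, t_start=40, t_end=200)
        with pytest.raises(ValueError):
            m.build_features(small_decode_epochs, t_start=50, t_end=251)

    def test_channel_major_layout(self, small_decode_epochs):
        """Features are concatenated channel-major and globally z-scored."""
        ep = small_decode_epochs
        fm = m.build_features(ep, t_start=50, t_end=60, zscore="none")
        raw = ep.data_uv[:, :, ep.pre + 50:ep.pre + 60]
        np.testing.assert_array_equal(fm.X[5], raw[5].reshape(-1))


class TestCrossvalSvm:
    def _blobs(self, n=200, d=4, classes=2, sep=20.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        y = np.repeat(np.arange(classes), n // classes)
        X[:, 0] += sep * y
        return X, y

    def test_separable_clouds_decode_perfectly(self):
        X, y = self._blobs()
        res = crossval_svm(X, y, C=1.0, seed=3)
        assert res.mean_acc == 1.0

    def test_gram_path_matches_direct_path(self):
        X, y = self._blobs(n=100, d=6, classes=4, sep=3.0)
        direct = crossval_svm(X, y, C=1.0, seed=5)
        grammed = crossval_svm(X, y, C=1.0, seed=5, gram=linear_gram(X))
        np.testing.assert_array_equal(direct.fold_acc, grammed.fold_acc)
        np.testing.assert_array_equal(direct.confusion, grammed.confusion)

    def test_confusion_matrix_conservation(self, small_decode_epochs):
        fm = m.build_features(small_decode_epochs, t_start=50, t_end=80)
        res = crossval_svm(fm, C=1.0, seed=1)
        assert res.confusion.sum() == 300
        np.testing.assert_array_equal(res.confusion.sum(axis=1),
                                      np.full(10, 30))
        assert res.mean_acc == pytest.approx(
            np.trace(res.confusion) / res.confusion.sum())

    def test_fixed_seed_reproducibility(self, small_decode_epochs):
        fm = m.build_features(small_decode_epochs, t_start=50, t_end=70)
        a = crossval_svm(fm, C=1.0, seed=9)
        b = crossval_svm(fm, C=1.0, seed=9)
        np.testing.assert_array_equal(a.fold_acc, b.fold_acc)
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_fold_split_is_shuffled_contiguous_blocks(self):
        folds = fold_indices(50, 10, seed=4)
        assert [len(f) for f in folds] == [5] * 10
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(50))
        again = fold_indices(50, 10, seed=4)
        for f, g in zip(folds, again):
            np.testing.assert_array_equal(f, g)

    def test_uneven_fold_size_rejected(self):
        X, y = self._blobs(n=202)
        with pytest.raises(ValueError):
            crossval_svm(X, y, n_folds=10)

    def test_invalid_C_rejected(self):
        X, y = self._blobs()
        with pytest.raises(ValueError):
            crossval_svm(X, y, C=0.0)

    def test_oracle_equivalence_on_toy_margin_problem(self):
        """Fold predictions match a brute-force maximum-margin classifier
        found by exhaustive search over a coarse grid of line orientations
        and offsets (20 samples, 2 classes, 2 features)."""
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal((-3, 0), 0.5, size=(10, 2)),
                       rng.normal((3, 0), 0.5, size=(10, 2))])
        y = np.repeat([0, 1], 10)

        def oracle_margin(Xtr, ytr):
            best = None
            for theta in np.linspace(0, np.pi, 181):
                w = np.array([np.cos(theta), np.sin(theta)])
                p = Xtr @ w
                lo, hi = p[ytr == 0], p[ytr == 1]
                for sgn in (1, -1):
                    a, b = (lo, hi) if sgn == 1 else (hi, lo)
                    margin = b.min() - a.max()
                    if margin > 0 and (best is None or margin > best[0]):
                        bias = -(a.max() + b.min()) / 2
                        best = (margin, sgn * w, sgn * bias)
            return best[1], best[2]

        folds = fold_indices(20, 5, seed=2)
        svm_preds, oracle_preds = [], []
        for k in range(5):
            te = folds[k]
            tr = np.concatenate([folds[j] for j in range(5) if j != k])
            from sklearn.svm import SVC
            clf = SVC(kernel="linear", C=1.0).fit(X[tr], y[tr])
            svm_preds.append(clf.predict(X[te]))
            w, b = oracle_margin(X[tr], y[tr])
            oracle_preds.append((X[te] @ w + b > 0).astype(int))
        np.testing.assert_array_equal(np.concatenate(svm_preds),
                                      np.concatenate(oracle_preds))


class TestDecoderModel:
    def test_from_epochs_fit_summary(self, small_decode_epochs):
        res = SEPDecoder.from_epochs(small_decode_epochs, t_start=50,
                                     t_end=132).fit(seed=0)
        text = res.summary()
        assert "accuracy" in text and "D3x4mA" in text
        assert 0.0 <= res.mean_acc <= 1.0

    def test_label_shuffle_control_sits_at_chance(self, small_decode_epochs):
        fm = m.build_features(small_decode_epochs, t_start=50, t_end=132)
        accs = m.shuffled_label_control(fm, n_permutations=6, seed=21)
        # 10 balanced classes -> chance 0.1
        assert abs(accs.mean() - 0.1) < 0.05


class TestSweeps:
    def test_c_grid_has_20_log_points_with_stated_endpoints(self):
        assert DEFAULT_C_GRID.size == 20
        assert DEFAULT_C_GRID[0] == pytest.approx(1e-10)
        assert DEFAULT_C_GRID[-1] == pytest.approx(1e2)

    def test_sweep_c_selected_value_not_worse_than_smallest(self,
                                                            small_decode_epochs):
        fm = m.build_features(small_decode_epochs, channels=[46, 54, 45],
                              t_start=50, t_end=132)
        curve = m.sweep_C(fm, grid=[1e-10, 1e-4, 1.0], seed=2)
        assert curve.loc[1.0] >= curve.loc[1e-10]

    def test_truncation_curve_chance_before_onset_then_informative(
            self, small_decode_epochs):
        """Windows that end before the planted 9 ms response onset decode at
        chance; windows that cover the early component do not."""
        # 9 ms post-stimulus = sample offset 16 + 55 = 71
        curve = m.temporal_truncation_curve(
            small_decode_epochs, t_ends=[55, 60, 65, 70, 130, 250], seed=6)
        assert curve.index.tolist() == [55, 60, 65, 70, 130, 250]
        pre = curve.loc[[55, 60, 65, 70]]
        assert np.all(np.abs(pre - 0.1) < 0.06)
        assert curve.loc[130] > 0.9
        assert curve.loc[250] >= curve.loc[130] - 0.02

    def test_single_timepoint_accuracy_tracks_sep_amplitude(
            self, small_decode_epochs):
        grid = m.single_timepoint_map(small_decode_epochs, n_grid=[91],
                                      t_grid=[55, 132], repeats=2, seed=3)
        # pre-response time point decodes at chance, main-peak point does not
        assert abs(grid.loc[91, 55] - 0.1) < 0.06
        assert grid.loc[91, 132] > 0.6

    def test_subsampling_grid_shapes_and_default_grids(self, small_decode_epochs):
        n_grid = np.arange(1, 92, 5)
        t_grid = np.arange(1, 197, 5)
        assert n_grid.size == 19 and t_grid.size == 40
        out = m.spatial_subsampling_grid(small_decode_epochs,
                                         n_grid=[1, 46, 91], t_grid=[10, 100],
                                         repeats=2, seed=8)
        assert out.shape == (3, 2)
        # more channels should not hurt, within sampling tolerance
        assert out.loc[91, 100] >= out.loc[1, 100] - 0.02


class TestMergedChannels:
    def test_default_levels_partition_retained_channels(self, geometry):
        levels = default_merge_levels(geometry)
        sizes = [lv.n_groups for lv in levels]
        assert sizes == [3, 6, 24, 94]
        retained = set(int(c) for c in geometry.retained_channels)
        for lv in levels:
            assert lv.channel_union() == retained

    def test_singleton_groups_are_identity(self, small_decode_epochs):
        groups = ChannelGroups(groups=tuple(
            (int(c),) for c in small_decode_epochs.channel_ids))
        merged = m.merge_channels(small_decode_epochs, groups)
        np.testing.assert_array_equal(merged.data_uv,
                                      small_decode_epochs.data_uv)

    def test_merging_identical_channels_preserves_signal(self,
                                                         small_decode_epochs):
        ep = small_decode_epochs
        dup = ep.select_trials(np.arange(ep.n_trials))
        dup.data_uv[:, 1, :] = dup.data_uv[:, 0, :]
        ids = dup.channel_ids
        merged = m.merge_channels(dup, ChannelGroups(
            groups=((int(ids[0]), int(ids[1])),)))
        np.testing.assert_allclose(merged.data_uv[:, 0, :],
                                   dup.data_uv[:, 0, :], atol=1e-4)

    def test_merging_with_remote_channels_lowers_peak(self, small_cfg,
                                                      geometry):
        """Averaging the on-centre template with far, low-amplitude templates
        strictly lowers the virtual channel's peak."""
        lab = m.ConditionLabel("D3", 4)
        on = m.sep_kernel(52, lab, small_cfg, geometry)
        far = [m.sep_kernel(c, lab, small_cfg, geometry) for c in (0, 1, 2)]
        virtual = (on + sum(far)) / 4.0
        assert virtual.max() < on.max()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ChannelGroups(groups=((1, 2), ()))

    def test_merged_curve_window_and_monotonicity(self, small_decode_epochs,
                                                  geometry):
        assert MERGE_WINDOW == (102, 112)     # t_stim + 86, 10 samples long
        curve, results = m.merged_channel_curve(small_decode_epochs,
                                                geometry=geometry, seed=5)
        assert curve.index.tolist() == [3, 6, 24, 94]
        assert results[-1].confusion.sum() == 300
        # finer levels should not decode worse (tolerance for CV noise)
        acc = curve["mean_acc"].values
        assert np.all(np.diff(acc) >= -0.05)
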