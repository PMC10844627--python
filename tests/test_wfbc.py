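import numpy as np
import pytest

import dentspike as ds
from dentspike.exceptions import ConfigError
from conftest import gaussian_waveform


def _wm(values, window=(-100, 100), fs=1000.0):
    values = np.atleast_2d(values)
    return ds.WaveformMatrix(values=values, window=window, fs=fs,
                             event_ids=np.arange(values.shape[0]))


class TestFeatures:
    def test_31_features_at_1khz(self, clean_pool):
        _, _, wm, _ = clean_pool
        feats = ds.extract_features(wm)
        assert feats.shape[1] == 31

    def test_peak_column_is_raw_peak(self, clean_pool):
        _, _, wm, _ = clean_pool
        feats = ds.extract_features(wm)
        np.testing.assert_array_equal(feats[:, 15], wm.values[:, wm.peak_column])

    def test_2khz_input_resampled(self):
        t = np.arange(-100, 100.5, 0.5)
        v = np.exp(-0.5 * (t / 5.0) ** 2)
        wm = _wm(np.tile(v, (3, 1)), fs=2000.0)
        feats = ds.extract_features(wm)
        assert feats.shape == (3, 31)
        assert feats[0, 15] == pytest.approx(1.0, abs=1e-6)

    def test_narrow_window_rejected(self):
        with pytest.raises(ConfigError):
            ds.extract_features(_wm(np.zeros(21), window=(-10, 10)))


class TestArtifactRejection:
    def _pool_with_artifacts(self, n_good=970, n_art=30, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(-100, 101, 1.0)
        tpl1 = 1.8 * np.exp(-0.5 * (t / 6.5) ** 2)
        tpl2 = 2.2 * np.exp(-0.5 * (t / 4.2) ** 2)
        good = np.vstack([tpl1 + rng.normal(0, 0.05, t.size)
                          for _ in range(n_good // 2)] +
                         [tpl2 + rng.normal(0, 0.05, t.size)
                          for _ in range(n_good - n_good // 2)])
        art = np.vstack([12.0 * np.abs(np.sinc(t / 3.0)) +
                         rng.normal(0, 0.05, t.size)
                         for _ in range(n_art)])
        return np.vstack([good, art]), n_good

    def test_small_artifact_cluster_rejected(self):
        X, n_good = self._pool_with_artifacts()
        cfg = ds.WfbcConfig()
        assign, active, rejected = ds.cluster_with_artifact_rejection(
            ds.extract_features(_wm(X), cfg), cfg)
        assert set(rejected) == set(range(n_good, X.shape[0]))
        fracs = np.bincount(assign.labels, minlength=2) / X.shape[0]
        assert fracs.min() >= 0.05 and fracs.max() <= 0.95

    def test_balanced_input_single_round(self, clean_pool):
        _, _, wm, _ = clean_pool
        cfg = ds.WfbcConfig()
        feats = ds.extract_features(wm, cfg)[:400]
        _, active, rejected = ds.cluster_with_artifact_rejection(feats, cfg)
        assert rejected.size == 0 and active.size == 400

    def test_deterministic_across_calls(self):
        X, _ = self._pool_with_artifacts(seed=3)
        cfg = ds.WfbcConfig()
        feats = ds.extract_features(_wm(X), cfg)
        a = ds.cluster_with_artifact_rejection(feats, cfg)
        b = ds.cluster_with_artifact_rejection(feats, cfg)
        np.testing.assert_array_equal(a[0].labels, b[0].labels)
        np.testing.assert_array_equal(a[2], b[2])


class TestPostPeakAssignment:
    def test_lower_sum_is_ds2(self):
        t = np.arange(-100, 101, 1.0)
        flat = np.exp(-0.5 * (t / 5) ** 2)
        neg = flat.copy()
        neg[(t > 10) & (t <= 50)] -= 0.1
        tm, flagged = ds.assign_types_by_postpeak(flat, neg, 1000.0, (-100, 100))
        assert tm == {1: 2, 0: 1} and not flagged

    def test_templates_assign_correctly(self):
        t1 = ds.make_ds_template(1)
        t2 = ds.make_ds_template(2)
        tm, _ = ds.assign_types_by_postpeak(
            t1.peak_amplitude_mv * t1.shape, t2.peak_amplitude_mv * t2.shape,
            1000.0, (-100, 100))
        assert tm == {0: 1, 1: 2}

    def test_common_baseline_shift_preserves_assignment(self):
        t1 = ds.make_ds_template(1)
        t2 = ds.make_ds_template(2)
        a, b = 1.8 * t1.shape + 0.3, 2.2 * t2.shape + 0.3
        tm, _ = ds.assign_types_by_postpeak(a, b, 1000.0, (-100, 100))
        assert tm == {0: 1, 1: 2}


class TestDissimilarityIndex:
    def test_identity_zero(self):
        wf = gaussian_waveform(5, (-100, 100))
        res = ds.dissimilarity_index(wf, wf, 1000.0, (-100, 100))
        assert res.di == 0.0 and res.same_type

    def test_symmetry_and_bounds(self):
        a = gaussian_waveform(6, (-100, 100))
        b = ds.make_ds_template(2).shape
        r1 = ds.dissimilarity_index(a, b, 1000.0, (-100, 100))
        r2 = ds.dissimilarity_index(b, a, 1000.0, (-100, 100))
        assert r1.di == pytest.approx(r2.di)
        assert 0 <= r1.di <= 1

    def test_distinct_gaussians_exceed_threshold(self):
        a = gaussian_waveform(6.0, (-100, 100))
        b = gaussian_waveform(4.5, (-100, 100))
        res = ds.dissimilarity_index(a, b, 1000.0, (-100, 100))
        assert res.di > 0.06 and not res.same_type

    def test_scaled_derivatives_in_unit_interval(self):
        a = ds.make_ds_template(1).shape
        b = ds.make_ds_template(2).shape
        res = ds.dissimilarity_index(a, b, 1000.0, (-100, 100))
        for v in (res.scaled_d2_a, res.scaled_d2_b):
            assert v.min() >= 0 and v.max() <= 1

    def test_flat_derivative_flagged(self):
        flat = np.zeros(201)
        bump = gaussian_waveform(5, (-100, 100))
        res = ds.dissimilarity_index(flat, bump, 1000.0, (-100, 100))
        assert res.flagged


class TestVote:
    @pytest.mark.parametrize("width,start,end,expected", [
        (21.0, -10.0, 10.0, 1),   # unanimous type 1
        (15.0, -7.0, 7.0, 2),     # unanimous type 2
        (20.0, -9.0, 10.0, 1),    # 2-of-3
        (18.0, -10.0, 9.0, 2),    # 1-of-3 fails
    ])
    def test_vote_rule(self, width, start, end, expected):
        w = ds.WidthMeasurement(start_ms=start, end_ms=end, width_ms=width,
                                method="second_derivative")
        assert ds.single_type_vote(w) == expected


class TestClassifyWfbc:
    def test_recovery_on_clean_pool(self, clean_pool):
        _, _, wm, types = clean_pool
        sub = slice(0, 1000)
        clf = ds.WaveformClassifier()
        labels = clf.fit_predict(wm.values[sub])
        assert (labels == types[sub]).mean() >= 0.95
        assert not clf.merged_single_type_

    def test_determinism(self, clean_pool):
        _, _, wm, _ = clean_pool
        a = ds.WaveformClassifier().fit_predict(wm.values[:300])
        b = ds.WaveformClassifier().fit_predict(wm.values[:300])
        np.testing.assert_array_equal(a, b)

    def test_event_order_permutation_permutes_labels(self, clean_pool):
        _, _, wm, _ = clean_pool
        X = wm.values[:300]
        rng = np.random.default_rng(0)
        perm = rng.permutation(300)
        a = ds.WaveformClassifier().fit_predict(X)
        b = ds.WaveformClassifier().fit_predict(X[perm])
        np.testing.assert_array_equal(a[perm], b)

    def test_amplitude_scale_covariance(self, clean_pool):
        _, _, wm, _ = clean_pool
        X = wm.values[:400]
        a = ds.WaveformClassifier().fit_predict(X)
        b = ds.WaveformClassifier().fit_predict(2.5 * X)
        np.testing.assert_array_equal(a, b)

    def test_single_type_pool_merges(self, clean_pool):
        _, _, wm, types = clean_pool
        only1 = wm.values[types == 1][:600]
        clf = ds.WaveformClassifier().fit(only1)
        assert clf.merged_single_type_
        assert set(clf.labels_[~clf.rejected_mask_]) == {1}

    def test_functional_wrapper_updates_events(self, clean_pool):
        rec, truth, wm, types = clean_pool
        events, report = ds.classify_wfbc(wm, truth)
        got = events["label_wfbc"].dropna().to_numpy(dtype=int)
        assert (got == types).mean() >= 0.95
        assert report["n_rejected"] == 0
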