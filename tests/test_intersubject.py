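"""Tests of cleaning, segment extraction and intersubject statistics."""

import numpy as np
import pytest

from beliefdyn.intersubject import (
    PatternSeriesSet,
    ROISeriesSet,
    SegmentSpec,
    clean_series,
    extract_segments,
    isfc,
    isfc_seed_map,
    ispc_timecourse,
    loo_isc,
    segment_indices,
    sliding_isc,
)
from tests.conftest import brute_force_loo_isc


def roi_set(data, tr=2.47, roi="test"):
    return ROISeriesSet(roi, np.asarray(data, dtype=float), tr)


class TestCleaning:
    def test_motion_regressor_input_projected_out(self):
        rng = np.random.default_rng(0)
        motion = rng.standard_normal((120, 6))
        data = np.tile(motion[:, 2], (3, 1))
        out = clean_series(roi_set(data, tr=1.0), motion, 0.01, 0.1)
        assert np.linalg.norm(out.data) < 1e-8 * np.linalg.norm(data)

    def test_band_pass_frequency_response(self):
        # 0.05 Hz sits inside the 0.01-0.1 Hz band; 0.5 Hz far outside.
        # gain measured away from the ends where filtfilt transients live
        t = np.arange(3000) * 0.5  # tr = 0.5 s, Nyquist 1 Hz
        for freq, lo, hi in [(0.05, 0.9, 1.1), (0.5, 0.0, 0.1)]:
            wave = np.sin(2 * np.pi * freq * t)
            out = clean_series(roi_set(np.tile(wave, (2, 1)), tr=0.5), None)
            gain = out.data[0, 500:-500].std() / wave[500:-500].std()
            assert lo <= gain <= hi, f"{freq} Hz gain {gain}"

    def test_constant_series_zeroed(self):
        out = clean_series(roi_set(np.full((2, 100), 7.0), tr=1.0), None)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-8)

    def test_band_edges_validated(self):
        with pytest.raises(ValueError, match="band"):
            clean_series(roi_set(np.zeros((2, 50)), tr=2.47), None,
                         low_hz=0.01, high_hz=0.3)  # above Nyquist


class TestSegments:
    def test_two_disjoint_windows_concatenate(self):
        data = roi_set(np.arange(200).reshape(1, -1).repeat(2, axis=0))
        seg, idx = extract_segments(data, SegmentSpec(np.array([10, 30]), 3))
        assert seg.shape == (2, 14)
        np.testing.assert_array_equal(idx, list(range(7, 14))
                                      + list(range(27, 34)))

    def test_overlapping_windows_merge(self):
        idx = segment_indices(np.array([10, 12]), 3, 200)
        np.testing.assert_array_equal(idx, np.arange(7, 16))

    def test_zero_half_width_returns_update_trs(self):
        idx = segment_indices(np.array([5, 9, 40]), 0, 100)
        np.testing.assert_array_equal(idx, [5, 9, 40])

    def test_merged_indices_match_interval_union_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            ups = np.unique(rng.integers(4, 96, size=6))
            hw = int(rng.integers(0, 5))
            got = segment_indices(ups, hw, 100)
            oracle = sorted({t for u in ups
                             for t in range(max(u - hw, 0), min(u + hw, 99) + 1)})
            np.testing.assert_array_equal(got, oracle)

    def test_provenance_reconstructs_original_samples(self, small_dataset):
        series = small_dataset.roi_series["PCN"]
        seg, idx = extract_segments(series, SegmentSpec(np.array([20, 50]), 4))
        np.testing.assert_array_equal(seg, series.data[:, idx])

    def test_empty_update_set_gives_empty_output(self):
        seg, idx = extract_segments(roi_set(np.zeros((2, 50))),
                                    SegmentSpec(np.array([], dtype=int), 3))
        assert seg.shape == (2, 0) and idx.size == 0

    def test_out_of_bounds_update_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            segment_indices(np.array([120]), 3, 100)


class TestLooISC:
    def test_identical_subjects_give_unit_correlation(self):
        base = np.sin(np.arange(50) / 3.0)
        vals = loo_isc(roi_set(np.tile(base, (5, 1))))
        np.testing.assert_allclose(vals, 1.0)

    def test_white_noise_is_uncorrelated(self):
        means = []
        for seed in range(20):
            data = np.random.default_rng(seed).standard_normal((10, 189))
            means.append(np.mean(loo_isc(roi_set(data))))
        assert abs(np.mean(means)) < 0.05

    def test_matches_brute_force_oracle(self):
        data = np.random.default_rng(2).standard_normal((3, 5))
        np.testing.assert_allclose(loo_isc(roi_set(data)),
                                   brute_force_loo_isc(data), atol=1e-12)

    def test_affine_rescaling_invariance(self):
        # Pearson invariance: rescaling one subject's series leaves that
        # subject's r unchanged (the left-out mean excludes it); a global
        # affine transform leaves every r unchanged
        rng = np.random.default_rng(3)
        data = rng.standard_normal((6, 40))
        base = loo_isc(roi_set(data))
        one = data.copy()
        one[2] = 3.5 * one[2] - 7.0
        assert loo_isc(roi_set(one))[2] == pytest.approx(base[2], abs=1e-10)
        np.testing.assert_allclose(loo_isc(roi_set(2.0 * data + 1.0)), base,
                                   atol=1e-10)

    def test_zero_variance_subject_reported_missing(self):
        data = np.random.default_rng(4).standard_normal((4, 30))
        data[1] = 2.0
        vals = loo_isc(roi_set(data))
        assert np.isnan(vals[1]) and np.isfinite(vals[[0, 2, 3]]).all()


class TestSlidingISC:
    def test_identical_subjects_capped_at_z_cap(self):
        from beliefdyn.intersubject import Z_CAP
        base = np.random.default_rng(5).standard_normal(80)
        res = sliding_isc(roi_set(np.tile(base, (4, 1))), window=21)
        # r is 1 up to float rounding; z saturates at (or just under) the cap
        assert np.all(res.z >= np.arctanh(1 - 1e-15))
        assert np.all(res.z <= Z_CAP)

    def test_planted_shared_interval_peaks_inside_it(self):
        rng = np.random.default_rng(6)
        shared = rng.standard_normal(189) * 3.0
        data = rng.standard_normal((8, 189))
        data[:, 50:81] += shared[50:81]
        res = sliding_isc(roi_set(data), window=21)
        assert 50 <= res.centers[np.argmax(res.z)] <= 80

    def test_single_window_consistent_with_whole_series_isc(self):
        from beliefdyn.intersubject import fisher_z
        data = np.random.default_rng(7).standard_normal((5, 60))
        res = sliding_isc(roi_set(data), window=60, step=1)
        assert res.z.shape == (1,)
        assert res.z[0] == pytest.approx(
            np.mean(fisher_z(loo_isc(roi_set(data)))), abs=1e-12)

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError, match="window"):
            sliding_isc(roi_set(np.zeros((3, 50))), window=3)


class TestISFC:
    def test_self_pair_equals_loo_isc(self):
        data = roi_set(np.random.default_rng(8).standard_normal((5, 60)))
        np.testing.assert_allclose(isfc(data, data), loo_isc(data), atol=1e-12)

    def test_independent_rois_uncorrelated(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = roi_set(rng.standard_normal((8, 150)))
            b = roi_set(rng.standard_normal((8, 150)))
            vals.append(np.mean(isfc(a, b)))
        assert abs(np.mean(vals)) < 0.05

    def test_large_lag_decorrelates(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal((6, 200))
        lagged = np.roll(base, 80, axis=1)
        vals = isfc(roi_set(base), roi_set(lagged))
        assert abs(np.mean(vals)) < 0.15

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        a, b = rng.standard_normal((2, 5, 20))
        got = isfc(roi_set(a), roi_set(b))
        for s in range(5):
            others = np.mean([b[j] for j in range(5) if j != s], axis=0)
            assert got[s] == pytest.approx(np.corrcoef(a[s], others)[0, 1],
                                           abs=1e-12)


class TestSeedMap:
    def _sets(self, seed, coupled):
        rng = np.random.default_rng(seed)
        seed_data = rng.standard_normal((8, 120)) + rng.standard_normal(120) * 2
        vox = rng.standard_normal((8, 120, 30))
        if coupled:
            shared = seed_data.mean(axis=0)
            vox[:, :, :10] += 2.0 * shared[None, :, None]
        return (ROISeriesSet("seed", seed_data, 1.0),
                PatternSeriesSet("targets", vox, 1.0))

    def test_voxel_equal_to_seed_mean_has_unit_correlation(self):
        rng = np.random.default_rng(11)
        seed_data = rng.standard_normal((6, 100))
        shared = seed_data.mean(axis=0)
        vox = np.tile(shared[None, :, None], (6, 1, 3))
        vox += 1e-6 * rng.standard_normal(vox.shape)
        res = isfc_seed_map(ROISeriesSet("s", np.tile(shared, (6, 1)), 1.0),
                            PatternSeriesSet("t", vox, 1.0))
        assert np.all(res.r > 0.99)

    def test_null_voxels_rarely_survive_fdr(self):
        empty = 0
        for seed in range(20):
            seed_set, targets = self._sets(seed, coupled=False)
            res = isfc_seed_map(seed_set, targets, q=0.001)
            empty += not res.fdr_mask.any()
        assert empty >= 19

    def test_planted_coupled_block_recovered(self):
        hits = miss = 0
        for seed in range(5):
            seed_set, targets = self._sets(100 + seed, coupled=True)
            res = isfc_seed_map(seed_set, targets, q=0.001)
            hits += res.display_mask[:10].mean() >= 0.8
            miss += res.fdr_mask[10:].sum()
        assert hits >= 4 and miss <= 2

    def test_empty_segment_rejected(self):
        seed_set, targets = self._sets(0, coupled=False)
        with pytest.raises(ValueError, match="empty segment"):
            isfc_seed_map(seed_set, targets,
                          SegmentSpec(np.array([], dtype=int), 3))


class TestISPC:
    def test_shared_patterns_give_unit_course(self):
        rng = np.random.default_rng(12)
        shared = rng.standard_normal((40, 20))
        data = np.tile(shared, (4, 1, 1))
        res = ispc_timecourse(PatternSeriesSet("r", data, 1.0))
        np.testing.assert_allclose(res, 1.0)

    def test_null_patterns_spread_matches_finite_voxel_count(self):
        rng = np.random.default_rng(13)
        n_vox = 50
        data = rng.standard_normal((10, 100, n_vox))
        res = ispc_timecourse(PatternSeriesSet("r", data, 1.0))
        # Fisher-z of a null spatial r over V voxels has SD ~ 1/sqrt(V - 3)
        z = np.arctanh(res)
        assert z.std() == pytest.approx(1 / np.sqrt(n_vox - 3), rel=0.15)

    def test_shared_template_at_one_tr_spikes_there(self):
        rng = np.random.default_rng(14)
        data = rng.standard_normal((6, 80, 25))
        template = rng.standard_normal(25) * 5
        data[:, 37, :] += template[None, :]
        res = ispc_timecourse(PatternSeriesSet("r", data, 1.0))
        course = np.nanmean(res, axis=0)
        assert np.argmax(course) == 37
        assert course[37] > 0.8

    def test_zero_variance_pattern_reported_missing(self):
        data = np.random.default_rng(15).standard_normal((3, 10, 5))
        data[0, 4, :] = 3.14
        res = ispc_timecourse(PatternSeriesSet("r", data, 1.0))
        assert np.isnan(res[0, 4])
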