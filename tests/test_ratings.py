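"""Unit tests for the rater-log -> update-course pipeline."""

import numpy as np
import pytest
from scipy import stats

from beliefdyn.ratings import (
    DomainAssociation,
    RaterEventLog,
    UpdateCourse,
    binarize_updates,
    domain_association,
    loess_smooth,
    mutual_information,
    rasterize_events,
    select_nonupdates,
    smooth_course,
    split_half_reliability,
    threshold_course,
)


def log(presses, duration=470.0, rid="r0"):
    return RaterEventLog(rid, np.asarray(presses, dtype=float), duration)


class TestRasterize:
    def test_single_press_covers_five_second_window(self):
        # press at 10 s with TR 2.47 s: TRs overlapping [10, 15) are 4, 5, 6
        course = rasterize_events([log([10.0])], tr=2.47, n_trs=20)
        expected = np.zeros(20)
        expected[4:7] = 1.0
        np.testing.assert_array_equal(course.values, expected)

    def test_duplicate_raters_leave_course_unchanged(self):
        one = rasterize_events([log([10.0])], 2.47, 20)
        two = rasterize_events([log([10.0], rid="a"), log([10.0], rid="b")],
                               2.47, 20)
        np.testing.assert_array_equal(one.values, two.values)

    def test_disjoint_boxcars_peak_at_one_over_n(self):
        logs = [log([30.0 * i + 10.0], rid=f"r{i}") for i in range(10)]
        course = rasterize_events(logs, tr=2.47, n_trs=150)
        assert course.values.max() == pytest.approx(0.1)
        assert course.values.min() == 0.0

    def test_rater_order_invariance(self):
        rng = np.random.default_rng(0)
        logs = [log(np.sort(rng.uniform(0, 400, 5)), rid=f"r{i}")
                for i in range(8)]
        a = rasterize_events(logs, 2.47, 189)
        b = rasterize_events(logs[::-1], 2.47, 189)
        np.testing.assert_array_equal(a.values, b.values)

    def test_press_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="presses"):
            log([500.0], duration=470.0)

    def test_unsorted_presses_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            log([20.0, 10.0])


class TestLoess:
    def test_constant_preserved(self):
        out = loess_smooth(np.full(50, 0.3), span=0.2)
        np.testing.assert_allclose(out, 0.3, atol=1e-12)

    def test_full_span_reproduces_line(self):
        ramp = np.linspace(0, 1, 40)
        np.testing.assert_allclose(loess_smooth(ramp, span=1.0), ramp,
                                   atol=1e-9)

    def test_impulse_matches_weighted_least_squares_oracle(self):
        # independent oracle: tricube-weighted quadratic polyfit per point
        rng = np.random.default_rng(3)
        y = rng.random(60)
        span = 0.25
        q = int(np.ceil(span * y.size))
        x = np.arange(y.size, dtype=float)
        smoothed = loess_smooth(y, span=span)
        for i in [0, 7, 29, 44, 59]:
            d = np.abs(x - i)
            idx = np.sort(np.argsort(d)[:q])
            w = (1 - (d[idx] / d[idx].max()) ** 3) ** 3
            coeffs = np.polynomial.polynomial.polyfit(
                x[idx] - i, y[idx], 2, w=np.sqrt(w))
            assert smoothed[i] == pytest.approx(coeffs[0], abs=1e-6)

    def test_impulse_mass_spreads_symmetrically(self):
        y = np.zeros(100)
        y[50] = 1.0
        out = loess_smooth(y, span=0.1)
        assert np.argmax(out) == 50
        np.testing.assert_allclose(out[51:60], out[49:40:-1], atol=1e-9)

    def test_too_narrow_span_rejected(self):
        with pytest.raises(ValueError, match="local fit"):
            loess_smooth(np.random.default_rng(0).random(20), span=0.05)

    def test_smooth_course_clamps_to_unit_interval(self):
        vals = np.zeros(40)
        vals[10:13] = 1.0
        course = smooth_course(UpdateCourse("states", vals, 2.47), span=0.3)
        assert course.values.min() >= 0.0 and course.values.max() <= 1.0


class TestBinarize:
    def test_final_tr_of_suprathreshold_run_selected(self):
        vals = np.array([0, 0, 0.9, 0.9, 0.9] + [0] * 15, dtype=float)
        ups = binarize_updates(UpdateCourse("states", vals, 2.47), 2.0)
        # mean + 2SD sits below 0.9 here, so the run 2..4 collapses to TR 4
        assert vals.mean() + 2 * vals.std(ddof=1) < 0.9
        np.testing.assert_array_equal(ups.update_trs, [4])

    def test_constant_course_yields_empty_set_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            ups = binarize_updates(UpdateCourse("states", np.full(30, 0.2),
                                                2.47), 2.0)
        assert len(ups) == 0

    def test_theta_zero_matches_run_scan_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.random(200)
        got = threshold_course(vals, 0.0)
        thr = vals.mean() + 0.0 * vals.std(ddof=1)
        expected = [t for t in range(200)
                    if vals[t] > thr and (t == 199 or vals[t + 1] <= thr)]
        np.testing.assert_array_equal(got, expected)

    def test_update_count_non_increasing_in_theta_on_rating_courses(
            self, small_updates):
        # on rough courses a rising threshold can split one run into two;
        # the sweep applies to the pipeline's smoothed rating courses, whose
        # isolated bumps shrink coherently as the threshold rises
        courses, _ = small_updates
        for course in courses.values():
            counts = [threshold_course(course.values, th).size
                      for th in np.arange(0.0, 3.01, 0.25)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestNonupdates:
    def _courses(self, vals):
        return {"states": UpdateCourse("states", vals, 2.47)}

    def test_update_neighbourhood_excluded(self):
        from beliefdyn.ratings import UpdatePointSet
        vals = np.linspace(0, 1, 100)
        ups = {"states": UpdatePointSet("states", [50], 2.0)}
        sel = select_nonupdates(self._courses(vals), ups, "states")
        assert not set(sel.update_trs) & {49, 50, 51}
        assert len(sel) == 1 and sel.update_trs[0] == 0  # lowest-rated TR

    def test_zero_updates_give_empty_set(self):
        from beliefdyn.ratings import UpdatePointSet
        ups = {"states": UpdatePointSet("states", [], 2.0)}
        sel = select_nonupdates(self._courses(np.ones(20) * 0.1), ups, "states")
        assert len(sel) == 0

    def test_matches_exhaustive_sort_and_filter_oracle(self):
        from beliefdyn.ratings import UpdatePointSet
        rng = np.random.default_rng(9)
        vals = rng.random(120)
        trs = {"states": [10, 40], "agents": [80]}
        ups = {d: UpdatePointSet(d, v, 2.0) for d, v in trs.items()}
        courses = {d: UpdateCourse(d, vals, 2.47) for d in trs}
        sel = select_nonupdates(courses, ups, "states")
        banned = {u + d for us in trs.values() for u in us for d in (-1, 0, 1)}
        eligible = sorted((t for t in range(120) if t not in banned),
                          key=lambda t: (vals[t], t))
        np.testing.assert_array_equal(sel.update_trs, np.sort(eligible[:2]))

    def test_shortfall_reported(self):
        from beliefdyn.ratings import UpdatePointSet
        ups = {"states": UpdatePointSet("states", [1, 4, 7], 2.0)}
        with pytest.raises(ValueError, match="shortfall"):
            select_nonupdates(
                {"states": UpdateCourse("states", np.ones(9) * 0.1, 2.47)},
                ups, "states")


class TestReliability:
    def test_identical_raters_give_unit_reliability(self):
        logs = [log([50.0, 150.0, 300.0], rid=f"r{i}") for i in range(6)]
        res = split_half_reliability(logs, 2.47, 189, n_splits=10, seed=0)
        assert res.mean == pytest.approx(1.0)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_independent_raters_give_near_zero_reliability(self):
        rng = np.random.default_rng(2)
        logs = [log(np.sort(rng.uniform(0, 460, 12)), rid=f"r{i}")
                for i in range(16)]
        res = split_half_reliability(logs, 2.47, 189, n_splits=100, seed=1)
        assert abs(res.mean) < 0.1

    def test_spearman_brown_formula(self):
        # the correction applied to r = 0.5 must give 2*0.5/1.5
        assert 2 * 0.5 / (1 + 0.5) == pytest.approx(0.667, abs=1e-3)

    def test_too_few_raters_rejected(self):
        with pytest.raises(ValueError, match="4 raters"):
            split_half_reliability([log([1.0]), log([2.0])], 2.47, 189)


class TestDomainAssociation:
    def test_self_correlation_and_entropy(self):
        rng = np.random.default_rng(4)
        vals = rng.random(500)
        courses = {"a": UpdateCourse("a", vals, 1.0),
                   "b": UpdateCourse("b", vals.copy(), 1.0)}
        res = domain_association(courses, max_lag=5)
        assert isinstance(res, DomainAssociation)
        row = res.pairwise.iloc[0]
        assert row.pearson_r == pytest.approx(1.0)
        # MI of a course with itself is the entropy of its binned marginal
        counts, _ = np.histogram(vals, bins=8)
        p = counts / counts.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert row.mutual_information == pytest.approx(entropy, abs=1e-12)

    def test_cross_correlation_peaks_at_shift(self):
        rng = np.random.default_rng(6)
        base = rng.random(300)
        k = 4
        shifted = np.roll(base, k)
        res = domain_association({"a": UpdateCourse("a", base, 1.0),
                                  "b": UpdateCourse("b", shifted, 1.0)},
                                 max_lag=8)
        prof = res.crosscorr[("a", "b")]
        assert res.lags[np.nanargmax(prof)] == k

    def test_gaussian_mutual_information_closed_form(self):
        rho = 0.5
        rng = np.random.default_rng(7)
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=10_000)
        mi = mutual_information(xy[:, 0], xy[:, 1], n_bins=8)
        assert mi == pytest.approx(-0.5 * np.log(1 - rho ** 2), abs=0.03)

    def test_constant_course_reported_missing(self):
        courses = {"a": UpdateCourse("a", np.ones(50), 1.0),
                   "b": UpdateCourse("b", np.random.default_rng(0).random(50),
                                     1.0)}
        res = domain_association(courses)
        assert np.isnan(res.pairwise.iloc[0].pearson_r)
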