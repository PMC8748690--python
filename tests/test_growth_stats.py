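import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from _oracles import boschloo_oracle, fisher_two_sided_oracle
from spherotil import growth_stats as gs
from spherotil import synthetic


class TestEllipticalVolume:
    def test_printed_formula(self):
        assert gs.elliptical_volume(10, 8) == pytest.approx(320.0)

    def test_square_tumor(self):
        assert gs.elliptical_volume(5, 5) == pytest.approx(62.5)

    def test_degenerate_width(self):
        assert gs.elliptical_volume(7, 0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gs.elliptical_volume(-1, 2)


class TestRValue:
    def test_fivefold_growth(self):
        assert gs.r_value(100, 500, dt_h=8) == pytest.approx(0.5)

    def test_no_growth(self):
        assert gs.r_value(250, 250) == 0.0

    def test_qg_cancellation_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            vi, vf = rng.uniform(1, 2000, 2)
            assert gs.r_value(vi, vf) == pytest.approx(
                gs.r_value(vi, vf, explicit_qg=True), rel=1e-14)

    def test_zero_initial_rejected(self):
        with pytest.raises(ValueError):
            gs.r_value(0, 100)


class TestClassifyCourse:
    @staticmethod
    def _course(volumes, days=None):
        days = days if days is not None else 12 + 2 * np.arange(len(volumes))
        dims = np.array([synthetic._dims_from_volume(v) for v in volumes])
        return gs.TumorCourse(mouse="m", group="g", days=days,
                              length_mm=dims[:, 0], width_mm=dims[:, 1])

    def test_monotone_growth_not_responder(self):
        st_ = gs.classify_course(self._course([60, 80, 110, 150, 200]))
        assert not st_.responder and not st_.relapsed

    def test_dip_and_recross_is_relapse(self):
        st_ = gs.classify_course(self._course([60, 25, 24, 30, 80]))
        assert st_.responder and st_.relapsed

    def test_single_dip_not_responder(self):
        st_ = gs.classify_course(self._course([60, 25, 70, 90, 120]))
        assert not st_.responder

    def test_deep_remission_flag(self):
        # 10 mm3 -> ~3.1 mm length: both dims < 5 mm over >= 8 days
        st_ = gs.classify_course(self._course([60, 10, 9, 9, 9, 9, 9]))
        assert st_.responder and st_.stable_remission and not st_.relapsed

    def test_scale_invariance(self):
        v = [60, 25, 24, 30, 80]
        a = gs.classify_course(self._course(v))
        b = gs.classify_course(self._course([x * 7.3 for x in v]))
        assert (a.responder, a.relapsed) == (b.responder, b.relapsed)

    def test_short_course_rejected(self):
        with pytest.raises(ValueError):
            gs.classify_course(self._course([60, 70]))

    def test_cohort_relapse_fraction_within_binomial_ci(self):
        p_gen = 0.6
        courses, truth = synthetic.make_growth_cohort(
            n_mice=40, groups={"A": p_gen}, seed=7)
        flags = [gs.classify_course(c).relapsed for c in courses]
        assert flags == truth.relapsed            # exact recovery, noiseless
        lo, hi = sps.binom.ppf([0.005, 0.995], len(flags), p_gen)
        assert lo <= sum(flags) <= hi


class TestFisherExact:
    def test_relapse_table(self):
        assert gs.fisher_exact(((8, 2), (3, 9))) == pytest.approx(
            fisher_two_sided_oracle(8, 2, 3, 9), rel=1e-10)
        assert gs.fisher_exact(((8, 2), (3, 9))) == pytest.approx(0.0300, abs=2e-4)

    def test_depletion_table(self):
        assert gs.fisher_exact(((6, 0), (5, 14))) == pytest.approx(
            fisher_two_sided_oracle(6, 0, 5, 14), rel=1e-10)
        assert gs.fisher_exact(((6, 0), (5, 14))) == pytest.approx(0.00261, abs=5e-5)

    def test_symmetric_table(self):
        assert gs.fisher_exact(((5, 5), (5, 5))) == pytest.approx(1.0)

    @given(st.tuples(st.integers(0, 10), st.integers(0, 10),
                     st.integers(0, 10), st.integers(0, 10)))
    @settings(max_examples=120, deadline=None)
    def test_matches_enumeration_oracle(self, tbl):
        a, b, c, d = tbl
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        assert gs.fisher_exact(((a, b), (c, d))) == pytest.approx(
            fisher_two_sided_oracle(a, b, c, d), rel=1e-9, abs=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            gs.Contingency2x2(-1, 2, 3, 4)


class TestBoschloo:
    def test_matches_enumeration_oracle(self):
        for tbl in [(8, 2, 3, 9), (6, 0, 5, 14), (4, 6, 7, 3)]:
            assert gs.boschloo(((tbl[0], tbl[1]), (tbl[2], tbl[3])), grid_size=501) \
                == pytest.approx(boschloo_oracle(*tbl, n_grid=501), abs=2e-3)

    def test_not_larger_than_fisher(self):
        # Boschloo is uniformly at least as powerful as Fisher
        p_b = gs.boschloo(((8, 2), (3, 9)))
        p_f = 2 * gs.fisher_exact_one_sided(((8, 2), (3, 9)), "greater")
        assert p_b <= p_f + 1e-12

    def test_no_evidence_capped_at_one(self):
        assert gs.boschloo(((5, 0), (5, 0))) == 1.0

    def test_grid_convergence(self):
        p200 = gs.boschloo(((8, 2), (3, 9)), grid_size=200)
        p600 = gs.boschloo(((8, 2), (3, 9)), grid_size=600)
        assert abs(p200 - p600) < 1e-3

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            gs.boschloo(((1, 1), (1, 1)), grid_size=5)

    def test_matches_scipy_one_sided(self):
        # scipy treats columns as the binomial samples; transpose to match
        # our rows-are-groups convention
        from scipy.stats import boschloo_exact
        res = boschloo_exact([[8, 3], [2, 9]], alternative="greater", n=256)
        ours = gs.boschloo(((8, 2), (3, 9)), grid_size=256, alternative="one-sided")
        assert ours == pytest.approx(res.pvalue, abs=2e-3)


class TestPropZtest:
    def test_equal_proportions(self):
        z, p = gs.prop_ztest(5, 10, 10, 20)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_translocation_comparison_significant(self):
        _, p = gs.prop_ztest(71, 100, 23, 100)
        assert p < 1e-4

    def test_chi_square_equivalence(self):
        z, _ = gs.prop_ztest(30, 80, 12, 60)
        chi2 = sps.chi2_contingency([[30, 50], [12, 48]], correction=False)[0]
        assert z**2 == pytest.approx(chi2, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gs.prop_ztest(1, 10, 0, 0)


class TestSampleSize:
    def test_unit_difference(self):
        assert gs.sample_size(1.0) == 24          # ceil(2 * 11.7)

    def test_double_difference(self):
        assert gs.sample_size(2.0) == 6           # ceil(5.85)

    def test_large_difference_floors_at_one(self):
        assert gs.sample_size(1e6) == 1

    def test_invalid(self):
        with pytest.raises(ValueError):
            gs.sample_size(0.0)


class TestExcludeOutliers:
    @staticmethod
    def _course(name, v12, v16):
        days = np.array([12.0, 14.0, 16.0])
        vols = np.array([v12, (v12 + v16) / 2, v16])
        dims = np.array([synthetic._dims_from_volume(v) for v in vols])
        return gs.TumorCourse(mouse=name, group="g", days=days,
                              length_mm=dims[:, 0], width_mm=dims[:, 1])

    def test_identical_courses_none_excluded(self):
        courses = [self._course(f"m{i}", 60, 120) for i in range(6)]
        assert len(gs.exclude_outliers(courses)) == 6

    def test_extreme_course_excluded(self):
        courses = [self._course(f"m{i}", 60, 100 + i) for i in range(8)]
        courses.append(self._course("fast", 60, 1200))
        kept = gs.exclude_outliers(courses)
        assert len(kept) == 8
        assert all(c.mouse != "fast" for c in kept)

    def test_slow_growers_kept(self):
        # one-sided rule: an unusually SLOW course stays in
        courses = [self._course(f"m{i}", 60, 100 + i) for i in range(8)]
        courses.append(self._course("slow", 60, 20))
        assert len(gs.exclude_outliers(courses)) == 9

    def test_empty_cohort(self):
        assert gs.exclude_outliers([]) == []
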