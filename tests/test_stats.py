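import numpy as np
import pandas as pd
import pytest

import nucleoflux as nf
from nucleoflux.stats import TimeCourse


def make_tc(values, tps=None):
    values = np.asarray(values, dtype=float)
    if tps is None:
        tps = 15.0 * (1 + np.arange(len(values)))
    return TimeCourse(tps, values, np.zeros(len(values)), np.full(len(values), 50))


@pytest.fixture(scope="module")
def noiseless_hela_tc():
    cfg = nf.hela_config()
    return make_tc(nf.noiseless_trace(cfg), np.asarray(cfg.timepoints))


class TestAssemble:
    def test_constant_table(self):
        rows = []
        for t in (15, 30, 45):
            for c in range(5):
                rows.append((1, c, t, "nucleolar", 7.0))
        table = pd.DataFrame(rows, columns=["experiment", "cell", "timepoint_min", "compartment", "intensity"])
        tc = nf.assemble_timecourse(table, "nucleolar")
        assert np.all(tc.mean == 7.0)
        assert np.all(tc.sem == 0.0)
        assert np.all(tc.n == 5)

    def test_hand_arithmetic_sem(self):
        rows = [(1, 0, t, "nucleolar", v) for t in (15, 30, 45) for v in (1.0, 3.0)]
        table = pd.DataFrame(rows, columns=["experiment", "cell", "timepoint_min", "compartment", "intensity"])
        tc = nf.assemble_timecourse(table, "nucleolar")
        assert tc.mean == pytest.approx([2.0, 2.0, 2.0])
        assert tc.sem == pytest.approx([1.0, 1.0, 1.0])

    def test_single_cell_timepoint_rejected(self):
        rows = [(1, 0, 15, "nucleolar", 1.0), (1, 1, 15, "nucleolar", 2.0),
                (1, 0, 30, "nucleolar", 1.0),
                (1, 0, 45, "nucleolar", 1.0), (1, 1, 45, "nucleolar", 2.0)]
        table = pd.DataFrame(rows, columns=["experiment", "cell", "timepoint_min", "compartment", "intensity"])
        with pytest.raises(ValueError):
            nf.assemble_timecourse(table, "nucleolar")

    def test_simulated_means_near_kinetics(self, hela_table):
        tc = nf.assemble_timecourse(hela_table, "nucleolar")
        expected = nf.noiseless_trace(nf.hela_config())
        # batch noise dominates the per-point spread; allow 3 x (batch + sem)
        tol = 3 * (0.07 * expected + tc.sem)
        assert np.all(np.abs(tc.mean - expected) <= tol)


class TestCV:
    def test_constant_trace_zero(self):
        assert nf.coefficient_of_variation(make_tc([5, 5, 5, 5])) == 0.0

    def test_noiseless_hela_value(self, noiseless_hela_tc):
        assert nf.coefficient_of_variation(noiseless_hela_tc) == pytest.approx(0.267, abs=0.002)

    def test_scale_invariance(self, noiseless_hela_tc):
        scaled = make_tc(noiseless_hela_tc.mean * 37.5, noiseless_hela_tc.timepoints)
        assert nf.coefficient_of_variation(scaled) == pytest.approx(
            nf.coefficient_of_variation(noiseless_hela_tc), rel=1e-12
        )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            nf.coefficient_of_variation(make_tc([1.0, -1.0, 0.0]))


class TestPeriodogram:
    def test_pure_cosine_recovers_period(self):
        tps = np.arange(15.0, 151.0, 15.0)
        for period in (50.0, 60.0, 75.0):
            tc = make_tc(10 + np.cos(2 * np.pi * tps / period), tps)
            assert nf.dominant_period(nf.periodogram(tc)) == pytest.approx(period, abs=1.0)

    def test_constant_trace_all_zero(self):
        pg = nf.periodogram(make_tc([4.0] * 10))
        assert np.allclose(pg.amplitudes, 0.0)
        with pytest.raises(ValueError):
            nf.dominant_period(pg)

    def test_shift_invariance(self, noiseless_hela_tc):
        shifted = make_tc(noiseless_hela_tc.mean + 123.0, noiseless_hela_tc.timepoints)
        a = nf.periodogram(noiseless_hela_tc).amplitudes
        b = nf.periodogram(shifted).amplitudes
        assert np.allclose(a, b, atol=1e-9)

    def test_noiseless_hela_dominant_period_band(self, noiseless_hela_tc):
        """The deterministic trace peaks within the 60 +- 5 min band."""
        p = nf.dominant_period(nf.periodogram(noiseless_hela_tc))
        assert abs(p - 60.0) <= 5.0

    def test_invalid_grid_rejected(self, noiseless_hela_tc):
        with pytest.raises(ValueError):
            nf.periodogram(noiseless_hela_tc, periods=[-5.0, 10.0])

    def test_tie_breaks_to_smaller_period(self):
        pg = nf.Periodogram(np.array([40.0, 50.0, 60.0]), np.array([1.0, 2.0, 2.0]))
        assert nf.dominant_period(pg) == 50.0


class TestPeriodInterval:
    def test_sampling_uncertainty_band(self):
        assert nf.period_interval(60.0, 15.0) == (45.0, 75.0)
        assert nf.period_interval(100.0, 15.0) == (85.0, 115.0)

    def test_collapses_as_interval_shrinks(self):
        low, high = nf.period_interval(60.0, 1e-9)
        assert low == pytest.approx(60.0) and high == pytest.approx(60.0)

    def test_period_not_exceeding_interval_rejected(self):
        with pytest.raises(ValueError):
            nf.period_interval(10.0, 15.0)


class TestCorrelationAndFold:
    def test_self_correlation(self, noiseless_hela_tc):
        assert nf.pearson_correlation(noiseless_hela_tc, noiseless_hela_tc) == pytest.approx(1.0)

    def test_reflected_correlation(self, noiseless_hela_tc):
        reflected = make_tc(
            2 * np.mean(noiseless_hela_tc.mean) - noiseless_hela_tc.mean,
            noiseless_hela_tc.timepoints,
        )
        assert nf.pearson_correlation(noiseless_hela_tc, reflected) == pytest.approx(-1.0)

    def test_affine_invariance(self, noiseless_hela_tc):
        other = make_tc(3.0 * noiseless_hela_tc.mean + 11.0, noiseless_hela_tc.timepoints)
        assert nf.pearson_correlation(noiseless_hela_tc, other) == pytest.approx(1.0)

    def test_zero_variance_rejected(self, noiseless_hela_tc):
        flat = make_tc(np.full(10, 3.0), noiseless_hela_tc.timepoints)
        with pytest.raises(ValueError):
            nf.pearson_correlation(noiseless_hela_tc, flat)

    def test_threefold_increase_15_to_30(self, noiseless_hela_tc):
        assert nf.fold_change(noiseless_hela_tc, 15.0, 30.0) == pytest.approx(3.0, rel=1e-9)
        assert nf.fold_change(noiseless_hela_tc, 45.0, 45.0) == 1.0

    def test_fold_scale_invariance(self, noiseless_hela_tc):
        scaled = make_tc(noiseless_hela_tc.mean * 9.0, noiseless_hela_tc.timepoints)
        assert nf.fold_change(scaled, 15.0, 30.0) == pytest.approx(
            nf.fold_change(noiseless_hela_tc, 15.0, 30.0)
        )

    def test_missing_timepoint_rejected(self, noiseless_hela_tc):
        with pytest.raises(ValueError):
            nf.fold_change(noiseless_hela_tc, 17.0, 30.0)


class TestStudentsT:
    def test_identical_groups(self):
        t, p = nf.students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_equal_means(self):
        assert nf.students_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_degenerate_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            nf.students_t([2.0, 2.0], [3.0, 3.0])

    def test_matches_pooled_formula(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        t, p = nf.students_t(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_manual = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_manual, rel=1e-9)

    def test_strong_effect_significant(self):
        """n=50 draws from the 15- vs 30-min unit-intensity distributions."""
        rng = np.random.default_rng(11)
        lo = 75.0 * rng.lognormal(-0.043, 0.294, 50)
        hi = 225.0 * rng.lognormal(-0.043, 0.294, 50)
        _, p = nf.students_t(lo, hi)
        assert p < 1e-4


class TestTimeCourseValidation:
    def test_uneven_spacing_rejected(self):
        with pytest.raises(ValueError):
            TimeCourse(np.array([15.0, 30.0, 60.0]), np.ones(3), np.zeros(3), np.full(3, 5))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            TimeCourse(np.array([15.0, 30.0]), np.ones(2), np.zeros(2), np.full(2, 5))
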