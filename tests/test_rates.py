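"""Detection correction, rate/mutation-rate estimators, MA+WGS arithmetic,
Welch and unconditional exact comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mutltrace as mt
from mutltrace.rates import experiment_rates, long_exposure_generations


def brute_force_detection(tau_s, dt_s, n, rng):
    """Independent oracle: place Exp(tau) foci at uniform phase on the grid."""
    life = rng.exponential(tau_s, n)
    phase = rng.uniform(0, dt_s, n)  # time from onset to the next frame
    return float((phase < life).mean())


class TestDetectionProbability:
    def test_limits(self):
        assert mt.detection_probability(1e9, 120.0) == pytest.approx(1.0, abs=1e-6)
        assert mt.detection_probability(40.0, 1e-6) == pytest.approx(1.0, abs=1e-6)
        assert mt.detection_probability(40.0, 120.0) == pytest.approx(0.3167, abs=2e-4)

    def test_matches_brute_force_placement(self):
        rng = np.random.default_rng(0)
        for ratio in (0.1, 0.33, 1.0, 3.0):
            tau, dt = 40.0, 40.0 / ratio
            p = mt.detection_probability(tau, dt)
            n = 200_000
            phat = brute_force_detection(tau, dt, n, rng)
            assert abs(p - phat) < 4 * math.sqrt(p * (1 - p) / n)

    def test_invalid_inputs(self):
        for bad in ((0, 10), (10, -1), (math.nan, 10)):
            with pytest.raises(ValueError):
                mt.detection_probability(*bad)


class TestCorrectedTotalRate:
    def test_full_detection_equals_raw(self):
        r = mt.corrected_total_rate(100, 10, 1000.0, 1.0)
        assert r.corrected_rate_per_min == r.raw_rate_per_min

    def test_zero_short(self):
        r = mt.corrected_total_rate(0, 25, 1000.0, 0.3)
        assert r.corrected_rate_per_min == pytest.approx(25 / 1000.0)

    def test_correction_never_decreases(self):
        r = mt.corrected_total_rate(100, 10, 1000.0, 0.3)
        assert r.corrected_rate_per_min >= r.raw_rate_per_min
        assert r.ci_per_min[0] < r.corrected_rate_per_min < r.ci_per_min[1]

    def test_generation_units_consistent(self):
        r = mt.corrected_total_rate(50, 5, 2660.0, 0.5, doubling_min=26.6)
        assert r.corrected_rate_per_generation == pytest.approx(
            r.corrected_rate_per_min * 26.6)
        assert r.ci_per_generation[1] == pytest.approx(r.ci_per_min[1] * 26.6)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            mt.corrected_total_rate(1, 1, 10.0, 0.0)
        with pytest.raises(ValueError):
            mt.corrected_total_rate(1, 1, 10.0, 1.2)

    def test_fine_interval_correction_is_tiny(self, fine_dt_spans):
        # at dt=7.5 s, p ~ 0.91: correcting changes the estimate by the
        # detection shortfall only, and raw/corrected differ by ~ 1/p
        p = mt.detection_probability(40.0, 7.5)
        r = mt.corrected_total_rate(len(fine_dt_spans), 0, 56000.0, p)
        assert r.corrected_rate_per_min / r.raw_rate_per_min == pytest.approx(1 / p)


class TestPoissonCI:
    def test_zero_count_upper_bound(self):
        lo, hi = mt.poisson_ci(0)
        assert lo == 0.0
        assert hi == pytest.approx(3.689, abs=1e-3)

    def test_mutation_rate_from_zero_long_foci(self):
        r = mt.mutation_rate_from_long_foci(0, 1000.0)
        assert r.corrected_rate_per_generation == 0.0
        assert r.ci_per_generation[1] == pytest.approx(3.689 / 1000.0, rel=1e-3)

    def test_doubling_generations_halves_rate(self):
        a = mt.mutation_rate_from_long_foci(40, 1000.0)
        b = mt.mutation_rate_from_long_foci(40, 2000.0)
        assert a.corrected_rate_per_generation == pytest.approx(
            2 * b.corrected_rate_per_generation)


class TestMAWGS:
    def test_generations_per_cycle(self):
        assert mt.generations_per_cycle(5e8) == pytest.approx(28.897, abs=1e-3)
        assert mt.generations_per_cycle(2.0) == 1.0
        with pytest.raises(ValueError):
            mt.generations_per_cycle(1.0)

    def test_rate_arithmetic(self):
        inp = mt.MAWGSInput(n_mutations=58, n_lines=4, dilution_factor=5e8, n_cycles=2)
        rate, ci = mt.ma_wgs_rate(inp)
        assert rate == pytest.approx(58 / (4 * math.log2(5e8) * 2))
        assert ci[0] < rate < ci[1]

    def test_invalid_design(self):
        with pytest.raises(ValueError):
            mt.MAWGSInput(n_mutations=-1, n_lines=4, dilution_factor=5e8, n_cycles=2)
        with pytest.raises(ValueError):
            mt.MAWGSInput(n_mutations=5, n_lines=4, dilution_factor=0.5, n_cycles=2)


class TestWelch:
    def test_identical_samples(self):
        a = [0.1, 0.2, 0.3]
        t, p = mt.compare_rate_estimates(a, a)
        assert p == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 2, 20)
        _, p1 = mt.compare_rate_estimates(a, b)
        _, p2 = mt.compare_rate_estimates(b, a)
        assert p1 == pytest.approx(p2)

    def test_detects_unit_shift(self):
        rng = np.random.default_rng(2)
        detected = sum(
            mt.compare_rate_estimates(rng.normal(0, 1, 50), rng.normal(1, 1, 50))[1] < 0.01
            for _ in range(20)
        )
        assert detected == 20


class TestRepairFailureFraction:
    def test_recovers_failure_prob(self, wt_longterm_experiment):
        params, traces, foci = wt_longterm_experiment
        nwf = mt.ImagingConfig(120.0).n_frames(traces[0].window_min)
        r = experiment_rates(foci, [t.window_min for t in traces], nwf)
        lo, hi = r["failure_fraction_ci"]
        realized = sum(int(t.unrepaired.sum()) for t in traces) / sum(t.n_events for t in traces)
        assert lo < realized < hi
        assert r["failure_fraction"] == pytest.approx(0.01, abs=0.004)

    def test_zero_long(self):
        frac, (lo, hi) = mt.repair_failure_fraction(0, 500.0)
        assert frac == 0.0 and lo == 0.0 and 0 < hi < 0.02

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            mt.repair_failure_fraction(10, 5.0)


class TestBarnard:
    def test_similar_rows_large_p(self):
        assert mt.barnard_exact_score([[3, 297], [4, 296]]).pvalue > 0.5

    def test_strong_difference_small_p(self):
        assert mt.barnard_exact_score([[0, 300], [30, 270]]).pvalue < 0.001

    def test_identical_rows_p_one(self):
        r = mt.barnard_exact_score([[5, 5], [5, 5]])
        assert r.pvalue == pytest.approx(1.0)
        assert r.statistic == 0.0

    def test_matches_scipy_unconditional(self):
        # scipy fixes column totals, so pass the transpose
        tables = [[[7, 12], [3, 8]], [[10, 5], [3, 12]], [[2, 28], [8, 22]],
                  [[0, 5], [5, 0]], [[12, 48], [25, 35]]]
        for t in tables:
            mine = mt.barnard_exact_score(t).pvalue
            ref = stats.barnard_exact(np.transpose(t), pooled=True, n=128).pvalue
            assert mine == pytest.approx(ref, abs=5e-3)

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            mt.barnard_exact_score([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            mt.barnard_exact_score([[0, 0], [1, 1]])


class TestAgeBinned:
    def _classified(self, wt_longterm_experiment):
        params, traces, foci = wt_longterm_experiment
        nwf = mt.ImagingConfig(120.0).n_frames(traces[0].window_min)
        return mt.classify_foci(mt.drop_edge_foci(foci, nwf), 14.0)

    def test_stable_failure_rate_not_flagged(self, wt_longterm_experiment):
        clf = self._classified(wt_longterm_experiment)
        res = mt.age_binned_analysis(clf)
        assert len(res.bins) == 10
        assert res.endpoint_pvalue > 0.05
        assert (res.bins["n_total"] > 0).all()

    def test_requires_labels(self):
        with pytest.raises(ValueError, match="label"):
            mt.age_binned_analysis(pd.DataFrame({"onset_frame": [1], "frame_interval_s": [120.0]}))

    def test_injected_age_effect_detected(self, wt_longterm_experiment):
        clf = self._classified(wt_longterm_experiment).copy()
        gen = clf["onset_frame"] * 2.0 / 26.6
        # make the last 10 generations strongly failure-prone
        old = gen >= 90
        rng = np.random.default_rng(5)
        clf.loc[old & (rng.random(len(clf)) < 0.2), "label"] = "long"
        res = mt.age_binned_analysis(clf)
        assert res.endpoint_pvalue < 0.001


class TestFoldChange:
    def test_equal_rates(self):
        ratio, (lo, hi) = mt.fold_change(50, 100.0, 50, 100.0)
        assert ratio == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_zero_numerator(self):
        ratio, (lo, hi) = mt.fold_change(0, 100.0, 20, 100.0)
        assert ratio == 0.0 and lo == 0.0 and np.isfinite(hi)

    def test_twofold_difference_detected(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(20):
            n_a = rng.poisson(100)
            n_b = rng.poisson(200)
            _, (lo, hi) = mt.fold_change(n_a, 1000.0, n_b, 1000.0)
            hits += hi < 1.0
        assert hits >= 16  # CI excludes 1 in >= 80% of draws

    def test_exposure_adjustment(self):
        ratio, _ = mt.fold_change(50, 100.0, 50, 200.0)
        assert ratio == pytest.approx(2.0)


class TestExperimentRates:
    def test_recovers_total_and_mutation_rate(self, wt_longterm_experiment):
        params, traces, foci = wt_longterm_experiment
        nwf = mt.ImagingConfig(120.0).n_frames(traces[0].window_min)
        r = experiment_rates(foci, [t.window_min for t in traces], nwf)
        truth_total = params.error_rate_per_min * 26.6
        assert r["total"].corrected_rate_per_generation == pytest.approx(truth_total, rel=0.05)
        lo, hi = r["mutation"].ci_per_generation
        # the realized unrepaired count drives the estimate
        n_true = sum(int(t.unrepaired.sum()) for t in traces)
        gens = long_exposure_generations([t.window_min for t in traces])
        assert lo < n_true / gens * 0.999 and hi > n_true / gens * 0.9

    def test_long_exposure_short_window(self):
        assert long_exposure_generations([10.0], doubling_min=26.6) == 0.0
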