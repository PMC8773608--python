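"""Bootstrap Z-tests, t-tests, JZS Bayes factors, correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import magcomp as m
from magcomp.errors import (
    DegenerateModelError,
    InsufficientDataError,
    InvalidArgumentError,
)


class TestZCompare:
    def test_hand_arithmetic(self):
        res = m.z_compare((0.0, 3.0), (3.0, 4.0))
        assert res.statistic == pytest.approx(0.6)

    def test_identical_distributions(self):
        res = m.z_compare((500.0, 5.0), (500.0, 5.0))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    @given(
        ma=st.floats(-100, 100), mb=st.floats(-100, 100),
        sa=st.floats(0.1, 50), sb=st.floats(0.1, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, ma, mb, sa, sb):
        r1 = m.z_compare((ma, sa), (mb, sb))
        r2 = m.z_compare((mb, sb), (ma, sa))
        assert r1.statistic == r2.statistic
        assert r1.p_value == r2.p_value

    def test_zero_combined_variance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            m.z_compare((1.0, 0.0), (2.0, 0.0))


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,k,expected", [(0.05, 3, 0.05 / 3), (0.05, 1, 0.05), (0.01, 5, 0.002)]
    )
    def test_threshold(self, alpha, k, expected):
        assert m.bonferroni_alpha(alpha, k) == pytest.approx(expected)

    def test_three_comparison_threshold_rounds_to_printed_value(self):
        assert round(m.bonferroni_alpha(0.05, 3), 3) == 0.017


class TestTCompare:
    def test_all_zero_differences(self):
        x = np.array([500.0, 600.0, 700.0, 550.0])
        res = m.t_compare(x, x)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.effect_size_d == 0.0

    def test_constant_nonzero_difference_flagged(self):
        base = np.array([500.0, 600.0, 700.0])
        with pytest.raises(DegenerateModelError):
            m.t_compare(base * 1.1, base)  # constant log-unit shift

    def test_log_units_make_t_scale_free(self):
        rng = np.random.default_rng(0)
        base = 600 * np.exp(rng.normal(0, 0.05, 15))
        cond = base * np.exp(rng.normal(-0.07, 0.03, 15))
        r1 = m.t_compare(cond, base)
        r2 = m.t_compare(cond * 10, base * 10)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_matches_scipy_paired_t(self):
        rng = np.random.default_rng(1)
        base = 600 * np.exp(rng.normal(0, 0.05, 15))
        cond = base * np.exp(rng.normal(-0.07, 0.03, 15))
        res = m.t_compare(cond, base)
        from scipy.stats import ttest_rel

        ref = ttest_rel(np.log10(cond), np.log10(base))
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)
        assert res.df == 14

    def test_power_against_running_dilation(self, duration_plan, run_observer):
        # with the dilation gain on, the paired test on per-participant
        # PSEs should detect the effect in essentially every cohort
        detected = 0
        n_rep = 100
        streams = np.random.SeedSequence(77).spawn(n_rep)
        for ss in streams:
            s = int(ss.generate_state(1)[0] % 2**31)
            trials = m.simulate_cohort(
                duration_plan, m.CohortParams(seed=s), run_observer
            )
            per_run = m.aggregate_proportions(trials, "per_participant", "RUN_TEST")
            per_t1 = m.aggregate_proportions(trials, "per_participant", "T1")
            run = np.array([m.fit_gaussian(per_run[p]).pse for p in sorted(per_run)])
            t1 = np.array([m.fit_gaussian(per_t1[p]).pse for p in sorted(per_t1)])
            if m.t_compare(run, t1, alpha_corrected=0.05).significant:
                detected += 1
        assert detected >= 0.95 * n_rep


class TestJzsBayesFactor:
    def test_agrees_with_independent_implementation(self):
        # cross-check the quad integration against pingouin's JZS
        # implementation (g-prior integral route)
        pg = pytest.importorskip("pingouin")
        for t in (-5.0, -1.2, 0.0, 0.21, 2.5, 7.27):
            mine = m.jzs_log10_bf(t, 15)
            ref = float(np.log10(float(pg.bayesfactor_ttest(t, 15, paired=True,
                                                            r=0.707))))
            assert mine == pytest.approx(ref, abs=1e-6)

    def test_monotone_in_absolute_t(self):
        vals = [m.jzs_log10_bf(t, 15) for t in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(vals) > 0)

    def test_null_favoured_at_t_zero(self):
        for n in (3, 10, 15, 50):
            assert m.jzs_log10_bf(0.0, n) < 0  # BF10 < 1

    def test_prior_scale_and_n_validation(self):
        with pytest.raises(InvalidArgumentError):
            m.jzs_log10_bf(1.0, 1)
        with pytest.raises(InvalidArgumentError):
            m.jzs_log10_bf(1.0, 15, cauchy_scale=0.0)


class TestBootstrap:
    def test_seed_determinism(self, cohort_trials):
        a = m.bootstrap_pse(cohort_trials, "RUN_TEST", 50, seed=5)
        b = m.bootstrap_pse(cohort_trials, "RUN_TEST", 50, seed=5)
        assert np.array_equal(a.peaks, b.peaks)
        assert a.n_iterations == 50

    def test_single_iteration_structure(self, cohort_trials):
        d = m.bootstrap_pse(cohort_trials, "T1", 1, seed=2)
        assert d.peaks.size + d.n_failed == 1

    def test_mean_peak_brackets_point_estimate(self, cohort_trials):
        fit = m.fit_gaussian(
            m.aggregate_proportions(cohort_trials, "aggregate", "RUN_TEST")
        )
        d = m.bootstrap_pse(cohort_trials, "RUN_TEST", 500, seed=11)
        assert abs(d.mean_peak - fit.pse) < 2 * d.se_peak

    def test_se_shrinks_with_more_data(self, duration_set, run_observer):
        ses = []
        for reps, seed in ((4, 1), (40, 2)):
            sched = m.build_decoding_schedule(duration_set, reps, 3 * reps,
                                              seed=seed)
            trials = m.simulate_trials(sched, 600.0, run_observer,
                                       phase="RUN_TEST", seed=seed)
            ses.append(m.bootstrap_pse(trials, "RUN_TEST", 300, seed=seed).se_peak)
        assert ses[1] < ses[0] / 2  # ~sqrt(10) expected


@pytest.fixture(scope="module")
def after_run_trials():
    plan = m.build_session_plan("duration_after", n_blocks=2)
    return m.simulate_cohort(
        plan, m.CohortParams(seed=21), m.duration_observer_params()
    )


class TestMedianSplit:
    def test_halves_are_balanced(self, after_run_trials):
        res = m.median_split_compare(after_run_trials, n_iterations=100, seed=3)
        assert set(res) == {"early", "late"}
        for half in res.values():
            assert half.n_baseline == half.n_test
        total = res["early"].n_baseline + res["late"].n_baseline
        assert total == (after_run_trials["phase"] == "T1").sum()
        # 66-trial phases split 33/34 per participant-phase (ties early)
        assert res["early"].n_baseline >= res["late"].n_baseline

    def test_both_halves_fit_and_compare(self, after_run_trials):
        res = m.median_split_compare(after_run_trials, n_iterations=200, seed=7)
        for half in res.values():
            assert half.baseline_fit.converged and half.test_fit.converged
            assert half.comparison.statistic_kind == "bootstrap_z"

    def test_identical_timestamps_flagged(self, after_run_trials):
        frozen = after_run_trials.assign(seconds_since_phase_start=0.0)
        with pytest.raises(InsufficientDataError):
            m.median_split_compare(frozen, n_iterations=10, seed=0)

    def test_null_after_run_split_rarely_significant(self):
        # gain 1 in both halves: neither half's Z-test should reject
        # often (alpha here 0.05 uncorrected)
        plan = m.build_session_plan("duration_after", n_blocks=2)
        params = m.duration_observer_params(run_gain=1.0)
        n_sig = 0
        n_rep = 25
        for seed in range(n_rep):
            trials = m.simulate_cohort(plan, m.CohortParams(seed=100 + seed),
                                       params)
            res = m.median_split_compare(trials, n_iterations=150,
                                         seed=seed)
            n_sig += any(h.comparison.significant for h in res.values())
        assert n_sig <= 0.25 * n_rep  # two tests per replicate at alpha=.05


class TestPrecisionCorrelation:
    def test_identity_and_reversal(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        assert m.precision_correlation(x, x).statistic == pytest.approx(1.0)
        assert m.precision_correlation(x, -x).statistic == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateModelError):
            m.precision_correlation(np.ones(5), np.arange(5.0))

    def test_independent_precisions_rarely_correlate(self):
        rng = np.random.default_rng(3)
        small = 0
        n_rep = 100
        for _ in range(n_rep):
            a = rng.lognormal(np.log(0.25), 0.2, 15)
            b = rng.lognormal(np.log(0.15), 0.2, 15)
            if abs(m.precision_correlation(a, b).statistic) < 0.5:
                small += 1
        assert small >= 0.90 * n_rep
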