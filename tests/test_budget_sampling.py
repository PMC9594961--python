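import datetime as dt
import warnings

import numpy as np
import pandas as pd
import pytest

import ethobudget as eb
from ethobudget import budget_sampling as bs
from ethobudget.io_formats import EPOCHS_PER_DAY, ETHOGRAM, LABEL_TO_INDEX
from ethobudget.synthetic_data import IID_VALIDATION_BUDGET


class TestDayFiltering:
    def _days(self, factory, counts):
        return [
            factory([LABEL_TO_INDEX["resting"]] * c,
                    day=dt.date(2021, 1, 1) + dt.timedelta(days=i))
            for i, c in enumerate(counts)
        ]

    def test_coverage_threshold(self, seq_factory):
        # 43,000 epochs = 99.54% -> retained; 42,900 = 99.31% -> dropped
        days = self._days(seq_factory, [100, 43_000, 42_900, 100])
        kept = bs.filter_complete_days(days)
        assert [s.n_epochs for s in kept] == [43_000]

    def test_first_and_last_day_removed(self, seq_factory):
        days = self._days(seq_factory, [43_200, 43_200, 43_200])
        kept = bs.filter_complete_days(days)
        assert [s.day for s in kept] == [dt.date(2021, 1, 2)]

    def test_endpoint_rule_per_animal(self, seq_factory):
        a = self._days(seq_factory, [43_200] * 3)
        b = [
            seq_factory([0] * 43_200, day=dt.date(2021, 2, 1) + dt.timedelta(days=i),
                        animal_id="d02")
            for i in range(4)
        ]
        kept = bs.filter_complete_days(a + b)
        assert len(kept) == 1 + 2


class TestBudgetsAndDownsampling:
    def test_single_behaviour_budget(self, full_day_factory):
        budget = bs.compute_budget(full_day_factory("resting"))
        assert budget[LABEL_TO_INDEX["resting"]] == 1.0
        assert budget.sum() == 1.0

    def test_half_half_budget(self, seq_factory):
        seq = seq_factory(
            [LABEL_TO_INDEX["resting"]] * 21_600 + [LABEL_TO_INDEX["floating"]] * 21_600
        )
        budget = bs.compute_budget(seq)
        assert budget[LABEL_TO_INDEX["resting"]] == 0.5
        assert budget[LABEL_TO_INDEX["floating"]] == 0.5

    def test_budget_matches_independent_counter(self, seq_factory):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 8, 10_000)
        budget = bs.compute_budget(seq_factory(codes))
        brute = np.array([(codes == j).sum() for j in range(8)]) / codes.size
        np.testing.assert_allclose(budget, brute)

    @pytest.mark.parametrize(
        "interval_s,expected",
        [(600, 144), (3600, 24), (2, 43_200), (10, 8640)],
    )
    def test_downsample_counts(self, full_day_factory, interval_s, expected):
        seq = full_day_factory()
        assert bs.downsample(seq, interval_s).n_epochs == expected
        assert bs.records_per_day(interval_s) == expected

    def test_downsample_keeps_first_epoch_and_stride(self, seq_factory):
        seq = seq_factory(np.arange(20) % 8)
        out = bs.downsample(seq, 10)  # every 5th epoch
        np.testing.assert_array_equal(out.codes, seq.codes[::5])
        np.testing.assert_array_equal(out.times, seq.times[::5])

    def test_downsample_rejects_bad_interval(self, full_day_factory):
        with pytest.raises(ValueError):
            bs.downsample(full_day_factory(), 5)
        with pytest.raises(ValueError):
            bs.records_per_day(0)


class TestSamplingErrorTable:
    def test_identity_interval_zero_error(self, seq_factory):
        rng = np.random.default_rng(4)
        days = [
            seq_factory(rng.integers(0, 8, 1000),
                        day=dt.date(2021, 1, 1) + dt.timedelta(days=i))
            for i in range(3)
        ]
        table = bs.sampling_error_table(days, intervals_s=[2])
        assert (table["sd_sampling"] == 0).all()
        assert (table.loc[table["defined"], "error_ratio"] == 0).all()

    def test_hand_computed_sd_and_ratio(self, seq_factory):
        """Two days engineered so (continuous - sampled) = +0.01 / -0.01 for
        'flying' with p = 0.1: sd = sqrt(2e-4/1) = 0.014142, ratio 0.14142."""
        m, n_epochs = 10, 1000  # interval 20 s, 100 sampled records
        fly = LABEL_TO_INDEX["flying"]
        rest = LABEL_TO_INDEX["resting"]

        def build(cont_count, sampled_count, day):
            codes = np.full(n_epochs, rest, dtype=np.int8)
            sampled_pos = list(range(0, n_epochs, m))[:sampled_count]
            codes[sampled_pos] = fly
            remaining = cont_count - sampled_count
            unsampled = [i for i in range(n_epochs) if i % m != 0]
            codes[unsampled[:remaining]] = fly
            return seq_factory(codes, day=day)

        d1 = build(110, 10, dt.date(2021, 1, 1))  # cont .11, sampled .10
        d2 = build(90, 10, dt.date(2021, 1, 2))  # cont .09, sampled .10 -> -0.01
        table = bs.sampling_error_table([d1, d2], intervals_s=[20])
        row = table[table["behaviour"] == "flying"].iloc[0]
        assert row["p"] == pytest.approx(0.1)
        assert row["sd_sampling"] == pytest.approx(0.0141421, abs=1e-6)
        assert row["error_ratio"] == pytest.approx(0.141421, abs=1e-5)

    def test_never_observed_behaviour_flagged_undefined(self, seq_factory):
        days = [
            seq_factory([LABEL_TO_INDEX["resting"]] * 1000,
                        day=dt.date(2021, 1, 1) + dt.timedelta(days=i))
            for i in range(2)
        ]
        table = bs.sampling_error_table(days, intervals_s=[20])
        undef = table[~table["defined"]]
        assert set(undef["behaviour"]) == set(ETHOGRAM) - {"resting"}
        assert undef["error_ratio"].isna().all()

    def test_pooled_and_daily_mean_agree_on_complete_days(self):
        days = eb.simulate_iid_days(IID_VALIDATION_BUDGET, 3, seed=11)
        a = bs.behaviour_proportions(days, "daily_mean")
        b = bs.behaviour_proportions(days, "pooled")
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestExpectedErrorRatio:
    @pytest.mark.parametrize(
        "p,n,expected",
        [(0.5, 1, 1.0), (0.5, 100, 0.1), (0.1, 144, 0.25)],
    )
    def test_closed_form_values(self, p, n, expected):
        assert bs.expected_error_ratio(p, n) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bs.expected_error_ratio(0.0, 10)
        with pytest.raises(ValueError):
            bs.expected_error_ratio(1.0, 10)

    def test_reference_grid_definition_and_monotonicity(self):
        df = bs.expected_error_table()
        for p in df.index:
            for interval in df.columns:
                assert df.loc[p, interval] == pytest.approx(
                    bs.expected_error_ratio(p, bs.records_per_day(interval))
                )
        vals = df.to_numpy()
        assert (np.diff(vals, axis=1) >= 0).all()  # longer interval -> worse
        assert (np.diff(vals, axis=0) <= 0).all()  # commoner behaviour -> better

    def test_rare_behaviour_hourly_sampling_exceeds_one(self):
        # p = 0.5%, hourly sampling (24 records/day): error ratio ~ 2.88
        val = bs.expected_error_ratio(0.005, 24)
        assert val == pytest.approx(2.88, abs=0.01)
        assert bs.expected_error_table().attrs["gt_one"].loc[0.005, 3600]

    def test_finite_overlap_correction_matches_subset_variance(self):
        """With the sampled records a subset of the continuous reference,
        Var(diff) = p(1-p)(1/n - 1/N); the day_epochs argument applies it."""
        p, n, N = 0.2, 8640, 43_200
        full = bs.expected_error_ratio(p, n)
        corrected = bs.expected_error_ratio(p, n, day_epochs=N)
        assert corrected == pytest.approx(full * np.sqrt(1 - n / N))


class TestEmpiricalMatchesIndependenceOracle:
    def test_iid_days_match_finite_overlap_expectation(self):
        """On i.i.d. days the pipeline's error ratio agrees with the exact
        subset-sampling expectation sqrt(p(1-p)(1/n-1/N))/p at every
        interval, within 3 bootstrap SEs over 200 days."""
        n_days = 200
        days = eb.simulate_iid_days(IID_VALIDATION_BUDGET, n_days, seed=21)
        intervals = bs.DEFAULT_INTERVALS_S
        diffs = bs.sampling_differences(days, intervals)
        p = bs.behaviour_proportions(days)
        sd = diffs.std(axis=0, ddof=1)
        emp = sd / p
        rng = np.random.default_rng(99)
        boot = np.empty((300,) + sd.shape)
        for b in range(300):
            idx = rng.integers(0, n_days, n_days)
            boot[b] = diffs[idx].std(axis=0, ddof=1)
        se = boot.std(axis=0, ddof=1) / p
        n = np.array([bs.records_per_day(i) for i in intervals], dtype=float)
        expected = bs.expected_error_ratio(
            p[None, :], n[:, None], day_epochs=EPOCHS_PER_DAY
        )
        assert (np.abs(emp - expected) <= 3 * se).all()


class TestDependence:
    def test_zero_when_q_equals_p(self):
        p = np.full(8, 1 / 8)
        assert bs.dependence_from_qp(p, p) == 0.0

    def test_one_for_uniform_p_point_mass_q(self):
        p = np.full(8, 1 / 8)
        q = np.zeros(8)
        q[3] = 1.0
        assert bs.dependence_from_qp(q, p) == pytest.approx(1.0)

    def test_bounds_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            q = rng.dirichlet(np.ones(8))
            p = rng.dirichlet(np.ones(8))
            d = bs.dependence_from_qp(q, p)
            assert 0.0 <= d <= 1.0 + 1e-12

    def test_iid_sequence_dependence_vanishes_with_data(self):
        days = eb.simulate_iid_days(IID_VALIDATION_BUDGET, 10, seed=23)
        val = bs.dependence(days, 60, "resting")
        assert val < 0.01

    def test_sticky_chain_dependence_decreases_with_lag(self):
        from ethobudget.synthetic_data import (
            DEFAULT_STATIONARY_BUDGET,
            sticky_transition_matrix,
        )
        cfg = eb.SimulationConfig(
            transition_matrix=sticky_transition_matrix(DEFAULT_STATIONARY_BUDGET),
            site_layout=[], diurnal_schedule={}, behaviour_speeds={},
            odba_intensity={}, n_days=10, seed=5,
        )
        seqs, _ = eb.simulate_behaviour_days(cfg)
        curve = [bs.dependence(seqs, i, "resting") for i in (2, 10, 60, 300)]
        assert all(a > b for a, b in zip(curve, curve[1:]))
        assert curve[0] > 0.3  # strong short-lag dependence
        # beyond the chain's memory the statistic sits at its noise floor
        assert bs.dependence(seqs, 1800, "resting") < 0.05

    def test_never_observed_focal_raises(self, seq_factory):
        days = [seq_factory([LABEL_TO_INDEX["resting"]] * 100)]
        with pytest.raises(ValueError, match="never observed"):
            bs.dependence(days, 2, "flying")

    def test_pairs_do_not_span_days(self, seq_factory):
        # flying only as the last epoch of day 1: no valid lag pair exists
        fly, rest = LABEL_TO_INDEX["flying"], LABEL_TO_INDEX["resting"]
        d1 = seq_factory([rest] * 9 + [fly], day=dt.date(2021, 1, 1))
        d2 = seq_factory([rest] * 10, day=dt.date(2021, 1, 2))
        with pytest.raises(ValueError, match="never observed"):
            bs.dependence([d1, d2], 2, "flying")


class TestLogLogRegression:
    def _exact_table(self, a=-4.0, b=0.6, c=-0.55):
        rows = []
        for interval in bs.DEFAULT_INTERVALS_S:
            for j, beh in enumerate(ETHOGRAM):
                p = 0.02 + 0.05 * j
                ratio = np.exp(
                    a + b * np.log(interval / 60) + c * np.log(p * 100)
                )
                rows.append(
                    {
                        "interval_s": interval,
                        "behaviour": beh,
                        "sd_sampling": ratio * p,
                        "p": p,
                        "error_ratio": ratio,
                        "n_records": bs.records_per_day(interval),
                        "defined": True,
                    }
                )
        return pd.DataFrame(rows)

    def test_exact_recovery(self):
        fit = bs.fit_loglog_regression(self._exact_table())
        assert fit.intercept == pytest.approx(-4.0, abs=1e-9)
        assert fit.coef_ln_interval == pytest.approx(0.6, abs=1e-9)
        assert fit.coef_ln_p == pytest.approx(-0.55, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_degrees_of_freedom_9x8_design(self):
        fit = bs.fit_loglog_regression(self._exact_table())
        assert (fit.df_model, fit.df_resid) == (2, 69)
        assert fit.n_obs == 72

    def test_zero_ratio_rows_excluded_with_warning(self):
        table = self._exact_table()
        table.loc[0, "error_ratio"] = 0.0
        with pytest.warns(UserWarning, match="error ratio 0"):
            fit = bs.fit_loglog_regression(table)
        assert fit.n_obs == 71
        assert fit.n_excluded == 1

    def test_too_few_rows_raises(self):
        table = self._exact_table().head(3)
        with pytest.raises(ValueError):
            bs.fit_loglog_regression(table)
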