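import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import critattract as ca
from critattract.stats_report import group_report, timecourse


class TestPairedT:
    def test_identical_inputs(self):
        res = ca.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["cohen_d"] == 0.0
        assert res["df"] == 2

    def test_constant_nonzero_difference_flagged(self):
        res = ca.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res["degenerate"] and res["t"] == np.inf

    def test_hand_computed_diffs(self):
        """diffs (1, 2, 3, 6): mean 3, SD sqrt(14/3), t = 3/(SD/2)."""
        sd = np.sqrt(14 / 3)
        res = ca.paired_t([1.0, 2.0, 3.0, 6.0])
        assert res["t"] == pytest.approx(3 / (sd / 2))
        assert res["cohen_d"] == pytest.approx(3 / sd)
        assert res["df"] == 3
        assert res["p"] == pytest.approx(
            2 * stats.t.sf(3 / (sd / 2), 3)
        )


class TestJzsBF:
    def test_null_favoring_at_t_zero(self):
        assert ca.jzs_bf(0.0, 26) < 1.0

    def test_large_t_supports_alternative(self):
        assert ca.jzs_bf(9.7, 26) > 3.0

    def test_monotone_in_abs_t(self):
        vals = [ca.jzs_bf(t, 26) for t in np.linspace(0, 6, 13)]
        assert np.all(np.diff(vals) > 0)

    def test_matches_g_prior_quadrature_oracle(self):
        """Independent oracle: the same Bayes factor written as an
        inverse-chi-square mixture over the g-prior variance."""
        from scipy import integrate

        t, n, r = 2.5, 26, np.sqrt(2) / 2
        df = n - 1

        def integrand(g):
            c = 1 + n * g * r**2
            return (
                c**-0.5
                * (1 + t**2 / (c * df)) ** (-(df + 1) / 2)
                * (2 * np.pi) ** -0.5
                * g**-1.5
                * np.exp(-1 / (2 * g))
            )

        numerator, _ = integrate.quad(integrand, 0, np.inf, limit=300)
        oracle = numerator / (1 + t**2 / df) ** (-(df + 1) / 2)
        mine = ca.jzs_bf(t, n)
        assert mine == pytest.approx(oracle, rel=1e-3)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        bf = float(pingouin.bayesfactor_ttest(2.5, nx=26, paired=True))
        assert ca.jzs_bf(2.5, 26) == pytest.approx(bf, rel=1e-3)


class TestWilcoxon:
    def test_all_ties_error(self):
        with pytest.raises(ValueError):
            ca.wilcoxon_signrank([3.0, 3.0, 3.0], threshold=3.0)

    def test_symmetric_sample_not_significant(self):
        x = 3.0 + np.array([-0.4, -0.3, -0.2, -0.1, 0.1, 0.2, 0.3, 0.4])
        res = ca.wilcoxon_signrank(x, threshold=3.0)
        assert res["p"] > 0.5

    def test_exact_enumeration_oracle_n6(self):
        """One-sided p for n=6 distinct values by enumerating all 2^6 sign
        assignments of the ranks."""
        x = np.array([1.2, -0.5, 2.3, 0.7, -1.8, 3.1])
        res = ca.wilcoxon_signrank(x, threshold=0.0, alternative="less")

        ranks = stats.rankdata(np.abs(x))
        w_obs = ranks[x > 0].sum()
        w_all = [
            np.sum(ranks[np.array(signs, dtype=bool)])
            for signs in itertools.product([0, 1], repeat=6)
        ]
        p_oracle = np.mean([w <= w_obs for w in w_all])
        assert res["p"] == pytest.approx(p_oracle)


class TestScaledCriteriaTest:
    def _criteria_frames(self, cohort):
        trials, _ = cohort
        low_rows, high_rows = [], []
        for tr in trials:
            kept, _ = ca.balance_trials(tr)
            low_rows.append(ca.estimate_criteria(kept[kept.condition == "low"]).t)
            high_rows.append(ca.estimate_criteria(kept[kept.condition == "high"]).t)
        return pd.DataFrame(low_rows), pd.DataFrame(high_rows)

    def test_identical_inputs_give_zero_t(self):
        t = pd.DataFrame([{i: 3.0 * i for i in (-3, -2, -1, 1, 2, 3)}] * 4)
        res = ca.scaled_criteria_test(t, 3.0 * t)
        assert all(r["t"] == 0.0 for r in res.values())

    def test_attracted_cohort_scaled_low_more_extreme(self, attracted_cohort):
        low_df, high_df = self._criteria_frames(attracted_cohort)
        res = ca.scaled_criteria_test(low_df, high_df)
        assert all(r["t"] > 0 for r in res.values())

    def test_no_attraction_cohort_null(self):
        cohort = ca.simulate_cohort(6, ca.gaussian_alpha_sampler(mean=1.0), seed=55)
        low_df, high_df = self._criteria_frames(cohort)
        res = ca.scaled_criteria_test(low_df, high_df)
        assert np.mean([abs(r["t"]) for r in res.values()]) < 3.0


class TestTimecourse:
    def test_epoch_equal_to_block_reproduces_block_mean(self, single_subject):
        tc = timecourse(single_subject, epoch_length=50)
        for cond in ("low", "high"):
            expected = single_subject[single_subject.condition == cond]["confidence"].mean()
            assert tc.loc[cond, 1] == pytest.approx(expected)

    def test_epoch_must_divide_block(self, single_subject):
        with pytest.raises(ValueError):
            timecourse(single_subject, epoch_length=7)

    def test_static_alpha_flat_difference(self):
        trials, _ = ca.simulate_cohort(
            8, ca.gaussian_alpha_sampler(mean=1.244), seed=56
        )
        tcs = [timecourse(t, 10) for t in trials]
        diff = sum(tc.loc["high"] - tc.loc["low"] for tc in tcs) / len(tcs)
        assert diff.max() - diff.min() < 0.25  # no systematic trend, noise only

    def test_decaying_alpha_first_epoch_largest(self):
        """Attraction decaying within blocks concentrates the confidence
        difference in the first 10-trial epoch."""
        sched = lambda t: ca.timecourse_attraction(1.5, 1.05, 0.15, t)  # noqa: E731
        diffs = []
        rng = np.random.default_rng(57)
        for _ in range(8):
            stim = ca.generate_stimuli(seed=rng)
            out = ca.simulate_observer(stim, ca.ObserverParams(), seed=rng, alpha_schedule=sched)
            tc = timecourse(out, 10)
            diffs.append(tc.loc["high"] - tc.loc["low"])
        mean_diff = sum(diffs) / len(diffs)
        assert mean_diff.idxmax() == 1


class TestCorrelations:
    def test_self_and_negation(self):
        df = pd.DataFrame({
            "conf_effect": [0.1, 0.2, 0.5, 0.3],
            "dprime_effect": [0.1, 0.2, 0.5, 0.3],
            "rt_effect": [-0.1, -0.2, -0.5, -0.3],
        })
        out = ca.confidence_effect_correlations(df)
        assert out["conf_vs_dprime_effect"]["r"] == pytest.approx(1.0)
        assert out["conf_vs_rt_effect"]["r"] == pytest.approx(-1.0)

    def test_five_point_hand_table(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        df = pd.DataFrame({"conf_effect": x, "dprime_effect": y,
                           "rt_effect": [np.nan] * 5})
        r_hand = np.sum((x - 3) * (y - 3)) / np.sqrt(np.sum((x - 3) ** 2) * np.sum((y - 3) ** 2))
        out = ca.confidence_effect_correlations(df)
        assert out["conf_vs_dprime_effect"]["r"] == pytest.approx(r_hand)
        assert "conf_vs_rt_effect" not in out  # NaNs are skipped, not fabricated

    def test_alpha_drives_confidence_not_dprime(self):
        """Subjects varying in attraction show conf-effect strongly tied to
        alpha but not to d' (the dissociation's individual-difference
        structure)."""
        trials, params = ca.simulate_cohort(
            12, ca.gaussian_alpha_sampler(mean=1.244, sd=0.12), seed=58
        )
        rows = []
        for tr, p in zip(trials, params):
            kept, _ = ca.balance_trials(tr)
            s = ca.summarize_subject(kept)
            rows.append({"conf_effect": s.conf_effect, "dprime_effect": s.dprime_effect,
                         "rt_effect": s.rt_effect, "alpha": p.alpha})
        df = pd.DataFrame(rows)
        out = ca.confidence_effect_correlations(df)
        assert out["conf_vs_alpha"]["r"] > 0.6
        assert abs(out["conf_vs_dprime_effect"]["r"]) < 0.6


class TestGroupReport:
    def test_report_recomputable_and_complete(self, attracted_cohort):
        trials, _ = attracted_cohort
        combined = pd.concat(trials, ignore_index=True)
        rep = group_report(combined)
        group = rep["group"]
        assert group["n_subjects"] == 6
        assert group["confidence"]["df"] == 5
        for key in ("confidence", "dprime", "rt"):
            assert np.isfinite(group[key]["t"])
        assert set(group["mean_ratios"]) == {-3, -2, -1, 1, 2, 3}
        assert group["mean_confidence"]["high"] > group["mean_confidence"]["low"]
        assert len(rep["per_subject"]["summaries"]) == 6
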