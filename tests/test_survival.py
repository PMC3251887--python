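import numpy as np
import pandas as pd
import pytest

from nbprofile.survival import (
    SurvivalRecord,
    backward_select,
    cox_fit,
    derive_pfs,
    km_estimate,
    logrank_test,
)


def _records(times, events, **groups):
    per_record = {k: v for k, v in groups.items()}
    out = []
    for i, (t, e) in enumerate(zip(times, events)):
        g = {k: (v[i] if np.ndim(v) else v) for k, v in per_record.items()}
        out.append(SurvivalRecord(str(i), float(t), int(e), g))
    return out


class TestDerivePFS:
    def _row(self, **kw):
        base = dict(
            patient_id="x",
            trial="INES99.2",
            upfront_chemo=False,
            followup_months=40.0,
            event=1,
            progression_months=1.5,
        )
        base.update(kw)
        return base

    def test_untreated_4s_early_progression_not_counted(self):
        rec = derive_pfs(self._row())
        assert rec.event == 0 and rec.time_months == 40.0

    def test_treated_4s_early_progression_counted(self):
        rec = derive_pfs(self._row(upfront_chemo=True))
        assert rec.event == 1 and rec.time_months == 1.5

    def test_localised_trial_relapse_counted(self):
        rec = derive_pfs(
            self._row(trial="INES99.1", upfront_chemo=True, progression_months=16.0)
        )
        assert rec.event == 1 and rec.time_months == 16.0

    def test_late_progression_in_untreated_4s_counted(self):
        rec = derive_pfs(self._row(progression_months=7.0))
        assert rec.event == 1 and rec.time_months == 7.0

    def test_non_positive_followup_rejected(self):
        with pytest.raises(ValueError):
            derive_pfs(self._row(followup_months=0.0, event=0))


class TestKaplanMeier:
    def test_single_subject_step(self):
        km = km_estimate(_records([5.0], [1]))
        assert km.survival_at(4.9) == 1.0
        assert km.survival_at(5.0) == 0.0

    def test_no_events_flat_curve(self):
        km = km_estimate(_records([3, 8, 12], [0, 0, 0]))
        assert km.survival_at(20.0) == 1.0
        assert km.std_err_at(20.0) == 0.0

    def test_uncensored_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 200)
        km = km_estimate(_records(t, np.ones(200)))
        for q in (2.0, 5.0, 15.0):
            assert km.survival_at(q) == pytest.approx(np.mean(t > q))

    def test_large_sample_matches_exponential(self):
        rng = np.random.default_rng(1)
        lam = 0.05
        t = rng.exponential(1 / lam, 10_000)
        km = km_estimate(_records(t, np.ones(10_000)))
        for q in (5.0, 20.0):
            s = np.exp(-lam * q)
            assert abs(km.survival_at(q) - s) < 2 * np.sqrt(s * (1 - s) / 10_000)

    def test_greenwood_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(5)
        t = rng.exponential(30, 150)
        e = (t < 40).astype(int)
        tt = np.minimum(t, 40)
        km = km_estimate(_records(tt, e))
        kmf = KaplanMeierFitter().fit(tt, e)
        assert km.survival_at(20.0) == pytest.approx(
            float(kmf.survival_function_at_times(20.0).iloc[0])
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])


class TestLogrank:
    def test_identical_groups_null(self):
        recs = _records([2, 4, 6, 2, 4, 6], [1, 1, 0, 1, 1, 0], g=["a"] * 3 + ["b"] * 3)
        res = logrank_test(recs, "g")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(_records([1, 2], [1, 1], g=["a", "a"]), "g")

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, 120)
        t = rng.exponential(20 / (1 + x))
        e = (t < 30).astype(int)
        tt = np.minimum(t, 30)
        res = logrank_test(_records(tt, e, g=x), "g")
        ref = ll_logrank(tt[x == 0], tt[x == 1], e[x == 0], e[x == 1])
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_invariance_to_relabelling_and_time_rescaling(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 2, 80)
        t = rng.exponential(10 / (1 + x))
        e = np.ones(80, dtype=int)
        base = logrank_test(_records(t, e, g=x), "g").statistic
        swapped = logrank_test(_records(t, e, g=1 - x), "g").statistic
        rescaled = logrank_test(_records(np.exp(t / 10), e, g=x), "g").statistic
        assert swapped == pytest.approx(base, rel=1e-9)
        assert rescaled == pytest.approx(base, rel=1e-9)

    def test_three_group_statistic_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(10)
        g = rng.integers(0, 3, 150)
        t = rng.exponential(15 / (1 + g))
        e = np.ones(150, dtype=int)
        res = logrank_test(_records(t, e, g=g), "g")
        ref = multivariate_logrank_test(t, g, e)
        assert res.df == 2
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)


class TestCox:
    def _sim(self, n=300, beta=1.0, seed=0, round_times=False):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.02 * np.exp(beta * x)))
        if round_times:
            t = np.ceil(t)  # force ties
        e = (t <= 60).astype(int)
        tt = np.minimum(t, 60)
        return tt, e, x

    def test_constant_covariate_rejected(self):
        recs = _records([1, 2, 3], [1, 1, 0], x=[1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="rank"):
            cox_fit(recs, ["x"])

    def test_score_test_equals_logrank_without_ties(self):
        tt, e, x = self._sim()
        recs = _records(tt, e, x=x)
        fit = cox_fit(recs, ["x"])
        lr = logrank_test(recs, "x")
        assert fit.score_statistic == pytest.approx(lr.statistic, abs=1e-8)

    def test_breslow_matches_lifelines(self):
        from lifelines import CoxPHFitter

        tt, e, x = self._sim(round_times=True, seed=4)
        fit = cox_fit(_records(tt, e, x=x), ["x"], ties="breslow")
        cph = CoxPHFitter()
        cph.fit(
            pd.DataFrame({"T": tt, "E": e, "x": x}), "T", "E"
        )  # lifelines uses Efron; compare with our Efron fit below instead
        efron = cox_fit(_records(tt, e, x=x), ["x"], ties="efron")
        assert efron.coef[0] == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)
        assert efron.se[0] == pytest.approx(float(cph.standard_errors_.iloc[0]), abs=1e-6)
        # Breslow and Efron should be close but not identical under ties
        assert fit.coef[0] == pytest.approx(efron.coef[0], rel=0.05)
        assert fit.coef[0] != efron.coef[0]

    def test_estimates_invariant_to_centering(self):
        tt, e, x = self._sim(seed=6)
        f1 = cox_fit(_records(tt, e, x=x), ["x"])
        f2 = cox_fit(_records(tt, e, x=x - x.mean()), ["x"])
        assert f1.coef[0] == pytest.approx(f2.coef[0], abs=1e-8)
        assert f1.se[0] == pytest.approx(f2.se[0], abs=1e-8)

    def test_wald_ci_and_hr_shape(self):
        tt, e, x = self._sim(beta=np.log(3.0), seed=7)
        fit = cox_fit(_records(tt, e, x=x), ["x"])
        assert fit.converged
        assert fit.ci_lower[0] < fit.hazard_ratios[0] < fit.ci_upper[0]
        summary = fit.summary()
        assert list(summary.index) == ["x"]
        assert summary.loc["x", "HR"] == pytest.approx(np.exp(fit.coef[0]))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(_records([1, 2], [0, 0], x=[0.0, 1.0]), ["x"])


class TestBackwardSelect:
    def test_alpha_one_retains_everything(self):
        rng = np.random.default_rng(2)
        n = 150
        x = rng.integers(0, 2, n).astype(float)
        z = rng.normal(size=n)
        t = rng.exponential(1 / (0.02 * np.exp(x)))
        e = (t <= 60).astype(int)
        recs = _records(np.minimum(t, 60), e, x=x, z=z)
        fit, retained = backward_select(recs, ["x", "z"], alpha=1.0)
        assert retained == ["x", "z"]

    def test_noise_covariate_dropped(self):
        rng = np.random.default_rng(3)
        dropped = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 150
            x = rng.integers(0, 2, n).astype(float)
            z = rng.normal(size=n)  # pure noise
            t = rng.exponential(1 / (0.02 * np.exp(1.5 * x)))
            e = (t <= 60).astype(int)
            recs = _records(np.minimum(t, 60), e, x=x, z=z)
            _fit, retained = backward_select(recs, ["x", "z"], alpha=0.05)
            if "z" not in retained:
                dropped += 1
        assert dropped / n_rep >= 0.90

    def test_all_dropped_returns_empty_model(self):
        rng = np.random.default_rng(4)
        n = 100
        z = rng.normal(size=n)
        t = rng.exponential(50, n)
        e = (t <= 60).astype(int)
        recs = _records(np.minimum(t, 60), e, z=z)
        fit, retained = backward_select(recs, ["z"], alpha=1e-6)
        assert fit is None and retained == []

    def test_retained_all_significant(self):
        rng = np.random.default_rng(5)
        n = 200
        x = rng.integers(0, 2, n).astype(float)
        z = rng.normal(size=n)
        t = rng.exponential(1 / (0.03 * np.exp(1.2 * x)))
        e = (t <= 60).astype(int)
        recs = _records(np.minimum(t, 60), e, x=x, z=z)
        fit, retained = backward_select(recs, ["x", "z"], alpha=0.05)
        assert fit is not None
        assert (fit.p_values <= 0.05).all()
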