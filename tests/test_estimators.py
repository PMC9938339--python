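"""Kaplan-Meier, Aalen-Johansen and the univariate Cox fitter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import survalid as sv
from oracles import cox_grid_oracle, km_survival_bruteforce


class TestKaplanMeier:
    def test_single_subject_event(self):
        curve = sv.kaplan_meier([2.0], [1])
        assert curve.survival_at(1.9) == 1.0
        assert curve.survival_at(2.0) == 0.0
        assert curve.survival_at(10.0) == 0.0

    def test_hand_product_limit(self):
        # events at 1 and 2; censored at 1.5 and 3
        curve = sv.kaplan_meier([1.0, 1.5, 2.0, 3.0], [1, 0, 1, 0])
        assert curve.survival_at(1.0) == pytest.approx(0.75, abs=1e-15)
        assert curve.survival_at(2.0) == pytest.approx(0.375, abs=1e-15)

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(0.1, 20.0), min_size=1, max_size=40))
    def test_no_censoring_equals_ecdf(self, times):
        times = np.asarray(times)
        curve = sv.kaplan_meier(times, np.ones(len(times), dtype=int))
        for t in np.unique(times):
            assert curve.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_risk_at_zero_and_beyond(self):
        curve = sv.kaplan_meier([2.0], [1])
        assert sv.km_risk_at(curve, 0.0) == 0.0
        assert sv.km_risk_at(curve, 10.0) == 1.0
        curve2 = sv.kaplan_meier([1.0, 2.0, 3.0], [1, 0, 0])
        with pytest.warns(UserWarning, match="beyond last follow-up"):
            assert sv.km_risk_at(curve2, 99.0) == pytest.approx(1 / 3)

    def test_no_events_flat_with_warning(self):
        with pytest.warns(UserWarning, match="no events"):
            curve = sv.kaplan_meier([1.0, 2.0], [0, 0])
        assert curve.survival_at(2.0) == 1.0

    def test_matches_bruteforce_and_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(7)
        times = rng.integers(1, 15, 200).astype(float)
        events = rng.integers(0, 2, 200)
        curve = sv.kaplan_meier(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in (1.0, 3.0, 7.0, 14.0):
            assert curve.survival_at(t) == pytest.approx(km_survival_bruteforce(times, events, t), abs=1e-12)
            assert curve.survival_at(t) == pytest.approx(float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-9)


class TestAalenJohansen:
    def test_reduces_to_km_without_competition(self):
        rng = np.random.default_rng(1)
        times = rng.uniform(0.1, 10, 100)
        codes = rng.integers(0, 2, 100)
        cifs, surv = sv.aalen_johansen(times, codes)
        km = sv.kaplan_meier(times, codes)
        for t in np.unique(times):
            assert cifs[1].incidence_at(t) == pytest.approx(1 - km.survival_at(t), abs=1e-12)

    def test_hand_three_subjects(self):
        # cause-1 at t=1, cause-2 at t=2, censored at 3
        cifs, surv = sv.aalen_johansen([1.0, 2.0, 3.0], [1, 2, 0])
        assert cifs[1].incidence_at(1.0) == pytest.approx(1 / 3, abs=1e-15)
        assert cifs[2].incidence_at(1.9) == 0.0
        assert cifs[2].incidence_at(2.0) == pytest.approx(1 / 3, abs=1e-15)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        times = rng.integers(1, 12, n).astype(float)
        codes = rng.integers(0, 3, n)
        cifs, surv = sv.aalen_johansen(times, codes)
        for i, t in enumerate(surv.event_times):
            total = cifs[1].incidence_at(t) + cifs[2].incidence_at(t) + surv.survival[i]
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_cif_below_cause_specific_km_risk(self, default_synth):
        # naive KM treating competing deaths as censoring overstates risk
        cfg, synth = default_synth
        c = synth.cohort
        cifs, _ = sv.aalen_johansen(c.times, c.events)
        km1 = sv.kaplan_meier(c.times, (c.events == 1).astype(int))
        for t in (2.0, 5.0, 10.0):
            assert cifs[1].incidence_at(t) <= 1 - km1.survival_at(t) + 1e-12

    def test_matches_lifelines(self, default_synth):
        from lifelines import AalenJohansenFitter

        cfg, synth = default_synth
        c = synth.cohort
        sub = c.subset(np.arange(len(c)) < 300)
        cifs, _ = sv.aalen_johansen(sub.times, sub.events)
        ajf = AalenJohansenFitter(calculate_variance=False).fit(sub.times, sub.events, event_of_interest=1)
        cd = ajf.cumulative_density_
        for t in (2.0, 5.0, 9.5):
            below = cd[cd.index <= t]
            expected = float(below.iloc[-1, 0]) if len(below) else 0.0
            assert cifs[1].incidence_at(t) == pytest.approx(expected, abs=1e-9)


class TestUnivariateCox:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sv.fit_cox_single_covariate([1.0, 2.0, 3.0], [1, 1, 0], [2.0, 2.0, 2.0])

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="2 events"):
            sv.fit_cox_single_covariate([1.0, 2.0, 3.0], [1, 0, 0], [1.0, 0.0, 2.0])

    def test_monotone_likelihood_flagged(self):
        # perfectly separated two-subject instance has no finite optimum
        with pytest.warns(UserWarning, match="converge"):
            fit = sv.fit_cox_single_covariate([1.0, 2.0], [1, 1], [1.0, 0.0])
        assert not fit.converged

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        x = rng.normal(size=n)
        times = rng.exponential(scale=np.exp(-0.8 * x))
        events = (rng.uniform(size=n) < 0.7).astype(int)
        if events.sum() < 3:
            events[:3] = 1
        fit = sv.fit_cox_single_covariate(times, events, x)
        assert fit.converged
        assert fit.beta == pytest.approx(cox_grid_oracle(times, events, x), abs=1e-6)

    def test_matches_lifelines_without_ties(self):
        # with distinct event times the Breslow and Efron likelihoods agree
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        times = rng.exponential(scale=5 * np.exp(-0.5 * x))
        events = (rng.uniform(size=n) < 0.6).astype(int)
        fit = sv.fit_cox_single_covariate(times, events, x)
        cph = CoxPHFitter().fit(pd.DataFrame({"t": times, "e": events, "x": x}), "t", "e")
        assert fit.beta == pytest.approx(float(cph.params_["x"]), abs=1e-5)
        assert fit.standard_error == pytest.approx(float(cph.standard_errors_["x"]), rel=1e-4)

    def test_breslow_ties_match_grid_oracle(self):
        rng = np.random.default_rng(4)
        n = 40
        x = rng.normal(size=n)
        times = np.ceil(3 * rng.exponential(scale=np.exp(-0.5 * x)))  # heavy ties
        times = np.maximum(times, 1.0)
        events = (rng.uniform(size=n) < 0.7).astype(int)
        events[:3] = 1
        fit = sv.fit_cox_single_covariate(times, events, x)
        assert fit.beta == pytest.approx(cox_grid_oracle(times, events, x), abs=1e-6)

    def test_simulation_recovery(self):
        cfg = sv.slope_recovery_scenario(n=10_000, seed=12, slope=1.0)
        synth = sv.generate_cohort(cfg)
        c = synth.cohort
        x = synth.truth["true_lp_stroke"].to_numpy()
        fit = sv.fit_cox_single_covariate(c.times, (c.events == 1).astype(int), x)
        assert 0.95 <= fit.beta <= 1.05
        lo, hi = fit.ci95
        assert lo == pytest.approx(fit.beta - 1.96 * fit.standard_error)
        assert hi == pytest.approx(fit.beta + 1.96 * fit.standard_error)

    def test_curve_export_tidy(self):
        curve = sv.kaplan_meier([1.0, 2.0, 3.0], [1, 1, 0])
        df = curve.to_frame()
        assert list(df.columns) == ["time", "estimate", "at_risk", "events"]
        assert len(df) == 2
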