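"""Model engine: loading, scoring, scaling, eligibility, complete cases."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import survalid as sv
from survalid.model import (MissingPredictorError, ModelLoadError,
                            eligibility_mask)


def _write_model(tmp_path, **overrides):
    base = {
        "name": "toy2",
        "outcome_label": "stroke",
        "horizon": 10.0,
        "predictors": [
            {"name": "a", "covariate": "a", "transform": {"type": "identity"}, "coefficient": 0.5},
            {"name": "b", "covariate": "b", "transform": {"type": "identity"}, "coefficient": -0.2},
        ],
        "centring_means": {"a": 1.0, "b": 2.0},
        "baseline_survival": 0.9,
        "outcome_fraction": 1.0,
    }
    base.update(overrides)
    path = tmp_path / "model.json"
    path.write_text(json.dumps(base))
    return path


class TestLoading:
    def test_round_trip(self, tmp_path):
        model = sv.load_model_definition(_write_model(tmp_path))
        assert len(model.predictors) == 2
        assert model.baseline_survival == 0.9
        assert [p.coefficient for p in model.predictors] == [0.5, -0.2]

    def test_composite_outcome_fractions(self, tmp_path):
        for frac in (0.366, 0.289):
            model = sv.load_model_definition(_write_model(tmp_path, outcome_fraction=frac))
            assert model.outcome_fraction == frac

    def test_missing_centring_means_rejected(self, tmp_path):
        path = _write_model(tmp_path, centring_means={"a": 1.0})
        with pytest.raises(ModelLoadError, match="centring_means"):
            sv.load_model_definition(path)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_baseline_survival_range(self, tmp_path, bad):
        with pytest.raises(ModelLoadError, match="baseline_survival"):
            sv.load_model_definition(_write_model(tmp_path, baseline_survival=bad))

    def test_shipped_fixtures_validate(self, model_def_dir):
        files = sorted(model_def_dir.glob("*.json"))
        assert len(files) >= 4
        for f in files:
            model = sv.load_model_definition(f)
            assert 0 < model.baseline_survival <= 1


class TestPrognosticIndex:
    def test_zero_covariates(self, toy_model):
        pi = sv.compute_prognostic_index(toy_model, {"age": 0.0, "sbp": 0.0, "smoker": 0})
        assert pi == 0.0

    def test_forced_arithmetic(self):
        from survalid.model import Predictor, TransformSpec

        model = sv.ModelDefinition(
            name="m1", outcome_label="x", horizon=10,
            predictors=[Predictor(name="v", covariate="v",
                                  transform=TransformSpec(type="identity"), coefficient=2.0)],
            centring_means={"v": 0.0}, baseline_survival=0.9,
        )
        assert sv.compute_prognostic_index(model, {"v": 3.0}) == pytest.approx(6.0)

    def test_hand_dot_product(self, toy_model):
        row = {"age": 72.0, "sbp": 150.0, "smoker": 1}
        expected = 0.05 * 72.0 + 0.02 * 150.0 + 0.6 * 1.0  # hand computation
        assert sv.compute_prognostic_index(toy_model, row) == pytest.approx(expected, abs=1e-12)

    def test_missing_covariate_raises(self, toy_model):
        with pytest.raises(MissingPredictorError, match="sbp"):
            sv.compute_prognostic_index(toy_model, pd.DataFrame({"age": [70.0], "smoker": [0]}))

    def test_product_and_log_transforms(self):
        from survalid.model import Predictor, TransformSpec

        model = sv.ModelDefinition(
            name="m", outcome_label="x", horizon=10,
            predictors=[
                Predictor(name="log_bmi", covariate="bmi",
                          transform=TransformSpec(type="log"), coefficient=1.0),
                Predictor(name="age_x_smoker", covariate="age",
                          transform=TransformSpec(type="product", with_covariate="smoker",
                                                  with_transform=TransformSpec(type="indicator")),
                          coefficient=0.1),
            ],
            centring_means={"log_bmi": 0.0, "age_x_smoker": 0.0}, baseline_survival=0.9,
        )
        pi = sv.compute_prognostic_index(model, {"bmi": np.e, "age": 70.0, "smoker": 1})
        assert pi == pytest.approx(1.0 + 7.0, abs=1e-12)
        pi0 = sv.compute_prognostic_index(model, {"bmi": np.e, "age": 70.0, "smoker": 0})
        assert pi0 == pytest.approx(1.0, abs=1e-12)


class TestCentringAndProbability:
    def test_zero_means_identity(self, toy_model):
        model = toy_model.model_copy(update={"centring_means": {"age": 0.0, "sbp": 0.0, "smoker": 0.0}})
        assert sv.centre_prognostic_index(model, 6.0) == 6.0

    def test_centred_at_mean(self, toy_model):
        pi_at_means = 0.05 * 70 + 0.02 * 140 + 0.6 * 0.2
        assert sv.centre_prognostic_index(toy_model, pi_at_means) == pytest.approx(0.0, abs=1e-12)

    def test_probability_at_zero_cpi(self, toy_model):
        assert sv.predict_event_probability(toy_model, 0.0) == pytest.approx(0.1)

    def test_degenerate_survivor(self, toy_model):
        model = toy_model.model_copy(update={"baseline_survival": 1.0})
        for cpi in (-3.0, 0.0, 5.0):
            assert sv.predict_event_probability(model, cpi) == 0.0

    def test_analytic_case(self, toy_model):
        # S0 = 0.9, CPI = ln 2 -> P = 1 - 0.9^2 = 0.19
        assert sv.predict_event_probability(toy_model, np.log(2.0)) == pytest.approx(0.19, abs=1e-12)

    def test_overflow_saturates_with_warning(self, toy_model):
        with pytest.warns(RuntimeWarning, match="extreme"):
            p = sv.predict_event_probability(toy_model, 800.0)
        assert 0.0 <= p < 1.0

    @settings(deadline=None, max_examples=60)
    @given(cpi=st.floats(-20, 20), delta=st.floats(1e-6, 5.0),
           s0=st.floats(0.01, 0.99))
    def test_strictly_increasing_in_cpi(self, cpi, delta, s0):
        from survalid.model import Predictor, TransformSpec

        model = sv.ModelDefinition(
            name="m", outcome_label="x", horizon=10,
            predictors=[Predictor(name="v", covariate="v",
                                  transform=TransformSpec(type="identity"), coefficient=1.0)],
            centring_means={"v": 0.0}, baseline_survival=s0,
        )
        from hypothesis import assume

        p_hi = sv.predict_event_probability(model, cpi + delta)
        assume(p_hi < 1 - 1e-12)  # beyond this the float grid saturates
        assert p_hi > sv.predict_event_probability(model, cpi)


class TestScaling:
    @pytest.mark.parametrize("frac,expected", [(0.366, 0.0366), (0.289, 0.0289), (1.0, 0.10)])
    def test_outcome_fraction(self, toy_model, frac, expected):
        model = toy_model.model_copy(update={"outcome_fraction": frac})
        assert sv.scale_to_outcome(model, 0.10) == pytest.approx(expected, abs=1e-15)

    def test_scaled_never_exceeds_probability(self, toy_model, default_synth):
        cfg, synth = default_synth
        model = toy_model.model_copy(update={"outcome_fraction": 0.366})
        preds = sv.RiskScorer(model).predict_set(synth.cohort.covariates())
        assert (preds["scaled_probability"] <= preds["probability"] + 1e-15).all()
        assert preds["probability"].between(0, 1, inclusive="left").all()


class TestSampleRestriction:
    def _flagged_cohort(self, flags):
        n = len(flags)
        return sv.Cohort(pd.DataFrame({
            "id": [f"P{i}" for i in range(n)],
            "time": np.full(n, 5.0),
            "event": np.zeros(n, dtype=int),
            "age": np.full(n, 70.0),
            "prior_stroke": flags,
        }))

    def _stroke_free_model(self, toy_model):
        from survalid.model import EligibilityPredicate
        return toy_model.model_copy(update={"eligibility": [
            EligibilityPredicate(name="prior stroke", covariate="prior_stroke")]})

    def test_no_flags_identity(self, toy_model):
        cohort = self._flagged_cohort([0] * 10)
        out = sv.apply_eligibility(cohort, self._stroke_free_model(toy_model))
        assert len(out) == 10

    def test_counting(self, toy_model):
        cohort = self._flagged_cohort([1, 0, 0, 1, 0, 0, 0, 1, 0, 0])
        out = sv.apply_eligibility(cohort, self._stroke_free_model(toy_model))
        assert len(out) == 7

    def test_overlapping_exclusions_match_set_oracle(self, default_synth, model_def_dir):
        cfg, synth = default_synth
        model = sv.load_model_definition(model_def_dir / "toy_composite_uk.json")
        out = sv.apply_eligibility(synth.cohort, model)
        df = synth.cohort.df
        # brute-force set difference over the three exclusion flags
        excluded = set()
        for flag in ("prior_stroke", "chd", "statin"):
            excluded |= set(df.loc[df[flag] != 0, "id"])
        assert len(out) == len(df) - len(excluded)
        assert set(out.ids) == set(df["id"]) - excluded

    def test_absent_predicate_covariate_errors(self, toy_model, small_cohort):
        model = self._stroke_free_model(toy_model)
        with pytest.raises(ValueError, match="prior_stroke"):
            sv.apply_eligibility(small_cohort, model)

    def test_complete_case_counts(self, toy_model):
        rng = np.random.default_rng(0)
        n = 100
        df = pd.DataFrame({
            "id": [f"P{i}" for i in range(n)],
            "time": np.full(n, 5.0),
            "event": np.zeros(n, dtype=int),
            "age": np.full(n, 70.0),
            "sbp": rng.normal(140, 15, n),
            "smoker": np.zeros(n, dtype=int),
        })
        df.loc[df.index[:8], "sbp"] = np.nan  # 8% missingness, within a realistic band
        out = sv.complete_case_filter(sv.Cohort(df), toy_model)
        assert len(out) == 92
        assert not out.covariates()[["age", "sbp", "smoker"]].isna().any().any()

    def test_complete_case_warns_when_heavy(self, toy_model):
        df = pd.DataFrame({
            "id": [f"P{i}" for i in range(10)],
            "time": np.full(10, 5.0),
            "event": np.zeros(10, dtype=int),
            "age": np.full(10, 70.0),
            "sbp": [np.nan] * 4 + [140.0] * 6,
            "smoker": np.zeros(10, dtype=int),
        })
        with pytest.warns(UserWarning, match="complete-case"):
            out = sv.complete_case_filter(sv.Cohort(df), toy_model)
        assert len(out) == 6

    def test_filters_idempotent(self, default_synth, model_def_dir):
        cfg, synth = default_synth
        model = sv.load_model_definition(model_def_dir / "toy_composite_uk.json")
        once = sv.complete_case_filter(sv.apply_eligibility(synth.cohort, model), model)
        twice = sv.complete_case_filter(sv.apply_eligibility(once, model), model)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_eligibility_value_ops(self, toy_model, small_cohort):
        from survalid.model import EligibilityPredicate
        model = toy_model.model_copy(update={"eligibility": [
            EligibilityPredicate(name="under 65 excluded", covariate="age", op="lt", value=65.0)]})
        out = sv.apply_eligibility(small_cohort, model)
        assert (out.ages >= 65.0).all()
        mask = eligibility_mask(small_cohort, model.eligibility)
        assert mask.sum() == (small_cohort.ages >= 65.0).sum()
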