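import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import frailtykit as fk
from frailtykit.errors import DataError, FitError

from conftest import two_group_logistic_data, two_group_poisson_data


class TestPrepareOutcomes:
    def test_censoring_rule(self):
        events = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c", "c"],
                "sae_time": [np.nan, 100.0, 50.0, 200.0],
                "attrition": [0, 0, 1, 1],
            }
        )
        out = fk.prepare_outcomes(events, follow_up=365.0).set_index("participant_id")
        assert tuple(out.loc["a", ["sae_event", "observation_time"]]) == (0, 365.0)
        assert tuple(out.loc["b", ["sae_event", "observation_time"]]) == (1, 100.0)
        # two SAEs: censored at the first, the later event is ignored
        assert tuple(out.loc["c", ["sae_event", "observation_time"]]) == (1, 50.0)
        assert out.loc["c", "attrition"] == 1

    def test_event_beyond_follow_up_is_a_data_error(self):
        events = pd.DataFrame(
            {"participant_id": ["a"], "sae_time": [400.0], "attrition": [0]}
        )
        with pytest.raises(DataError, match="follow-up"):
            fk.prepare_outcomes(events, follow_up=365.0)


def _grid_poisson_oracle(data, span=(-8.0, 0.0), span_b1=(-1.0, 2.0)):
    """Independent likelihood-grid MLE for a 2-parameter Poisson-offset model."""
    y = data["sae_event"].to_numpy(float)
    x = 10.0 * data["fi"].to_numpy(float)
    t = data["observation_time"].to_numpy(float)

    def nll(b0, b1):
        mu = np.exp(b0 + b1 * x) * t
        return float(np.sum(mu - y * np.log(mu)))

    grid0 = np.linspace(*span, 81)
    grid1 = np.linspace(*span_b1, 61)
    best = min(((nll(b0, b1), b0, b1) for b0 in grid0 for b1 in grid1))
    for half in (0.1, 0.02, 0.004, 0.0008, 0.00016):  # shrink around the optimum
        _, b0c, b1c = best
        grid0 = np.linspace(b0c - half, b0c + half, 41)
        grid1 = np.linspace(b1c - half, b1c + half, 41)
        best = min(((nll(b0, b1), b0, b1) for b0 in grid0 for b1 in grid1))
    return best[1], best[2]


def _grid_logistic_oracle(data):
    y = data["attrition"].to_numpy(float)
    x = 10.0 * data["fi"].to_numpy(float)

    def nll(b0, b1):
        eta = b0 + b1 * x
        return float(np.sum(np.logaddexp(0, eta) - y * eta))

    grid0 = np.linspace(-6.0, 4.0, 101)
    grid1 = np.linspace(-2.0, 3.0, 51)
    best = min(((nll(b0, b1), b0, b1) for b0 in grid0 for b1 in grid1))
    for half in (0.1, 0.02, 0.004, 0.0008, 0.00016):
        _, b0c, b1c = best
        grid0 = np.linspace(b0c - half, b0c + half, 41)
        grid1 = np.linspace(b1c - half, b1c + half, 41)
        best = min(((nll(b0, b1), b0, b1) for b0 in grid0 for b1 in grid1))
    return best[1], best[2]


class TestPoissonSAE:
    def test_two_group_closed_form_irr(self):
        # 10 events per 100 person-years at FI 0.1 vs 20 at FI 0.2 -> IRR 2.0
        data = two_group_poisson_data([(0.1, 100, 10, 1.0), (0.2, 100, 20, 1.0)])
        res = fk.fit_poisson_sae(data, covariates=())
        assert res.effect == pytest.approx(2.0, abs=5e-4)

    def test_agrees_with_likelihood_grid_oracle(self):
        data = two_group_poisson_data([(0.1, 80, 7, 1.0), (0.25, 90, 21, 2.0)])
        res = fk.fit_poisson_sae(data, covariates=())
        b0, b1 = _grid_poisson_oracle(data)
        assert res.beta == pytest.approx(b1, abs=5e-4)
        assert res.covariates["const"][0] == pytest.approx(b0, abs=5e-4)

    def test_offset_time_unit_cancels_from_the_irr(self):
        data = two_group_poisson_data([(0.1, 100, 10, 365.0), (0.2, 100, 20, 365.0)])
        days = fk.fit_poisson_sae(data, covariates=())
        years = fk.fit_poisson_sae(
            data.assign(observation_time=data["observation_time"] / 365.0), covariates=()
        )
        assert days.beta == pytest.approx(years.beta, abs=1e-8)

    def test_covariate_rescaling_consistency(self):
        data = two_group_poisson_data([(0.1, 100, 10, 1.0), (0.2, 100, 20, 1.0)])
        per_01 = fk.fit_poisson_sae(data, covariates=())
        per_001 = fk.fit_poisson_sae(data.assign(fi=data["fi"] / 10.0), covariates=())
        assert per_001.beta == pytest.approx(10.0 * per_01.beta, rel=1e-6)

    def test_equal_observation_times_reduce_to_event_probability_ratio(self):
        data = two_group_poisson_data([(0.1, 200, 20, 3.0), (0.2, 200, 30, 3.0)])
        res = fk.fit_poisson_sae(data, covariates=())
        assert res.effect == pytest.approx((30 / 200) / (20 / 200), abs=1e-6)

    def test_null_association_estimated_near_one(self):
        rng = np.random.default_rng(5)
        n = 20_000
        fi = rng.beta(4, 20, n)
        t = np.minimum(rng.exponential(1 / 0.2, n), 1.0)
        data = pd.DataFrame(
            {"fi": fi, "observation_time": t, "sae_event": (t < 1.0).astype(int)}
        )
        res = fk.fit_poisson_sae(data, covariates=())
        assert res.effect_ci95[0] < 1.0 < res.effect_ci95[1]

    def test_zero_events_is_a_fit_error(self):
        data = two_group_poisson_data([(0.1, 50, 0, 1.0)])
        with pytest.raises(FitError, match="event"):
            fk.fit_poisson_sae(data, covariates=())


class TestLogisticAttrition:
    def test_two_group_closed_form_or(self):
        # 20/100 withdraw at FI 0.1 vs 40/100 at FI 0.2 -> OR (40/60)/(20/80) = 8/3
        data = two_group_logistic_data([(0.1, 100, 20), (0.2, 100, 40)])
        res = fk.fit_logistic_attrition(data, covariates=())
        assert res.effect == pytest.approx(8 / 3, abs=5e-4)

    def test_agrees_with_likelihood_grid_oracle(self):
        data = two_group_logistic_data([(0.05, 120, 25), (0.3, 80, 35)])
        res = fk.fit_logistic_attrition(data, covariates=())
        b0, b1 = _grid_logistic_oracle(data)
        assert res.beta == pytest.approx(b1, abs=5e-4)
        assert res.covariates["const"][0] == pytest.approx(b0, abs=5e-4)

    def test_null_association_estimated_near_one(self):
        rng = np.random.default_rng(6)
        n = 20_000
        data = pd.DataFrame(
            {
                "fi": rng.beta(4, 20, n),
                "attrition": rng.random(n) < 0.25,
                "sae_event": 0,
                "observation_time": 1.0,
            }
        )
        res = fk.fit_logistic_attrition(data, covariates=())
        assert res.effect_ci95[0] < 1.0 < res.effect_ci95[1]

    def test_separation_raises_fit_error(self):
        data = two_group_logistic_data([(0.1, 50, 10), (0.4, 50, 50)])
        with pytest.raises(FitError):
            fk.fit_logistic_attrition(data, covariates=())

    def test_single_attrition_outcome_rejected(self):
        data = two_group_logistic_data([(0.1, 50, 50), (0.2, 50, 50)])
        with pytest.raises(FitError, match="both outcomes"):
            fk.fit_logistic_attrition(data, covariates=())


def _simulate_interaction_trial(rng, n, irr_female, irr_male, base_rate=0.15):
    """Light direct generator for interaction power/size studies."""
    fi = rng.beta(4, 20, n)
    female = (rng.random(n) < 0.5).astype(int)
    log_irr = np.where(female == 1, np.log(irr_female), np.log(irr_male))
    rate = base_rate * np.exp(log_irr * 10 * (fi - 0.15))
    t = rng.exponential(1 / rate, n)
    event = t <= 1.0
    return pd.DataFrame(
        {
            "fi": fi,
            "sae_event": event.astype(int),
            "observation_time": np.where(event, t, 1.0),
            "age_years": rng.normal(75, 6, n),
            "sex": np.where(female == 1, "F", "M"),
            "attrition": 0,
        }
    )


class TestInteraction:
    def test_type_i_error_near_nominal_under_no_interaction(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for _ in range(reps):
            data = _simulate_interaction_trial(rng, 600, 1.6, 1.6)
            res = fk.fit_interaction("poisson_sae", data)
            rejections += res.interaction.p < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_detects_sex_specific_effects(self):
        rng = np.random.default_rng(8)
        detected, signs = 0, 0
        reps = 20
        for _ in range(reps):
            data = _simulate_interaction_trial(rng, 4000, 2.0, 1.3)
            res = fk.fit_interaction("poisson_sae", data)
            detected += res.interaction.p < 0.05
            signs += res.interaction.beta > 0  # female effect is larger
        assert detected > reps / 2
        assert signs > reps / 2

    def test_single_sex_sample_rejected(self):
        rng = np.random.default_rng(9)
        data = _simulate_interaction_trial(rng, 500, 1.6, 1.6)
        data["sex"] = "F"
        with pytest.raises(FitError, match="both sexes"):
            fk.fit_interaction("poisson_sae", data)

    def test_logistic_interaction_reports_wald_p(self):
        rng = np.random.default_rng(10)
        n = 2000
        fi = rng.beta(4, 20, n)
        female = (rng.random(n) < 0.5).astype(int)
        p = expit(-1.0 + 2.0 * 10 * (fi - 0.15) * female)
        data = pd.DataFrame(
            {
                "fi": fi,
                "attrition": (rng.random(n) < p).astype(int),
                "age_years": rng.normal(75, 6, n),
                "sex": np.where(female == 1, "F", "M"),
                "sae_event": 0,
                "observation_time": 1.0,
            }
        )
        res = fk.fit_interaction("logistic_attrition", data)
        assert res.interaction is not None and 0.0 <= res.interaction.p <= 1.0
        assert res.interaction.beta > 0


class TestAdjustedModels:
    def test_age_sex_adjusted_fit_on_synthetic_trial(self, dementia_model_data):
        res = fk.fit_poisson_sae(dementia_model_data)
        assert set(res.covariates) == {"const", "age_years", "female"}
        assert res.effect_ci95[0] < res.effect < res.effect_ci95[1]
        assert res.ci95 == pytest.approx(
            (res.beta - 1.96 * res.se, res.beta + 1.96 * res.se)
        )

    def test_quadratic_term_is_optional_and_off_by_default(self, dementia_model_data):
        res = fk.fit_poisson_sae(dementia_model_data, quadratic=True)
        assert "fi10_sq" in res.covariates
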