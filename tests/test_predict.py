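import numpy as np
import pandas as pd
import pytest

import rettnorm as rn
from rettnorm.predict import (
    mean_predicted_css,
    posterior_random_effects,
    predict_trajectory,
)
from rettnorm.timescale import prediction_grid

from conftest import make_model


def subject_frame(genotype, ages, css, pid="S1"):
    return pd.DataFrame(
        {
            "participant_id": pid,
            "genotype": genotype,
            "visit_age_years": ages,
            "css_total": css,
        }
    )


def conditioning_oracle(model, genotype, ages, y):
    """Brute-force Gaussian conditioning via the explicit joint covariance of
    (random effects, observations)."""
    ln = np.log(np.asarray(ages, float))
    mean_ln = ln.mean()
    dur = ln - mean_ln
    df = pd.DataFrame(
        {
            "genotype": genotype,
            "mean_lnage_center": mean_ln - model.centering_,
            "duration": dur,
        }
    )
    X = model.fixed_design(df)
    Z = np.column_stack([np.ones(len(dur)), dur])
    D = model.cov_re_
    n = len(dur)
    joint = np.block([[D, D @ Z.T], [Z @ D, Z @ D @ Z.T + model.scale_ * np.eye(n)]])
    mu_y = X @ model.fe_params_.to_numpy()
    Sbb, Sby, Syy = joint[:2, :2], joint[:2, 2:], joint[2:, 2:]
    mean = Sby @ np.linalg.solve(Syy, np.asarray(y, float) - mu_y)
    cov = Sbb - Sby @ np.linalg.solve(Syy, Sby.T)
    return mean, cov


@pytest.fixture
def toy_model():
    return make_model(
        ["T158M", "R294X"],
        "T158M",
        {
            "Intercept": 18.0,
            "genotype[T.R294X]": -5.0,
            "mean_lnage_center": 4.0,
            "duration": 4.0,
            "mean_lnage_center:duration": 4.0,
        },
        re_cov=((9.0, 1.5), (1.5, 1.0)),
        resid_var=4.0,
        centering=2.0,
    )


class TestPosteriorRandomEffects:
    def test_matches_brute_force_conditioning(self, toy_model):
        ages = [3.0, 6.0, 11.0]
        y = [15.0, 21.0, 26.0]
        sub = subject_frame("T158M", ages, y)
        mean, cov = posterior_random_effects(toy_model, sub)
        mean_o, cov_o = conditioning_oracle(toy_model, "T158M", ages, y)
        np.testing.assert_allclose(mean, mean_o, atol=1e-8)
        np.testing.assert_allclose(cov, cov_o, atol=1e-8)

    def test_zero_visits_returns_prior(self, toy_model):
        mean, cov = posterior_random_effects(
            toy_model, subject_frame("T158M", [], []), genotype="T158M"
        )
        np.testing.assert_allclose(mean, 0.0)
        np.testing.assert_allclose(cov, toy_model.cov_re_)

    def test_degenerate_prior_pins_posterior_at_zero(self):
        model = make_model(
            ["T158M"], "T158M", {"Intercept": 20.0}, re_cov=((0, 0), (0, 0)), resid_var=4.0
        )
        sub = subject_frame("T158M", [3.0, 7.0], [5.0, 50.0])
        mean, cov = posterior_random_effects(model, sub)
        np.testing.assert_allclose(mean, 0.0)
        np.testing.assert_allclose(cov, 0.0)

    def test_observations_on_population_curve_give_zero_blup(self, toy_model):
        ages = np.array([3.0, 6.0, 11.0])
        ln = np.log(ages)
        dur = ln - ln.mean()
        df = pd.DataFrame(
            {
                "genotype": "T158M",
                "mean_lnage_center": ln.mean() - toy_model.centering_,
                "duration": dur,
            }
        )
        y = toy_model.predict_fixed(df)
        mean, _ = posterior_random_effects(toy_model, subject_frame("T158M", ages, y))
        np.testing.assert_allclose(mean, 0.0, atol=1e-10)

    def test_posterior_cov_psd_and_dominated_by_prior(self, toy_model, small_cohort):
        _, visits, _, _ = small_cohort
        D = toy_model.cov_re_
        for pid, sub in list(visits.groupby("participant_id"))[:20]:
            g = sub["genotype"].iloc[0]
            if g not in toy_model.genotype_levels_:
                continue
            _, cov = posterior_random_effects(toy_model, sub, genotype=g)
            assert np.min(np.linalg.eigvalsh(cov)) > -1e-10
            assert np.min(np.linalg.eigvalsh(D - cov)) > -1e-10

    def test_unknown_genotype_rejected(self, toy_model):
        with pytest.raises(ValueError, match="unknown genotype|absent"):
            posterior_random_effects(
                toy_model, subject_frame("R106W", [3.0], [20.0])
            )


class TestTrajectory:
    def test_zero_visit_subject_equals_population_curve(self, toy_model):
        pred = predict_trajectory(
            toy_model, subject_frame("R294X", [], []), genotype="R294X"
        )
        np.testing.assert_allclose(
            pred.predicted_css, toy_model.population_trajectory("R294X")
        )

    def test_constant_model_predicts_constant(self):
        model = make_model(
            ["T158M"], "T158M", {"Intercept": 20.0}, re_cov=((0, 0), (0, 0))
        )
        pred = predict_trajectory(model, subject_frame("T158M", [4.0, 8.0], [20, 20]))
        assert len(pred.predicted_css) == 231
        np.testing.assert_allclose(pred.predicted_css, 20.0)
        assert mean_predicted_css(pred) == pytest.approx(20.0)

    def test_log_linear_trajectory_matches_closed_form(self, toy_model):
        """For a subject pinned at zero random effects the grid trajectory is
        a + b*(M + M*d + d) with d = ln(age) - subject mean log-age."""
        ages = [4.0, 9.0]
        ln = np.log(ages)
        dur = ln - np.mean(ln)
        df = pd.DataFrame(
            {
                "genotype": "T158M",
                "mean_lnage_center": np.mean(ln) - toy_model.centering_,
                "duration": dur,
            }
        )
        y = toy_model.predict_fixed(df)
        pred = predict_trajectory(toy_model, subject_frame("T158M", ages, y))
        grid = prediction_grid()
        m = np.mean(ln) - toy_model.centering_
        d = np.log(grid) - np.mean(ln)
        expected = 18.0 + 4.0 * (m + m * d + d)
        np.testing.assert_allclose(pred.predicted_css, expected, atol=1e-8)
        assert mean_predicted_css(pred) == pytest.approx(np.mean(expected), abs=1e-9)

    def test_mc_sampling_approximates_exact_conditional(self, toy_model):
        sub = subject_frame("T158M", [3.0, 6.0, 11.0], [15.0, 21.0, 26.0])
        exact = predict_trajectory(toy_model, sub)
        mc = predict_trajectory(toy_model, sub, method="mc", n_draws=4000, seed=0)
        assert np.abs(mc.predicted_css - exact.predicted_css).max() < 0.2

    def test_grid_and_method_validation(self, toy_model):
        sub = subject_frame("T158M", [3.0], [20.0])
        with pytest.raises(ValueError, match="positive"):
            predict_trajectory(toy_model, sub, grid=np.array([-1.0, 2.0]))
        with pytest.raises(ValueError, match="method"):
            predict_trajectory(toy_model, sub, method="bogus")


class TestMeanPredictedCSS:
    def test_requires_full_grid(self, toy_model):
        sub = subject_frame("T158M", [3.0], [20.0])
        pred = predict_trajectory(toy_model, sub, grid=prediction_grid()[:100])
        with pytest.raises(ValueError, match="full"):
            mean_predicted_css(pred)

    def test_symmetric_linear_trajectory_averages_to_midpoint(self, toy_model):
        pred = rn.IndividualPrediction(
            "S", "T158M", np.zeros(2), np.zeros((2, 2)),
            prediction_grid(), np.linspace(0, 58, 231),
        )
        assert mean_predicted_css(pred) == pytest.approx(29.0)

    def test_grid_mean_agrees_with_trapezoidal_auc(self, toy_model):
        sub = subject_frame("T158M", [3.0, 6.0, 11.0], [15.0, 21.0, 26.0])
        pred = predict_trajectory(toy_model, sub)
        auc = np.trapezoid(pred.predicted_css, pred.grid_ages) / (25.0 - 2.0)
        assert abs(mean_predicted_css(pred) - auc) < 0.05


def test_added_visit_on_predicted_curve_leaves_blup_unchanged(toy_model):
    """In the small-noise limit, observing a point the model already predicts
    does not move the posterior."""
    model = make_model(
        toy_model.genotype_levels_,
        "T158M",
        dict(toy_model.fe_params_),
        re_cov=toy_model.cov_re_,
        resid_var=1e-8,
        centering=2.0,
    )
    sub = subject_frame("T158M", [3.0, 6.0], [15.0, 22.0])
    b1, _ = posterior_random_effects(model, sub)
    pred = predict_trajectory(model, sub)
    # the geometric-mean age keeps the subject's between-person anchor fixed
    new_age = float(np.sqrt(3.0 * 6.0))
    new_val = np.interp(new_age, pred.grid_ages, pred.predicted_css)
    sub2 = subject_frame("T158M", [3.0, 6.0, new_age], [15.0, 22.0, new_val])
    b2, _ = posterior_random_effects(model, sub2)
    assert np.abs(b2 - b1).max() < 1e-3


def test_predict_cohort_covers_every_participant(fitted_model, small_cohort):
    _, visits, _, _ = small_cohort
    preds = rn.predict_cohort(fitted_model, visits)
    assert len(preds) == visits["participant_id"].nunique()
    assert preds["mean_predicted_css"].notna().all()
    assert set(preds.columns) >= {
        "participant_id", "genotype", "diagnosis", "n_obs",
        "re_intercept", "re_duration", "mean_predicted_css",
    }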