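import numpy as np
import pandas as pd
import pytest

import rettnorm as rn
from rettnorm.growth import build_design
from rettnorm.simulate import true_fixed_effects
from rettnorm.timescale import decompose_time

from conftest import make_model


def reml_loglik(y, X, Z, groups, D, s2):
    """Independent REML criterion (profiled fixed effects), up to a constant."""
    D = np.asarray(D, float)
    logdetV = 0.0
    XtViX = np.zeros((X.shape[1], X.shape[1]))
    XtViy = np.zeros(X.shape[1])
    quads = []
    for g in np.unique(groups):
        m = groups == g
        Zi, Xi, yi = Z[m], X[m], y[m]
        Vi = Zi @ D @ Zi.T + s2 * np.eye(m.sum())
        sign, ld = np.linalg.slogdet(Vi)
        logdetV += ld
        Vinv = np.linalg.inv(Vi)
        XtViX += Xi.T @ Vinv @ Xi
        XtViy += Xi.T @ Vinv @ yi
        quads.append((Xi, yi, Vinv))
    beta = np.linalg.solve(XtViX, XtViy)
    quad = sum(
        float((yi - Xi @ beta) @ Vinv @ (yi - Xi @ beta)) for Xi, yi, Vinv in quads
    )
    _, ld_xvx = np.linalg.slogdet(XtViX)
    return -0.5 * (logdetV + ld_xvx + quad)


class TestFitting:
    def test_reml_estimate_beats_brute_force_grid(self):
        """REML criterion at the returned estimates dominates a coarse grid
        over diagonal random-effect variances and the residual variance."""
        cfg = rn.SimulationConfig.for_parameter_recovery(seed=12, n_participants=6)
        cfg.atypical_fraction = 0.0
        visits, _, _ = rn.generate_cohort(cfg)
        model = rn.CSSGrowthModel().fit(visits)

        dec, _ = decompose_time(visits)
        X, _ = build_design(
            dec, model.genotype_levels_, model.reference_, model.interaction_terms_
        )
        Z = np.column_stack([np.ones(len(dec)), dec["duration"].to_numpy(float)])
        y = dec["css_total"].to_numpy(float)
        groups = dec["participant_id"].to_numpy()

        ll_hat = reml_loglik(y, X, Z, groups, model.cov_re_, model.scale_)
        for d0 in (0.5, 4.0, 16.0, 36.0):
            for d1 in (0.1, 1.0, 4.0):
                for s2 in (1.0, 4.0, 9.0):
                    ll = reml_loglik(y, X, Z, groups, np.diag([d0, d1]), s2)
                    assert ll <= ll_hat + 1e-6

    def test_degenerate_mixed_model_matches_ols(self):
        """With no true random effects the mixed fit collapses to OLS."""
        cfg = rn.SimulationConfig.for_parameter_recovery(seed=4, n_participants=150)
        cfg.true_re_covariance = ((0.0, 0.0), (0.0, 0.0))
        cfg.atypical_fraction = 0.0
        visits, _, _ = rn.generate_cohort(cfg)
        model = rn.CSSGrowthModel(reference="CTT").fit(visits)
        dec, _ = decompose_time(visits)
        X, _ = build_design(
            dec, model.genotype_levels_, "CTT", model.interaction_terms_
        )
        beta, *_ = np.linalg.lstsq(X, dec["css_total"].to_numpy(float), rcond=None)
        # estimated random-effect variances shrink to near the boundary and
        # the fitted values approach the OLS solution
        assert np.abs(np.diag(model.cov_re_)).max() < 1.0
        fitted_mixed = X @ model.fe_params_.to_numpy()
        fitted_ols = X @ beta
        rms = np.sqrt(np.mean((fitted_mixed - fitted_ols) ** 2))
        assert rms < 0.1

    def test_parameter_recovery_at_reduced_n(self):
        """Fixed effects within 3 Monte-Carlo SEs of truth; variance
        components within 25% relative error, over 5 seeds at n=200."""
        diffs, comps = [], []
        for seed in range(5):
            cfg = rn.SimulationConfig.for_parameter_recovery(seed=seed, n_participants=200)
            visits, _, _ = rn.generate_cohort(cfg)
            model = rn.CSSGrowthModel(reference="CTT").fit(visits)
            truth = true_fixed_effects(cfg, model.genotype_levels_, "CTT")
            diffs.append(model.fe_params_ - pd.Series(truth))
            comps.append(
                [
                    model.cov_re_[0, 0],
                    model.cov_re_[0, 1],
                    model.cov_re_[1, 1],
                    model.scale_,
                ]
            )
        D = pd.DataFrame(diffs)
        assert D.notna().all().all()
        z = D.mean() / (D.std(ddof=1) / np.sqrt(len(D)))
        assert z.abs().max() < 3.0
        cfg = rn.SimulationConfig.for_parameter_recovery()
        Dtrue = np.asarray(cfg.true_re_covariance)
        truth_comps = np.array([Dtrue[0, 0], Dtrue[0, 1], Dtrue[1, 1], cfg.true_residual_sd**2])
        rel = np.abs(np.mean(comps, axis=0) / truth_comps - 1)
        assert rel.max() < 0.25

    def test_visits_outside_age_window_are_dropped(self, toy_visits):
        visits = toy_visits.copy()
        extra = visits.iloc[[0]].copy()
        extra["visit_age_years"] = 30.0
        model = rn.CSSGrowthModel()
        df = model._training_frame(pd.concat([visits, extra]))
        assert df["visit_age_years"].max() <= 25.0

    def test_single_subject_genotype_warns_but_is_retained(self):
        cfg = rn.SimulationConfig.for_parameter_recovery(seed=3, n_participants=40)
        cfg.atypical_fraction = 0.0
        visits, _, _ = rn.generate_cohort(cfg)
        per = visits.drop_duplicates("participant_id")
        rare = per["genotype"].value_counts().index[-1]
        keep_pid = per.loc[per["genotype"] == rare, "participant_id"].iloc[0]
        visits = visits[
            (visits["genotype"] != rare) | (visits["participant_id"] == keep_pid)
        ]
        with pytest.warns(UserWarning, match="single subject"):
            model = rn.CSSGrowthModel().fit(visits)
        assert rare in model.genotype_levels_


class TestPopulationTrajectory:
    def test_constant_model_gives_flat_curve(self):
        model = make_model(["T158M", "R294X"], "T158M", {"Intercept": 20.0})
        curve = model.population_trajectory("T158M")
        np.testing.assert_allclose(curve, 20.0)

    def test_log_growth_is_increasing_and_concave(self):
        model = make_model(
            ["T158M"], "T158M", {"Intercept": 10.0, "mean_lnage_center": 5.0}
        )
        curve = model.population_trajectory("T158M")
        inc = np.diff(curve)
        assert (inc > 0).all()
        assert (np.diff(inc) < 0).all()

    def test_intercept_only_difference_gives_parallel_curves(self):
        model = make_model(
            ["T158M", "R294X"],
            "T158M",
            {"Intercept": 20.0, "mean_lnage_center": 4.0, "genotype[T.R294X]": -6.0},
        )
        a = model.population_trajectory("T158M")
        b = model.population_trajectory("R294X")
        np.testing.assert_allclose(a - b, 6.0)

    def test_overall_curve_is_frequency_weighted(self):
        model = make_model(
            ["T158M", "R294X"],
            "T158M",
            {"Intercept": 20.0, "genotype[T.R294X]": -8.0},
            weights={"T158M": 0.75, "R294X": 0.25},
        )
        overall = model.population_trajectory(None)
        np.testing.assert_allclose(overall, 0.75 * 20.0 + 0.25 * 12.0)

    def test_unknown_genotype_rejected(self, fitted_model):
        with pytest.raises(ValueError, match="unknown genotype"):
            fitted_model.population_trajectory("Q19X")


def gls_beta(y, X, Z, groups, D, s2):
    XtViX = np.zeros((X.shape[1], X.shape[1]))
    XtViy = np.zeros(X.shape[1])
    for g in np.unique(groups):
        m = groups == g
        Vi = Z[m] @ D @ Z[m].T + s2 * np.eye(m.sum())
        Vinv = np.linalg.inv(Vi)
        XtViX += X[m].T @ Vinv @ X[m]
        XtViy += X[m].T @ Vinv @ y[m]
    return np.linalg.solve(XtViX, XtViy)


def test_fitted_values_invariant_to_reference_level(small_cohort):
    """Changing the treatment-coding baseline changes contrasts but not
    fitted values (at fixed variance components)."""
    _, visits, _, _ = small_cohort
    counts = visits.drop_duplicates("participant_id")["genotype"].value_counts()
    ref_a, ref_b = counts.index[0], counts.index[1]
    model = rn.CSSGrowthModel(reference=ref_a).fit(visits)

    df = model._training_frame(visits)
    dec, _ = decompose_time(df)
    y = dec["css_total"].to_numpy(float)
    Z = np.column_stack([np.ones(len(dec)), dec["duration"].to_numpy(float)])
    groups = dec["participant_id"].to_numpy()
    per_counts = dec.groupby("genotype")["participant_id"].nunique()

    n_visits = dec.groupby("genotype").size()
    fitted = {}
    for ref in (ref_a, ref_b):
        inter = {}
        for g in per_counts.index:
            if g == ref:
                continue
            if per_counts[g] >= 2:
                inter[g] = ["mean_lnage_center", "duration", "mean_lnage_center:duration"]
            elif n_visits[g] >= 2:
                inter[g] = ["duration"]
            else:
                inter[g] = []
        X, _ = build_design(dec, list(per_counts.index), ref, inter)
        beta = gls_beta(y, X, Z, groups, model.cov_re_, model.scale_)
        fitted[ref] = X @ beta
    np.testing.assert_allclose(fitted[ref_a], fitted[ref_b], atol=1e-8)


def test_serialization_round_trip(fitted_model, tmp_path):
    path = tmp_path / "fit.json"
    fitted_model.save(path)
    again = rn.CSSGrowthModel.load(path)
    pd.testing.assert_series_equal(again.fe_params_, fitted_model.fe_params_)
    np.testing.assert_allclose(again.cov_re_, fitted_model.cov_re_)
    assert again.centering_ == fitted_model.centering_
    g = fitted_model.genotype_levels_[0]
    np.testing.assert_allclose(
        again.population_trajectory(g), fitted_model.population_trajectory(g)
    )
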