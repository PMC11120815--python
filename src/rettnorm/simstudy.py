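"""Seeded simulation studies validating the pipeline end to end.

Each study generates synthetic cohorts with known ground truth, runs the
relevant pipeline stages, and returns summary statistics: growth-model
parameter recovery, exactness of the empirical-Bayes posterior against
brute-force Gaussian conditioning, calibration of the normative score,
round-trip recovery of corrupted longitudinal records, recovery of an
injected pXCI x variant-severity interaction, and null-control behaviour
when no XCI effect exists.  The test suite and the acceptance script both
drive their checks through these functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cleaning import clean_cohort
from .growth import CSSGrowthModel
from .normative import NormativeScorer
from .predict import predict_cohort
from .schema import SEVERITY_MAP, ItemSchema
from .simulate import SimulationConfig, corrupt_records, generate_cohort, true_fixed_effects
from .xci import fit_xci_model, grouped_correlations
from .crossval import loocv, summarize_rmse

__all__ = [
    "parameter_recovery_study",
    "blup_conditioning_error",
    "ncss_calibration_study",
    "cleaning_roundtrip_study",
    "interaction_recovery_study",
    "null_xci_study",
    "loocv_study",
]


def _sub_seed(seed: int, i: int) -> int:
    return int((seed * 1000 + i) % (2**31 - 1))


def parameter_recovery_study(
    seed: int = 0, n_subjects: int = 300, n_seeds: int = 30
) -> dict:
    """Recover the growth model's generative parameters from simulation.

    Fits the model on ``n_seeds`` independent cohorts drawn from the
    well-identified recovery design and compares the mean estimates with the
    truth: fixed effects as z-scores against their Monte-Carlo standard
    errors, variance components as relative errors of the mean.  The study
    uses one severe and one mild variant group, which exercises every block
    of the model (genotype contrasts on intercept and on each time term)
    while keeping the per-coefficient Monte-Carlo error well estimated.
    """
    diffs, comps = [], []
    for i in range(n_seeds):
        cfg = SimulationConfig.for_parameter_recovery(
            seed=_sub_seed(seed, i), n_participants=n_subjects
        )
        cfg.genotype_frequencies = {"T158M": 0.6, "CTT": 0.4}
        visits, _, _ = generate_cohort(cfg)
        model = CSSGrowthModel(reference="CTT").fit(visits)
        truth = true_fixed_effects(cfg, model.genotype_levels_, "CTT")
        diffs.append(model.fe_params_ - pd.Series(truth))
        comps.append(
            [model.cov_re_[0, 0], model.cov_re_[0, 1], model.cov_re_[1, 1], model.scale_]
        )
    D = pd.DataFrame(diffs)
    z = D.mean() / (D.std(ddof=1) / np.sqrt(len(D)))
    cfg = SimulationConfig.for_parameter_recovery()
    Dtrue = np.asarray(cfg.true_re_covariance)
    truth_comps = np.array(
        [Dtrue[0, 0], Dtrue[0, 1], Dtrue[1, 1], cfg.true_residual_sd**2]
    )
    rel = np.abs(np.mean(comps, axis=0) / truth_comps - 1)
    return {
        "max_abs_z_fixed_effects": float(z.abs().max()),
        "max_rel_err_variance_components": float(rel.max()),
        "rel_err_variance_components": dict(
            zip(["var_intercept", "cov", "var_duration", "resid_var"], map(float, rel))
        ),
    }


def _conditioning_oracle(model, genotype, ages, y):
    """Posterior of (U0, U1) by explicit joint-Gaussian construction."""
    ln = np.log(np.asarray(ages, float))
    dur = ln - ln.mean()
    df = pd.DataFrame(
        {
            "genotype": genotype,
            "mean_lnage_center": ln.mean() - model.centering_,
            "duration": dur,
        }
    )
    X = model.fixed_design(df)
    Z = np.column_stack([np.ones(len(dur)), dur])
    D = model.cov_re_
    Syy = Z @ D @ Z.T + model.scale_ * np.eye(len(dur))
    Sby = D @ Z.T
    resid = np.asarray(y, float) - X @ model.fe_params_.to_numpy()
    mean = Sby @ np.linalg.solve(Syy, resid)
    cov = D - Sby @ np.linalg.solve(Syy, Sby.T)
    return mean, cov


def blup_conditioning_error(seed: int = 0, n_toys: int = 25) -> float:
    """Worst absolute deviation between the model's posterior random effects
    and brute-force multivariate-normal conditioning on 3-visit toys."""
    from .predict import posterior_random_effects

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_toys):
        A = rng.normal(size=(2, 2))
        D = A @ A.T + 0.1 * np.eye(2)
        model = CSSGrowthModel.from_dict(
            {
                "fixed_effects": {
                    "Intercept": float(rng.normal(20, 3)),
                    "mean_lnage_center": float(rng.normal(4, 1)),
                    "duration": float(rng.normal(4, 1)),
                    "mean_lnage_center:duration": float(rng.normal(0, 1)),
                },
                "re_covariance": D.tolist(),
                "residual_variance": float(rng.uniform(0.5, 6.0)),
                "centering_constant": 2.0,
                "genotype_levels": ["T158M"],
                "reference": "T158M",
                "interaction_terms": {},
                "group_weights": {"T158M": 1.0},
                "n_subjects": 0,
                "n_obs": 0,
                "loglik": 0.0,
            }
        )
        ages = np.sort(rng.uniform(2, 25, size=3))
        y = rng.normal(20, 8, size=3)
        sub = pd.DataFrame(
            {"participant_id": "S", "genotype": "T158M", "visit_age_years": ages, "css_total": y}
        )
        mean, cov = posterior_random_effects(model, sub)
        mean_o, cov_o = _conditioning_oracle(model, "T158M", ages, y)
        worst = max(
            worst,
            float(np.abs(mean - mean_o).max()),
            float(np.abs(cov - cov_o).max()),
        )
    return worst


def _fit_predict_score(visits):
    """Run the modelling core: fit on classic, predict everyone, score."""
    model = CSSGrowthModel().fit(visits)
    lo, hi = model.age_window
    in_window = visits[
        (visits["visit_age_years"] >= lo) & (visits["visit_age_years"] <= hi)
    ]
    preds = predict_cohort(model, in_window)
    scorer = NormativeScorer().fit(preds[preds["diagnosis"] == "classic"])
    preds = preds.copy()
    preds["ncss"] = scorer.transform(preds)
    return model, preds


def ncss_calibration_study(seed: int = 0, n_per_group: int = 50) -> dict:
    """Distributional calibration of training nCSS.

    Uses equal genotype frequencies so every group reaches ``n_per_group``
    classic training subjects, runs fit/predict/score, and tests each
    group's training nCSS against U(0,1) (Kolmogorov-Smirnov).  Also returns
    the severity-group sequential-SS fraction on training nCSS under a null
    (no XCI effect), which collapses by construction.
    """
    genos = list(SEVERITY_MAP)
    # oversize so that after the atypical split and sampling noise every
    # group retains at least n_per_group classic training subjects
    n = int(np.ceil(len(genos) * n_per_group / 0.6))
    cfg = SimulationConfig(
        n_participants=n,
        seed=seed,
        genotype_frequencies={g: 1 / len(genos) for g in genos},
        xci_effect=0.0,
        xci_informative_fraction=1.0,
    )
    visits, xci, _ = generate_cohort(cfg)
    _, preds = _fit_predict_score(visits)
    train = preds[preds["diagnosis"] == "classic"]

    ks_p = {}
    for g, sub in train.groupby("genotype"):
        ks_p[g] = float(stats.kstest(sub["ncss"], "uniform").pvalue)

    merged = train.merge(xci, on="participant_id")
    merged["sev_group"] = [SEVERITY_MAP[g] for g in merged["genotype"]]
    _, part = fit_xci_model(merged)
    mild = train[train["genotype"].map(SEVERITY_MAP) == "mild"]["ncss"].mean()
    severe = train[train["genotype"].map(SEVERITY_MAP) == "severe"]["ncss"].mean()
    return {
        "min_ks_pvalue": min(ks_p.values()),
        "ks_pvalues": ks_p,
        "min_group_n": int(train.groupby("genotype").size().min()),
        "sevgroup_ss_fraction": float(part.fractions["SevGroup"]),
        "mild_severe_mean_ncss_gap": float(abs(mild - severe)),
    }


def cleaning_roundtrip_study(seed: int = 0, n_subjects: int = 150) -> dict:
    """Corrupt a pristine cohort, clean it, and count unrecovered cells."""
    schema = ItemSchema.default()
    cfg = SimulationConfig(n_participants=n_subjects, seed=seed)
    visits, _, _ = generate_cohort(cfg)
    dirty = corrupt_records(
        visits, {"historical": 0.3, "monotone": 0.3}, seed=_sub_seed(seed, 1)
    )
    revised, report = clean_cohort(dirty)
    pristine = visits.sort_values(["participant_id", "visit_age_years"]).reset_index(
        drop=True
    )
    mismatches = int(
        (revised[schema.item_ids].to_numpy() != pristine[schema.item_ids].to_numpy()).sum()
    )
    return {
        "unrecovered_cells": mismatches,
        "cells_revised": report.total_revised,
        "total_cells": int(len(pristine) * len(schema)),
    }


def interaction_recovery_study(
    seed: int = 0, n_subjects: int = 600, n_seeds: int = 20, xci_effect: float = -0.05
) -> dict:
    """Recover the injected pXCI x severity interaction variance fraction.

    The truth fraction applies the identical percentile-and-partition
    pipeline to the latent (noise-free) per-subject grid-mean severity from
    the generator, so estimate and truth differ only by the estimation
    pipeline itself.
    """
    est, tru = [], []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_participants=n_subjects,
            seed=_sub_seed(seed, i),
            xci_effect=xci_effect,
            xci_informative_fraction=1.0,
        )
        visits, xci, truth = generate_cohort(cfg)
        _, preds = _fit_predict_score(visits)
        merged = preds.merge(xci, on="participant_id")
        merged["sev_group"] = [SEVERITY_MAP[g] for g in merged["genotype"]]
        _, part = fit_xci_model(merged)
        est.append(part.fractions["SevGroup:pXCI"])

        tp = truth["participants"].rename(columns={"latent_mean_css": "mean_predicted_css"})
        train = tp[tp["diagnosis"] == "classic"]
        scorer = NormativeScorer().fit(train)
        oracle = tp.copy()
        oracle["ncss"] = scorer.transform(tp)
        oracle = oracle.merge(xci, on="participant_id")
        oracle["sev_group"] = oracle["severity"]
        _, part_t = fit_xci_model(oracle)
        tru.append(part_t.fractions["SevGroup:pXCI"])
    mean_est, mean_tru = float(np.mean(est)), float(np.mean(tru))
    return {
        "mean_estimated_fraction": mean_est,
        "mean_truth_fraction": mean_tru,
        "relative_error": abs(mean_est - mean_tru) / mean_tru,
    }


def null_xci_study(seed: int = 0, n_subjects: int = 1000, n_seeds: int = 5) -> dict:
    """Null control: no injected XCI effect.

    Severe-group pXCI/nCSS correlations should average to ~0 and the
    interaction variance fraction should be negligible.
    """
    rs, fracs = [], []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_participants=n_subjects,
            seed=_sub_seed(seed, i),
            xci_effect=0.0,
            xci_informative_fraction=1.0,
        )
        visits, xci, _ = generate_cohort(cfg)
        _, preds = _fit_predict_score(visits)
        scores = preds.rename(columns={"ncss": "score"})
        res = grouped_correlations(scores, xci, "score")
        rs.append(res["severe"].r)
        merged = preds.merge(xci, on="participant_id")
        merged["sev_group"] = [SEVERITY_MAP[g] for g in merged["genotype"]]
        _, part = fit_xci_model(merged)
        fracs.append(part.fractions["SevGroup:pXCI"])
    return {
        "mean_severe_r": float(np.mean(rs)),
        "mean_abs_severe_r": float(np.mean(np.abs(rs))),
        "mean_interaction_fraction": float(np.mean(fracs)),
    }


def loocv_study(seed: int = 0, n_subjects: int = 60) -> dict:
    """Median leave-one-out RMSE on a compact default-condition cohort."""
    freqs = {"T158M": 0.3, "R168X": 0.25, "R294X": 0.25, "CTT": 0.2}
    cfg = SimulationConfig(
        n_participants=n_subjects, seed=seed, genotype_frequencies=freqs
    )
    visits, _, _ = generate_cohort(cfg)
    results = loocv(visits)
    summary = summarize_rmse(results).set_index("group")
    return {
        "median_rmse": float(summary.loc["overall", "median"]),
        "max_rmse": float(summary.loc["overall", "max"]),
        "n_evaluated": int(summary.loc["overall", "n"]),
        "residual_sd_truth": cfg.true_residual_sd,
    }
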