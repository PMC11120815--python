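"""Pseudo leave-one-out cross-validation of the growth model.

Every participant (classic or atypical) is evaluated against a model
trained on classic participants only, excluding the participant themself
when they are classic.  The held-out model conditions on the participant's
own observed visits to form the random-effect posterior, predicts at the
observed visit ages, and reports the per-individual root mean squared
error.  Atypical participants are always scored against the full classic
model, so their result does not depend on any leave-one-out split.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .growth import CSSGrowthModel, ConvergenceError
from .predict import posterior_random_effects

logger = logging.getLogger(__name__)

__all__ = ["loocv", "summarize_rmse"]


def _subject_rmse(model: CSSGrowthModel, sub: pd.DataFrame, forward_chain: bool) -> float:
    ages = sub["visit_age_years"].to_numpy(dtype=float)
    y = sub["css_total"].to_numpy(dtype=float)
    genotype = sub["genotype"].iloc[0]

    def predict_at(cond: pd.DataFrame, target: pd.DataFrame) -> np.ndarray:
        b, _ = posterior_random_effects(model, cond, genotype)
        ln_all = np.log(ages)  # decomposition anchored on the subject's full series
        mean_ln = ln_all.mean()
        dur = np.log(target["visit_age_years"].to_numpy(float)) - mean_ln
        df = pd.DataFrame(
            {
                "genotype": genotype,
                "mean_lnage_center": mean_ln - model.centering_,
                "duration": dur,
            }
        )
        X = model.fixed_design(df)
        Z = np.column_stack([np.ones(len(dur)), dur])
        return X @ model.fe_params_.to_numpy() + Z @ b

    if not forward_chain or len(sub) < 2:
        pred = predict_at(sub, sub)
        return float(np.sqrt(np.mean((pred - y) ** 2)))
    errs = []
    for k in range(1, len(sub)):
        pred = predict_at(sub.iloc[:k], sub.iloc[k : k + 1])
        errs.append(float(pred[0] - y[k]))
    return float(np.sqrt(np.mean(np.square(errs))))


def loocv(
    visits: pd.DataFrame,
    model_params: dict | None = None,
    forward_chain: bool = False,
) -> pd.DataFrame:
    """Per-participant cross-validated RMSE.

    Parameters
    ----------
    visits : long-format visit table with diagnosis labels.
    model_params : keyword arguments for :class:`CSSGrowthModel`.
    forward_chain : condition only on visits before each predicted visit
        (stricter; default conditions on the full observation set and
        predicts at the same ages, one RMSE per subject).

    Returns a DataFrame with participant_id, diagnosis, genotype, n_obs,
    rmse; participants whose held-out refit fails to converge are flagged
    with ``rmse = NaN`` and logged.
    """
    model_params = model_params or {}
    classic_ids = set(
        visits.loc[visits["diagnosis"] == "classic", "participant_id"].unique()
    )
    if not classic_ids:
        raise ValueError("no classic participants to train on")

    full_model = CSSGrowthModel(**model_params).fit(visits)

    rows = []
    for pid, sub in visits.groupby("participant_id", sort=True):
        sub = sub.sort_values("visit_age_years")
        diagnosis = sub["diagnosis"].iloc[0]
        if diagnosis == "classic":
            train = visits[
                (visits["diagnosis"] == "classic") & (visits["participant_id"] != pid)
            ]
            if train.empty:
                raise ValueError("training set empty after excluding the test subject")
            try:
                model = CSSGrowthModel(**model_params).fit(train)
            except (ConvergenceError, ValueError) as exc:
                logger.warning("held-out refit failed for %s: %s", pid, exc)
                rows.append(
                    {
                        "participant_id": pid,
                        "diagnosis": diagnosis,
                        "genotype": sub["genotype"].iloc[0],
                        "n_obs": len(sub),
                        "rmse": np.nan,
                    }
                )
                continue
        else:
            model = full_model
        rmse = _subject_rmse(model, sub, forward_chain)
        rows.append(
            {
                "participant_id": pid,
                "diagnosis": diagnosis,
                "genotype": sub["genotype"].iloc[0],
                "n_obs": len(sub),
                "rmse": rmse,
            }
        )
    return pd.DataFrame(rows)


def _five_number(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    outliers = x[(x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)]
    return {
        "n": len(x),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(x.min()),
        "max": float(x.max()),
        "n_outliers": int(len(outliers)),
    }


def summarize_rmse(results: pd.DataFrame) -> pd.DataFrame:
    """Five-number RMSE summaries per genotype group and overall."""
    ok = results.dropna(subset=["rmse"])
    if ok.empty:
        raise ValueError("no successful cross-validation results to summarize")
    rows = [{"group": "overall", **_five_number(ok["rmse"].to_numpy())}]
    for g, sub in ok.groupby("genotype", sort=True):
        rows.append({"group": str(g), **_five_number(sub["rmse"].to_numpy())})
    return pd.DataFrame(rows)
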