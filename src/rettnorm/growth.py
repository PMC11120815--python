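"""Conditional growth mixed-effects model of CSS on log-age and MECP2 genotype.

The model regresses total CSS on genotype crossed with three time terms --
the between-person component ``mean_lnage_center``, the within-person
component ``duration``, and their product -- with a subject-specific random
intercept and random ``duration`` slope (unstructured 2x2 covariance) and a
homoscedastic residual:

    CSS_ij = X_ij' gamma + U0_j + U1_j * Duration_ij + R_ij
    X      = genotype * (mean_lnage_center + duration
                         + mean_lnage_center:duration)

Estimation is REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.
Training is restricted to classic-diagnosis participants with visits in the
2-25 year window; the fitted object then predicts any participant (classic
or atypical) with a genotype seen in training.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .schema import canonical_genotype
from .timescale import decompose_time, prediction_grid

TIME_TERMS = ("mean_lnage_center", "duration", "mean_lnage_center:duration")


class ConvergenceError(RuntimeError):
    """REML optimisation failed to converge."""


def build_design(
    df: pd.DataFrame,
    levels: list[str],
    reference: str,
    interaction_terms: dict | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build the fixed-effects design matrix for the growth model.

    Treatment (dummy) coding with ``reference`` as baseline; each
    non-reference genotype interacts with the time terms listed for it in
    ``interaction_terms`` (default: every term for every level).  The fitter
    restricts the terms of groups with a single training subject, whose
    subject-constant between-person time makes those interaction columns
    exactly collinear with the group dummy.  Column order is fixed by
    ``levels`` so matrices built from different data frames align.
    """
    g = df["genotype"].to_numpy()
    m = df["mean_lnage_center"].to_numpy(dtype=float)
    d = df["duration"].to_numpy(dtype=float)
    md = m * d
    time_cols = {"mean_lnage_center": m, "duration": d, "mean_lnage_center:duration": md}

    nonref = [lev for lev in levels if lev != reference]
    if interaction_terms is None:
        interaction_terms = {lev: list(TIME_TERMS) for lev in nonref}
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for lev in nonref:
        cols.append((g == lev).astype(float))
        names.append(f"genotype[T.{lev}]")
    for term in TIME_TERMS:
        cols.append(time_cols[term])
        names.append(term)
    for lev in nonref:
        dummy = (g == lev).astype(float)
        for term in TIME_TERMS:
            if term not in interaction_terms.get(lev, ()):
                continue
            cols.append(dummy * time_cols[term])
            names.append(f"genotype[T.{lev}]:{term}")
    return np.column_stack(cols), names


class CSSGrowthModel(BaseEstimator):
    """Scikit-learn style estimator for the CSS growth mixed model.

    Parameters
    ----------
    training_diagnosis : diagnosis label the training set is restricted to
        (``"classic"``), or ``None`` to train on every row.
    age_window : visits outside this age range are dropped before fitting.
    reml : estimate variance components by REML (default) or ML.
    maxiter, rtol : optimiser budget and relative convergence tolerance.
    reference : genotype used as the treatment-coding baseline; ``None``
        picks the largest training group.  Predictions are invariant to
        this choice.

    Fitted attributes
    -----------------
    fe_params_ : pd.Series of fixed-effect coefficients (houses the gamma's).
    cov_re_ : 2x2 random-effect covariance (intercept, duration slope).
    scale_ : residual variance (CSS points squared).
    centering_ : cohort centering constant ``c`` for mean log-age.
    genotype_levels_, reference_ : genotype coding.
    group_weights_ : training-frequency weights per genotype (overall curve).
    n_subjects_, n_obs_, loglik_ : fit bookkeeping.
    """

    def __init__(
        self,
        training_diagnosis: str | None = "classic",
        age_window: tuple = (2.0, 25.0),
        reml: bool = True,
        maxiter: int = 200,
        rtol: float = 1e-8,
        reference: str | None = None,
    ):
        self.training_diagnosis = training_diagnosis
        self.age_window = age_window
        self.reml = reml
        self.maxiter = maxiter
        self.rtol = rtol
        self.reference = reference

    # -- fitting ---------------------------------------------------------

    def _training_frame(self, visits: pd.DataFrame) -> pd.DataFrame:
        req = {"participant_id", "genotype", "visit_age_years", "css_total"}
        missing = req - set(visits.columns)
        if missing:
            raise ValueError(f"visit table lacks columns: {sorted(missing)}")
        df = visits
        if self.training_diagnosis is not None and "diagnosis" in df.columns:
            df = df[df["diagnosis"] == self.training_diagnosis]
        lo, hi = self.age_window
        df = df[(df["visit_age_years"] >= lo) & (df["visit_age_years"] <= hi)]
        if df.empty:
            raise ValueError("no training visits after diagnosis/age restriction")
        return df.copy()

    def fit(self, X: pd.DataFrame, y=None) -> "CSSGrowthModel":
        """Fit on a long-format visit table (one row per participant-visit)."""
        df = self._training_frame(X)
        df["genotype"] = [canonical_genotype(g) for g in df["genotype"]]
        df, c = decompose_time(df)

        counts = df.groupby("genotype")["participant_id"].nunique()
        levels = list(counts.sort_values(ascending=False).index)
        if self.reference is None:
            reference = levels[0]
        else:
            reference = canonical_genotype(self.reference)
            if reference not in levels:
                raise ValueError(f"reference genotype {reference!r} not in training data")
        singles = counts[counts < 2]
        if len(singles):
            warnings.warn(
                f"genotype groups with a single subject retained: {list(singles.index)}",
                stacklevel=2,
            )
        # groups with one training subject cannot identify between-person
        # slopes (their dummy*mean_lnage_center columns are collinear with
        # the dummy); with several visits the duration slope remains
        # identifiable.  This keeps the design full rank and the fitted
        # values invariant to the reference-level choice.
        n_visits = df.groupby("genotype").size()
        interaction_terms = {}
        for lev in levels:
            if lev == reference:
                continue
            if counts[lev] >= 2:
                interaction_terms[lev] = list(TIME_TERMS)
            elif n_visits[lev] >= 2:
                interaction_terms[lev] = ["duration"]
            else:
                interaction_terms[lev] = []

        Xmat, names = build_design(df, levels, reference, interaction_terms)
        Z = np.column_stack([np.ones(len(df)), df["duration"].to_numpy(float)])
        endog = df["css_total"].to_numpy(dtype=float)
        groups = df["participant_id"].to_numpy()

        model = sm.MixedLM(endog, Xmat, groups=groups, exog_re=Z)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # powell fallback rescues near-boundary variance surfaces where
            # gradient-based optimisers stall
            res = model.fit(
                reml=self.reml, method=["lbfgs", "bfgs", "powell"], maxiter=self.maxiter
            )
        if not res.converged:
            raise ConvergenceError(
                f"mixed-model fit did not converge in {self.maxiter} iterations; "
                f"gradient norm at exit unknown, parameters: {res.params}"
            )

        self.fe_params_ = pd.Series(np.asarray(res.fe_params, float), index=names)
        self.cov_re_ = np.asarray(res.cov_re, dtype=float)
        self.scale_ = float(res.scale)
        self.centering_ = c
        self.genotype_levels_ = levels
        self.reference_ = reference
        self.interaction_terms_ = interaction_terms
        self.group_weights_ = (counts / counts.sum()).to_dict()
        self.n_subjects_ = int(df["participant_id"].nunique())
        self.n_obs_ = int(len(df))
        self.loglik_ = float(res.llf)
        return self

    # -- prediction helpers ---------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "fe_params_"):
            raise RuntimeError("model is not fitted")

    def fixed_design(self, df: pd.DataFrame) -> np.ndarray:
        """Design matrix for new rows (requires genotype, mean_lnage_center,
        duration columns), aligned to the training coding."""
        self._check_fitted()
        unknown = set(df["genotype"]) - set(self.genotype_levels_)
        if unknown:
            raise ValueError(
                f"genotype(s) absent from the fitted model: {sorted(unknown)}"
            )
        Xmat, names = build_design(
            df, self.genotype_levels_, self.reference_, self.interaction_terms_
        )
        assert names == list(self.fe_params_.index)
        return Xmat

    def predict_fixed(self, df: pd.DataFrame) -> np.ndarray:
        """Fixed-effects-only prediction for decomposed rows."""
        return self.fixed_design(df) @ self.fe_params_.to_numpy()

    def population_trajectory(self, genotype: str | None, ages=None) -> np.ndarray:
        """Mean severity trajectory for a genotype (or the frequency-weighted
        overall curve when ``genotype`` is None).

        Evaluates the fixed effects for a hypothetical subject whose mean
        log-age equals each grid age (``duration = 0``).
        """
        self._check_fitted()
        ages = prediction_grid() if ages is None else np.asarray(ages, dtype=float)
        if np.any(ages <= 0):
            raise ValueError("ages must be positive")
        if genotype is None:
            curves = {
                g: self.population_trajectory(g, ages) for g in self.genotype_levels_
            }
            w = self.group_weights_
            return sum(w[g] * curves[g] for g in self.genotype_levels_)
        genotype = canonical_genotype(genotype)
        df = pd.DataFrame(
            {
                "genotype": genotype,
                "mean_lnage_center": np.log(ages) - self.centering_,
                "duration": 0.0,
            }
        )
        return self.predict_fixed(df)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "fixed_effects": {k: float(v) for k, v in self.fe_params_.items()},
            "re_covariance": self.cov_re_.tolist(),
            "residual_variance": self.scale_,
            "centering_constant": self.centering_,
            "genotype_levels": self.genotype_levels_,
            "reference": self.reference_,
            "interaction_terms": self.interaction_terms_,
            "group_weights": {k: float(v) for k, v in self.group_weights_.items()},
            "n_subjects": self.n_subjects_,
            "n_obs": self.n_obs_,
            "loglik": self.loglik_,
            "params": {
                "training_diagnosis": self.training_diagnosis,
                "age_window": list(self.age_window),
                "reml": self.reml,
                "maxiter": self.maxiter,
                "rtol": self.rtol,
                "reference": self.reference,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CSSGrowthModel":
        p = d.get("params", {})
        obj = cls(
            training_diagnosis=p.get("training_diagnosis", "classic"),
            age_window=tuple(p.get("age_window", (2.0, 25.0))),
            reml=p.get("reml", True),
            maxiter=p.get("maxiter", 200),
            rtol=p.get("rtol", 1e-8),
            reference=p.get("reference"),
        )
        obj.fe_params_ = pd.Series(d["fixed_effects"])
        obj.cov_re_ = np.asarray(d["re_covariance"], dtype=float)
        obj.scale_ = float(d["residual_variance"])
        obj.centering_ = float(d["centering_constant"])
        obj.genotype_levels_ = list(d["genotype_levels"])
        obj.reference_ = d["reference"]
        obj.interaction_terms_ = d.get(
            "interaction_terms",
            {
                lev: list(TIME_TERMS)
                for lev in obj.genotype_levels_
                if lev != obj.reference_
            },
        )
        obj.group_weights_ = dict(d["group_weights"])
        obj.n_subjects_ = int(d["n_subjects"])
        obj.n_obs_ = int(d["n_obs"])
        obj.loglik_ = float(d["loglik"])
        return obj

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "CSSGrowthModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_growth_model(visits: pd.DataFrame, **params) -> CSSGrowthModel:
    """Functional wrapper: fit a :class:`CSSGrowthModel` on a visit table."""
    return CSSGrowthModel(**params).fit(visits)
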