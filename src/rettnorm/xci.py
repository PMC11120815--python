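"""X-chromosome-inactivation vs severity analysis.

Correlates the percentage of paternal X inactivation (pXCI, measured in
blood; higher means more silencing of the variant-bearing allele) with
severity -- either the raw CSS at the visit nearest the cohort mean age, or
the age- and genotype-normalized nCSS -- overall and within the mild and
severe variant groups.  A simplified linear model

    nCSS ~ SevGroup + pXCI + SevGroup:pXCI

is then partitioned by sequential (Type-I) sums of squares, each term's SS
divided by the total SS, to quantify how much severity variation the
variant-severity x pXCI interaction explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .schema import SEVERITY_MAP

__all__ = [
    "CorrelationResult",
    "VariancePartition",
    "nearest_visit_css",
    "cohort_mean_visit_age",
    "pearson_test",
    "grouped_correlations",
    "fit_xci_model",
]


@dataclass
class CorrelationResult:
    n: int
    r: float
    p: float
    ci95: tuple


@dataclass
class VariancePartition:
    """Sequential sum-of-squares decomposition of the simplified XCI model."""

    ss: dict  # term -> sum of squares
    fractions: dict  # term -> SS / total SS

    def to_frame(self) -> pd.DataFrame:
        terms = list(self.ss)
        return pd.DataFrame(
            {
                "term": terms,
                "sum_sq": [self.ss[t] for t in terms],
                "fraction": [self.fractions[t] for t in terms],
            }
        )


def nearest_visit_css(visits: pd.DataFrame, target_age: float) -> tuple[int, float]:
    """CSS at the visit nearest ``target_age`` (ties go to the earlier visit)."""
    if len(visits) == 0:
        raise ValueError("participant has no visits")
    sub = visits.sort_values("visit_age_years")
    ages = sub["visit_age_years"].to_numpy(dtype=float)
    i = int(np.argmin(np.abs(ages - target_age)))  # first minimum = earlier visit
    return int(sub["css_total"].iloc[i]), float(ages[i])


def cohort_mean_visit_age(visits: pd.DataFrame) -> float:
    """Unweighted mean age over all visits (every visit counted once)."""
    if len(visits) == 0:
        raise ValueError("no visits in cohort")
    return float(visits["visit_age_years"].mean())


def pearson_test(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided t-test p and Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must align")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation input")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(0.95)  # Fisher z
    return CorrelationResult(
        n=len(x), r=float(res.statistic), p=float(res.pvalue), ci95=(float(ci.low), float(ci.high))
    )


def grouped_correlations(
    scores: pd.DataFrame,
    xci: pd.DataFrame,
    score_col: str,
    severity_map: dict | None = None,
) -> dict[str, CorrelationResult]:
    """pXCI-severity correlations for {all, mild, severe} informative subjects.

    ``scores`` needs ``participant_id``, ``genotype`` and ``score_col``
    (raw nearest-visit CSS or nCSS); ``xci`` needs ``participant_id``,
    ``pxci``, ``informative``.
    """
    severity_map = severity_map or SEVERITY_MAP
    merged = scores.merge(xci, on="participant_id", how="inner")
    merged = merged[merged["informative"] & merged["pxci"].notna()]
    merged = merged.assign(severity=[severity_map[g] for g in merged["genotype"]])
    out = {
        "all": pearson_test(merged["pxci"], merged[score_col]),
    }
    for grp in ("mild", "severe"):
        sub = merged[merged["severity"] == grp]
        out[grp] = pearson_test(sub["pxci"], sub[score_col])
    assert out["mild"].n + out["severe"].n == out["all"].n
    return out


def fit_xci_model(df: pd.DataFrame) -> tuple[pd.Series, VariancePartition]:
    """OLS of nCSS on variant severity, pXCI and their interaction.

    ``df`` needs complete-case columns ``ncss``, ``sev_group`` (binary
    labels) and ``pxci`` (percent, 0-100).  Sums of squares are sequential
    in the order SevGroup, pXCI, SevGroup:pXCI (main effects before the
    interaction); fractions are each term's SS over the total SS and sum
    to 1 with the residual.
    """
    needed = {"ncss", "sev_group", "pxci"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    data = df.dropna(subset=list(needed))
    if data["sev_group"].nunique() < 2:
        raise ValueError("sev_group is constant; interaction is inestimable")
    fit = smf.ols("ncss ~ C(sev_group) + pxci + C(sev_group):pxci", data=data).fit()
    anova = sm.stats.anova_lm(fit, typ=1)
    rename = {
        "C(sev_group)": "SevGroup",
        "pxci": "pXCI",
        "C(sev_group):pxci": "SevGroup:pXCI",
        "Residual": "residual",
    }
    ss = {rename[k]: float(v) for k, v in anova["sum_sq"].items()}
    total = sum(ss.values())
    fractions = {k: v / total for k, v in ss.items()}
    assert abs(sum(fractions.values()) - 1.0) < 1e-9
    return fit.params, VariancePartition(ss=ss, fractions=fractions)
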