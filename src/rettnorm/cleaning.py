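"""Systematic revision of logically inconsistent longitudinal CSS item series.

Two item classes carry longitudinal constraints that clinic records sometimes
violate:

* **historical** items record a fixed historical fact; any later value that
  deviates from the earliest reported observation is replaced with it.
* **monotone** items can only worsen or plateau; a value below the revised
  value of its predecessor is replaced with that predecessor (a left-to-right
  running maximum, the unique idempotent reading of "nearest previous
  observation").

Free-class items are never revised.  Revised totals are recomputed as exact
item sums.  Visits with a missing item value yield no total; participants
with no computable total at any visit are dropped and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import CSS_MAX, ItemSchema

__all__ = [
    "revise_historical",
    "revise_monotone",
    "recompute_css",
    "clean_cohort",
    "CleaningReport",
    "LongitudinalCleaner",
]


def revise_historical(scores):
    """Replace every value deviating from the earliest observation with it."""
    scores = list(scores)
    if not scores:
        raise ValueError("cannot revise an empty series")
    return [scores[0]] * len(scores)


def revise_monotone(scores):
    """Replace decreases with the revised predecessor (running maximum)."""
    scores = list(scores)
    if not scores:
        raise ValueError("cannot revise an empty series")
    out = [scores[0]]
    for s in scores[1:]:
        out.append(s if s >= out[-1] else out[-1])
    return out


def recompute_css(item_scores: dict, schema: ItemSchema) -> int:
    """Sum the 13 item scores into a total CSS, validating each against its cap."""
    total = 0
    for item in schema:
        if item.item_id not in item_scores:
            raise ValueError(f"missing score for item {item.item_id!r}")
        v = item_scores[item.item_id]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing score for item {item.item_id!r}")
        v = int(v)
        if not 0 <= v <= item.max_score:
            raise ValueError(
                f"score {v} for item {item.item_id!r} outside [0, {item.max_score}]"
            )
        total += v
    assert 0 <= total <= CSS_MAX
    return total


@dataclass
class CleaningReport:
    """Per-item revision counts plus dropped participants."""

    n_revised: dict = field(default_factory=dict)  # item_id -> revised cells
    n_missing: dict = field(default_factory=dict)  # item_id -> missing cells
    n_visits_dropped: int = 0
    dropped_participants: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        items = sorted(set(self.n_revised) | set(self.n_missing))
        return pd.DataFrame(
            {
                "item_id": items,
                "n_revised": [self.n_revised.get(i, 0) for i in items],
                "n_missing": [self.n_missing.get(i, 0) for i in items],
            }
        )

    @property
    def total_revised(self) -> int:
        return sum(self.n_revised.values())


def clean_cohort(
    visits: pd.DataFrame, schema: ItemSchema | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the class-specific revision rules to a long-format visit table.

    Returns the revised table (visits sorted by participant and age, totals
    recomputed; visits with a missing item removed) and a
    :class:`CleaningReport`.  Participants with no complete visit are dropped
    entirely and listed in the report.
    """
    schema = schema or ItemSchema.default()
    unknown = [c for c in visits.columns if c.startswith("item_") and c not in schema.item_ids]
    if unknown:
        raise ValueError(f"unknown item columns: {unknown}")
    missing_cols = [i for i in schema.item_ids if i not in visits.columns]
    if missing_cols:
        raise ValueError(f"visit table lacks item columns: {missing_cols}")

    out = visits.sort_values(["participant_id", "visit_age_years"]).reset_index(drop=True)
    out = out.copy()
    report = CleaningReport()

    item_cols = schema.item_ids
    incomplete = out[item_cols].isna().any(axis=1)
    for col in item_cols:
        n_miss = int(out[col].isna().sum())
        if n_miss:
            report.n_missing[col] = n_miss
    report.n_visits_dropped = int(incomplete.sum())
    if incomplete.any():
        dropped_all = set(out["participant_id"]) - set(
            out.loc[~incomplete, "participant_id"]
        )
        report.dropped_participants = sorted(dropped_all)
        out = out.loc[~incomplete].reset_index(drop=True)

    for item in schema:
        if item.item_class == "free":
            continue
        rule = revise_historical if item.item_class == "historical" else revise_monotone
        col = item.item_id
        revised_count = 0
        for _, idx in out.groupby("participant_id", sort=False).groups.items():
            idx = np.asarray(idx)
            vals = out.loc[idx, col].astype(int).tolist()
            new = rule(vals)
            if new != vals:
                revised_count += sum(a != b for a, b in zip(vals, new))
                out.loc[idx, col] = new
        if revised_count:
            report.n_revised[col] = revised_count

    out[item_cols] = out[item_cols].astype(int)
    out["css_total"] = out[item_cols].sum(axis=1).astype(int)
    return out, report


class LongitudinalCleaner:
    """Stateless transformer wrapping :func:`clean_cohort`.

    Follows the scikit-learn transformer protocol so it can open a
    pipeline; ``fit`` only validates the schema.  The report of the most
    recent ``transform`` is kept on ``report_``.
    """

    def __init__(self, schema: ItemSchema | None = None):
        self.schema = schema

    def get_params(self, deep: bool = True) -> dict:
        return {"schema": self.schema}

    def set_params(self, **params) -> "LongitudinalCleaner":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "LongitudinalCleaner":
        self.schema_ = self.schema or ItemSchema.default()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "schema_"):
            self.fit(X)
        revised, self.report_ = clean_cohort(X, self.schema_)
        return revised

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
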