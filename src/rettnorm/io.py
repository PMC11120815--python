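"""Reading and writing the pipeline's CSV tables.

All tables are UTF-8 CSV with a header row.  The long-format visit table
has one row per participant-visit:

    participant_id, diagnosis, sex, genotype, visit_age_years,
    item_01..item_13, css_total

Genotype labels are canonicalized case-insensitively with an alias map
("Large Deletion" -> large_deletion).  A ``css_total`` that disagrees with
the item sum is flagged and recomputed from the items.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .schema import DIAGNOSES, ItemSchema, canonical_genotype

logger = logging.getLogger(__name__)

__all__ = ["read_visit_table", "write_visit_table", "read_xci_table", "write_xci_table"]

VISIT_COLUMNS = ["participant_id", "diagnosis", "sex", "genotype", "visit_age_years"]


def read_visit_table(path, schema: ItemSchema | None = None) -> pd.DataFrame:
    """Read and validate a long-format visit CSV.

    Returns the table with canonical genotype labels, visits sorted by
    participant and age, and totals consistent with item sums.  Schema
    violations raise ``ValueError`` naming the offending rows.
    """
    schema = schema or ItemSchema.default()
    df = pd.read_csv(path)
    required = VISIT_COLUMNS + schema.item_ids + ["css_total"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    ages = pd.to_numeric(df["visit_age_years"], errors="coerce")
    bad = df.index[ages.isna()].tolist()
    if bad:
        raise ValueError(f"{path}: non-numeric visit_age_years in rows {bad[:5]}")
    df["visit_age_years"] = ages.astype(float)

    try:
        df["genotype"] = [canonical_genotype(g) for g in df["genotype"]]
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc

    bad_diag = set(df["diagnosis"].dropna()) - set(DIAGNOSES)
    if bad_diag:
        raise ValueError(f"{path}: unknown diagnosis labels {sorted(bad_diag)}")

    item_sum = df[schema.item_ids].sum(axis=1)
    complete = df[schema.item_ids].notna().all(axis=1)
    mismatch = complete & df["css_total"].notna() & (df["css_total"] != item_sum)
    if mismatch.any():
        rows = df.index[mismatch].tolist()
        logger.warning(
            "%s: css_total != item sum in %d row(s) (e.g. %s); recomputed from items",
            path,
            len(rows),
            rows[:5],
        )
        df.loc[mismatch, "css_total"] = item_sum[mismatch]

    return df.sort_values(["participant_id", "visit_age_years"]).reset_index(drop=True)


def write_visit_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_xci_table(path) -> pd.DataFrame:
    """Read the participant-level XCI table (participant_id, pxci, informative)."""
    df = pd.read_csv(path)
    missing = [c for c in ("participant_id", "pxci", "informative") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["pxci"] = pd.to_numeric(df["pxci"], errors="coerce")
    df["informative"] = df["informative"].astype(bool)
    out_of_range = df["pxci"].notna() & ((df["pxci"] < 0) | (df["pxci"] > 100))
    if out_of_range.any():
        raise ValueError(f"{path}: pxci outside [0,100] in rows {df.index[out_of_range].tolist()[:5]}")
    if (df["pxci"].notna() & ~df["informative"]).any():
        raise ValueError(f"{path}: pxci present for uninformative participants")
    return df


def write_xci_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
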