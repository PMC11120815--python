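"""Log transformation of visit age and its between/within-person decomposition.

CSS progression follows a logarithmic growth pattern, so visit age is
log-transformed before modelling.  The transformed age is then split into a
between-person component (the subject's mean log-age, centered on the
training-cohort mean) and a within-person component ("duration", the
deviation of each visit's log-age from the subject's own mean).  Only the
within-person component carries subject-specific random slopes downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["decompose_time", "prediction_grid"]


def prediction_grid(start: float = 2.0, stop: float = 25.0, step: float = 0.1) -> np.ndarray:
    """Inclusive, equally spaced age grid (default 2.0..25.0 by 0.1; 231 points)."""
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


def decompose_time(
    visits: pd.DataFrame,
    training_ids=None,
    centering_constant: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Decompose log visit age into between- and within-person components.

    Parameters
    ----------
    visits : DataFrame with ``participant_id`` and ``visit_age_years``.
    training_ids : iterable of participant ids whose subject-mean log-ages
        define the centering constant.  Defaults to all subjects present.
        Ignored when ``centering_constant`` is given.
    centering_constant : previously computed cohort constant ``c``; pass it
        to decompose held-out subjects deterministically.

    Returns
    -------
    (decomposed, c) : copy of ``visits`` with columns ``ln_age``,
        ``mean_lnage_center`` (subject mean log-age minus ``c``; constant
        within subject) and ``duration`` (log-age minus subject mean; sums
        to zero within subject), plus the constant ``c``.
    """
    ages = visits["visit_age_years"].to_numpy(dtype=float)
    if np.any(ages <= 0):
        raise ValueError("visit ages must be positive to log-transform")
    out = visits.copy()
    out["ln_age"] = np.log(ages)
    subj_mean = out.groupby("participant_id")["ln_age"].transform("mean")

    if centering_constant is None:
        per_subject = out.groupby("participant_id")["ln_age"].mean()
        if training_ids is not None:
            training_ids = list(training_ids)
            if len(training_ids) == 0:
                raise ValueError("training set is empty")
            missing = set(training_ids) - set(per_subject.index)
            if missing:
                raise ValueError(f"training ids absent from visit table: {sorted(missing)[:5]}")
            per_subject = per_subject.loc[training_ids]
        centering_constant = float(per_subject.mean())

    out["mean_lnage_center"] = subj_mean - centering_constant
    out["duration"] = out["ln_age"] - subj_mean
    return out, float(centering_constant)
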