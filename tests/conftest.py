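import numpy as np
import pandas as pd
import pytest

import rettnorm as rn


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort, small enough for fast unit tests."""
    cfg = rn.SimulationConfig(n_participants=120, seed=7)
    visits, xci, truth = rn.generate_cohort(cfg)
    return cfg, visits, xci, truth


@pytest.fixture(scope="session")
def fitted_model(small_cohort):
    _, visits, _, _ = small_cohort
    return rn.CSSGrowthModel().fit(visits)


def make_visits(records):
    """Build a minimal visit table from (pid, genotype, age, css) tuples."""
    rows = []
    schema = rn.ItemSchema.default()
    for pid, genotype, age, css in records:
        row = {
            "participant_id": pid,
            "diagnosis": "classic",
            "sex": "F",
            "genotype": genotype,
            "visit_age_years": float(age),
        }
        # arbitrary consistent item fill: all free items, capped
        remaining = int(css)
        for item in schema:
            v = min(item.max_score, remaining)
            row[item.item_id] = v
            remaining -= v
        row["css_total"] = int(css)
        rows.append(row)
    return pd.DataFrame(rows)


def make_model(
    levels,
    reference,
    coef=None,
    re_cov=((0.0, 0.0), (0.0, 0.0)),
    resid_var=1.0,
    centering=0.0,
    weights=None,
):
    """Construct a fitted CSSGrowthModel directly from coefficients.

    ``coef`` maps design-term names to values; unnamed terms default to 0.
    Term names follow the model's treatment coding, e.g. ``Intercept``,
    ``genotype[T.R294X]``, ``mean_lnage_center``, ``duration``,
    ``mean_lnage_center:duration`` and their genotype interactions.
    """
    time_terms = ["mean_lnage_center", "duration", "mean_lnage_center:duration"]
    nonref = [lev for lev in levels if lev != reference]
    names = (
        ["Intercept"]
        + [f"genotype[T.{lev}]" for lev in nonref]
        + time_terms
        + [f"genotype[T.{lev}]:{t}" for lev in nonref for t in time_terms]
    )
    coef = coef or {}
    unknown = set(coef) - set(names)
    assert not unknown, f"unknown coefficient names {unknown}"
    weights = weights or {lev: 1.0 / len(levels) for lev in levels}
    return rn.CSSGrowthModel.from_dict(
        {
            "fixed_effects": {n: float(coef.get(n, 0.0)) for n in names},
            "re_covariance": [list(map(float, row)) for row in re_cov],
            "residual_variance": float(resid_var),
            "centering_constant": float(centering),
            "genotype_levels": list(levels),
            "reference": reference,
            "group_weights": weights,
            "n_subjects": 0,
            "n_obs": 0,
            "loglik": 0.0,
        }
    )


@pytest.fixture
def toy_visits():
    return make_visits(
        [
            ("A", "T158M", 3.0, 10),
            ("A", "T158M", 5.0, 14),
            ("A", "T158M", 8.0, 18),
            ("B", "R294X", 4.0, 8),
            ("B", "R294X", 9.0, 12),
        ]
    )
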