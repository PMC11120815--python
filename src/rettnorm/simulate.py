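"""Synthetic longitudinal cohort generator with known ground truth.

Emulates a Rett-syndrome natural-history cohort: eleven common MECP2 variant
groups at realistic frequencies, 1-17 clinic visits per participant between
ages 2 and 25, total CSS following a log-age conditional growth model with
subject-specific random intercepts and within-person slopes, an item-level
decomposition of each total into 13 Likert items respecting their
longitudinal class, a latent paternal-XCI percentage per participant, and an
injected pXCI x variant-severity interaction acting on the subject intercept
of severe-variant participants.

The generative mean for participant *j* at visit *i* is

    mu_ij = (a_g + U0j + shift_j) + s_g * t_ij + U1j * Dur_ij
    t_ij  = M_j + M_j * Dur_ij + Dur_ij

where ``M_j`` is the subject's centered mean log-age (between-person time),
``Dur_ij`` the within-person deviation of log-age from the subject mean,
``(a_g, s_g)`` genotype-specific intercept/slope, ``(U0j, U1j)`` jointly
Gaussian random effects, and ``shift_j = xci_effect * (pXCI_j - 50)`` for
severe-variant participants (0 otherwise).  Observed totals add Gaussian
residual noise, then are rounded and clipped to [0, 58].

A separate corruption operator injects the two kinds of logical
inconsistency the cleaning rules repair: later-visit deviations of fixed
historical items, and downward deviations from a plateau in monotone items.
Corruptions are placed so that the one-pass revision rules recover the
pristine series exactly (historical items are never corrupted at the first
visit; monotone corruptions only push a plateaued value below its
predecessor).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    GENOTYPES,
    SEVERITY_MAP,
    ItemSchema,
)
from .timescale import prediction_grid

#: Genotype frequencies of the eleven common variant groups, matching the
#: composition of the modelled natural-history cohort (n = 1178).
DEFAULT_GENOTYPE_COUNTS = {
    "early_truncation": 111,
    "R106W": 40,
    "R133C": 94,
    "T158M": 124,
    "R168X": 133,
    "R255X": 123,
    "R270X": 77,
    "R294X": 77,
    "R306C": 106,
    "large_deletion": 117,
    "CTT": 176,
}
_TOTAL = sum(DEFAULT_GENOTYPE_COUNTS.values())
DEFAULT_GENOTYPE_FREQUENCIES = {g: c / _TOTAL for g, c in DEFAULT_GENOTYPE_COUNTS.items()}

#: True genotype intercepts (CSS points at the cohort-mean log age) and
#: slopes (CSS points per unit log-age).  Severe variants sit roughly eight
#: points above mild ones, mirroring established genotype-phenotype spread.
DEFAULT_INTERCEPTS = {
    "R106W": 25.0,
    "T158M": 24.0,
    "R168X": 24.0,
    "R255X": 23.0,
    "R270X": 25.0,
    "early_truncation": 24.0,
    "large_deletion": 24.0,
    "R133C": 16.0,
    "R294X": 15.0,
    "R306C": 16.0,
    "CTT": 17.0,
}
DEFAULT_SLOPES = {
    "R106W": 5.0,
    "T158M": 5.2,
    "R168X": 4.8,
    "R255X": 5.0,
    "R270X": 5.0,
    "early_truncation": 5.0,
    "large_deletion": 5.0,
    "R133C": 4.0,
    "R294X": 3.6,
    "R306C": 4.0,
    "CTT": 4.2,
}


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic cohort.

    Defaults reproduce the study conditions: 1178 participants at the
    published genotype frequencies, ~15% atypical diagnoses, a mean of ~5
    visits per participant (range 1-17) at ages 2-25, residual SD 2 CSS
    points, and a negative pXCI effect of 0.04 CSS points per percentage
    point of paternal inactivation restricted to severe variants (calibrated
    to give a severe-group pXCI/nCSS correlation near -0.2).
    """

    n_participants: int = 1178
    genotype_frequencies: dict = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_FREQUENCIES)
    )
    atypical_fraction: float = 175 / 1178
    mean_extra_visits: float = 4.0  # visit count = 1 + Poisson(mean), capped at 17
    max_visits: int = 17
    age_window: tuple = (2.0, 25.0)
    first_age_range: tuple = (2.0, 12.0)
    visit_gap_offset: float = 0.5  # years; gap = offset + Exp(scale)
    visit_gap_scale: float = 0.7
    true_intercepts: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    true_slopes: dict = field(default_factory=lambda: dict(DEFAULT_SLOPES))
    true_re_covariance: tuple = ((16.0, 2.0), (2.0, 1.0))
    true_residual_sd: float = 2.0
    xci_informative_fraction: float = 198 / 1178
    xci_effect: float = -0.04  # CSS points per pXCI percentage point, severe only
    corruption_rates: dict = field(
        default_factory=lambda: {"historical": 0.05, "monotone": 0.05}
    )
    seed: int = 0

    @classmethod
    def for_parameter_recovery(
        cls, seed: int = 0, n_participants: int = 300
    ) -> "SimulationConfig":
        """Well-identified design for parameter-recovery exercises.

        The cohort defaults mimic clinic visit spacing, under which the
        duration-slope variance is only weakly identified (within-person
        log-age spread is small).  Recovery exercises instead use ~9 visits
        per subject spread over a wide age span and a larger slope variance,
        so every variance component is informative at n = 300 subjects.
        """
        return cls(
            n_participants=n_participants,
            seed=seed,
            first_age_range=(2.0, 6.0),
            mean_extra_visits=8.0,
            visit_gap_offset=1.0,
            visit_gap_scale=1.2,
            true_re_covariance=((16.0, 3.0), (3.0, 4.0)),
        )

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        freqs = self.genotype_frequencies
        unknown = set(freqs) - set(GENOTYPES)
        if unknown:
            raise ValueError(f"unknown genotype groups in frequencies: {unknown}")
        if abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise ValueError("genotype_frequencies must sum to 1")
        D = np.asarray(self.true_re_covariance, dtype=float)
        if D.shape != (2, 2) or not np.allclose(D, D.T):
            raise ValueError("true_re_covariance must be a symmetric 2x2 matrix")
        if np.min(np.linalg.eigvalsh(D)) < -1e-12:
            raise ValueError("true_re_covariance must be positive semidefinite")
        if self.true_residual_sd < 0:
            raise ValueError("true_residual_sd must be non-negative")
        if not 0 <= self.atypical_fraction <= 1:
            raise ValueError("atypical_fraction must be in [0,1]")
        if not 0 <= self.xci_informative_fraction <= 1:
            raise ValueError("xci_informative_fraction must be in [0,1]")
        for k, v in self.corruption_rates.items():
            if not 0 <= v <= 1:
                raise ValueError(f"corruption rate for {k!r} must be in [0,1]")


def _draw_visit_ages(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    n = 1 + min(cfg.max_visits - 1, int(rng.poisson(cfg.mean_extra_visits)))
    first = rng.uniform(*cfg.first_age_range)
    gaps = cfg.visit_gap_offset + rng.exponential(cfg.visit_gap_scale, size=n - 1)
    ages = first + np.concatenate([[0.0], np.cumsum(gaps)])
    ages = ages[ages <= cfg.age_window[1]]
    return np.round(ages, 2)


def _allocate_items(
    rng: np.random.Generator, totals: np.ndarray, schema: ItemSchema
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose visit totals into per-item scores respecting item classes.

    Historical items are constant across visits, monotone items
    non-decreasing, free items unconstrained.  Returns ``(scores, totals)``
    where ``scores`` is (n_visits, 13) and ``totals`` the (possibly adjusted)
    row sums: if a total drops below the floor set by the constant historical
    and non-decreasing monotone parts, the total is redefined upward to keep
    item sums exact.
    """
    hist = schema.by_class("historical")
    mono = schema.by_class("monotone")
    free = schema.by_class("free")
    ch = np.array([it.max_score for it in hist])
    cm = np.array([it.max_score for it in mono])
    cf = np.array([it.max_score for it in free])
    Ch, Cm, Cf = ch.sum(), cm.sum(), cf.sum()

    totals = np.asarray(totals, dtype=int)
    n = len(totals)
    # constant historical allocation, proportional to the subject's mean severity
    h_lo = max(0, int(totals.max()) - Cm - Cf)
    h_hi = min(Ch, int(totals.min()))
    H = int(np.clip(round(totals.mean() * Ch / 58.0), h_lo, max(h_lo, h_hi)))
    h_scores = rng.multivariate_hypergeometric(ch, H)

    m_scores = np.zeros((n, len(cm)), dtype=int)
    f_scores = np.zeros((n, len(cf)), dtype=int)
    out_totals = np.zeros(n, dtype=int)
    M_prev = 0
    m_prev = np.zeros(len(cm), dtype=int)
    for t in range(n):
        rem = int(totals[t]) - H
        lo = max(M_prev, rem - Cf)
        hi = min(Cm, rem)
        desired = round(rem * Cm / (Cm + Cf)) if rem > 0 else 0
        M_t = int(np.clip(desired, lo, max(lo, hi)))
        inc = M_t - M_prev
        if inc > 0:
            room = cm - m_prev
            m_prev = m_prev + rng.multivariate_hypergeometric(room, inc)
        m_scores[t] = m_prev
        F_t = int(np.clip(rem - M_t, 0, Cf))
        f_scores[t] = rng.multivariate_hypergeometric(cf, F_t)
        out_totals[t] = H + M_t + F_t
        M_prev = M_t

    # assemble in schema order
    scores = np.zeros((n, len(schema)), dtype=int)
    cols = {it.item_id: i for i, it in enumerate(schema)}
    for j, it in enumerate(hist):
        scores[:, cols[it.item_id]] = h_scores[j]
    for j, it in enumerate(mono):
        scores[:, cols[it.item_id]] = m_scores[:, j]
    for j, it in enumerate(free):
        scores[:, cols[it.item_id]] = f_scores[:, j]
    return scores, out_totals


def generate_cohort(
    config: SimulationConfig, schema: ItemSchema | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate one synthetic cohort.

    Returns ``(visits, xci, truth)``:

    * ``visits`` -- long-format visit table (one row per participant-visit)
      with columns ``participant_id, diagnosis, sex, genotype,
      visit_age_years, item_01..item_13, css_total``.
    * ``xci`` -- one row per participant: ``participant_id, pxci,
      informative`` (``pxci`` is empty where uninformative).
    * ``truth`` -- dict with the realized latent state: per-participant
      random effects, XCI intercept shift, latent pXCI, subject mean
      log-age, latent grid-mean severity, plus the generative parameters
      and the cohort centering constant.
    """
    config.validate()
    schema = schema or ItemSchema.default()
    rng = np.random.default_rng(config.seed)

    genos = list(config.genotype_frequencies)
    probs = np.array([config.genotype_frequencies[g] for g in genos])
    D = np.asarray(config.true_re_covariance, dtype=float)

    n = config.n_participants
    pid_width = max(4, len(str(n)))
    genotype = rng.choice(genos, size=n, p=probs)
    atypical = rng.random(n) < config.atypical_fraction
    re = rng.multivariate_normal([0.0, 0.0], D, size=n)
    pxci = rng.uniform(0.0, 100.0, size=n)
    informative = rng.random(n) < config.xci_informative_fraction
    severity = np.array([SEVERITY_MAP[g] for g in genotype])
    shift = np.where(severity == "severe", config.xci_effect * (pxci - 50.0), 0.0)

    ages_per = [_draw_visit_ages(rng, config) for _ in range(n)]
    mean_lnage = np.array([np.log(a).mean() for a in ages_per])
    classic = ~atypical
    if classic.sum() == 0:
        c = float(mean_lnage.mean())
    else:
        c = float(mean_lnage[classic].mean())

    visit_rows = []
    latent_mean = np.zeros(n)
    grid_ln = np.log(prediction_grid())
    for j in range(n):
        g = genotype[j]
        a_g = config.true_intercepts[g]
        s_g = config.true_slopes[g]
        m_j = mean_lnage[j] - c
        ages = ages_per[j]
        d = np.log(ages) - mean_lnage[j]
        t_ij = m_j + m_j * d + d
        mu = a_g + re[j, 0] + shift[j] + s_g * t_ij + re[j, 1] * d
        y = mu
        if config.true_residual_sd > 0:
            y = y + rng.normal(0.0, config.true_residual_sd, size=len(ages))
        totals = np.clip(np.rint(y), 0, 58).astype(int)
        scores, totals = _allocate_items(rng, totals, schema)

        d_grid = grid_ln - mean_lnage[j]
        t_grid = m_j + m_j * d_grid + d_grid
        latent_mean[j] = float(
            np.mean(a_g + re[j, 0] + shift[j] + s_g * t_grid + re[j, 1] * d_grid)
        )

        pid = f"P{j + 1:0{pid_width}d}"
        diag = "atypical" if atypical[j] else "classic"
        for t, age in enumerate(ages):
            row = {
                "participant_id": pid,
                "diagnosis": diag,
                "sex": "F",
                "genotype": g,
                "visit_age_years": float(age),
            }
            for k, it in enumerate(schema):
                row[it.item_id] = int(scores[t, k])
            row["css_total"] = int(totals[t])
            visit_rows.append(row)

    visits = pd.DataFrame(visit_rows)
    pids = [f"P{j + 1:0{pid_width}d}" for j in range(n)]
    xci = pd.DataFrame(
        {
            "participant_id": pids,
            "pxci": np.where(informative, np.round(pxci, 2), np.nan),
            "informative": informative,
        }
    )
    truth_participants = pd.DataFrame(
        {
            "participant_id": pids,
            "genotype": genotype,
            "diagnosis": np.where(atypical, "atypical", "classic"),
            "severity": severity,
            "u0": re[:, 0],
            "u1": re[:, 1],
            "xci_shift": shift,
            "pxci_latent": pxci,
            "informative": informative,
            "mean_lnage": mean_lnage,
            "latent_mean_css": latent_mean,
        }
    )
    truth = {
        "config": dataclasses.asdict(config),
        "centering_constant": c,
        "participants": truth_participants,
    }
    return visits, xci, truth


def true_fixed_effects(
    config: SimulationConfig, levels: list[str], reference: str
) -> dict[str, float]:
    """Expand the generator's per-genotype (intercept, slope) truth into the
    growth model's coefficient basis (treatment coding with ``reference``).

    The generative model applies one genotype slope ``s_g`` to all three
    time terms, so the expanded truth repeats ``s_g`` across
    ``mean_lnage_center``, ``duration`` and their product.
    """
    a, s = config.true_intercepts, config.true_slopes
    time_terms = ("mean_lnage_center", "duration", "mean_lnage_center:duration")
    out = {"Intercept": a[reference]}
    nonref = [lev for lev in levels if lev != reference]
    for lev in nonref:
        out[f"genotype[T.{lev}]"] = a[lev] - a[reference]
    for term in time_terms:
        out[term] = s[reference]
    for lev in nonref:
        for term in time_terms:
            out[f"genotype[T.{lev}]:{term}"] = s[lev] - s[reference]
    return out


def corrupt_records(
    visits: pd.DataFrame,
    corruption_rates: dict,
    seed: int,
    schema: ItemSchema | None = None,
) -> pd.DataFrame:
    """Inject logical inconsistencies into item series; returns a dirty copy.

    Historical items are flipped to a different value at post-first visits
    with the ``historical`` rate; monotone items are pushed below their
    predecessor at plateau positions with the ``monotone`` rate; free items
    are never touched.  Totals are recomputed from the corrupted items.
    """
    schema = schema or ItemSchema.default()
    for k, v in corruption_rates.items():
        if not 0 <= v <= 1:
            raise ValueError(f"corruption rate for {k!r} must be in [0,1]")
    rng = np.random.default_rng(seed)
    out = visits.sort_values(["participant_id", "visit_age_years"]).reset_index(drop=True)
    out = out.copy()

    p_hist = corruption_rates.get("historical", 0.0)
    p_mono = corruption_rates.get("monotone", 0.0)
    for _, idx in out.groupby("participant_id", sort=False).groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            continue
        for it in schema.by_class("historical"):
            col = it.item_id
            vals = out.loc[idx, col].to_numpy(copy=True)
            for t in range(1, len(idx)):
                if rng.random() < p_hist:
                    choices = [v for v in range(it.max_score + 1) if v != vals[t]]
                    vals[t] = rng.choice(choices)
            out.loc[idx, col] = vals
        for it in schema.by_class("monotone"):
            col = it.item_id
            vals = out.loc[idx, col].to_numpy(copy=True)
            clean = vals.copy()
            for t in range(1, len(idx)):
                # only plateau positions with positive level can show a
                # spurious decrease that the revision rule can undo exactly
                if clean[t] == clean[t - 1] and clean[t] > 0 and rng.random() < p_mono:
                    vals[t] = int(rng.integers(0, clean[t]))
            out.loc[idx, col] = vals
    out["css_total"] = out[schema.item_ids].sum(axis=1).astype(int)
    return out
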