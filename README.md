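# rettnorm

Age- and genotype-normalized clinical severity scores for Rett syndrome.

Rett syndrome (RTT) is an X-linked neurodevelopmental disorder caused mainly
by loss-of-function variants in *MECP2*. Its standard severity metric, the
Clinical Severity Score (CSS; sum of 13 Likert-rated clinical items, range
0–58), is confounded for between-person comparisons by two strong effects:
severity rises with age following a logarithmic growth pattern, and *MECP2*
genotype groups differ systematically in group-level severity. `rettnorm`
removes both, producing a normative CSS (**nCSS**) on [0, 1] that lets
severity be compared across ages and genotypes — for example to test whether
skewed X-chromosome inactivation (XCI) modulates severity.

The pipeline, for users of longitudinal natural-history visit tables:

1. **Cleaning** — algorithmic revision of logically inconsistent item series:
   fixed-historical items are pinned to their earliest reported value;
   monotone items (can only worsen or plateau) are revised by a running
   maximum; totals are recomputed from items.
2. **Growth model** — a conditional growth mixed-effects model on classic-RTT
   training data. With log-transformed age decomposed into a between-person
   component M<sub>j</sub> (centered subject-mean log-age) and a within-person
   component Dur<sub>ij</sub>:

   Y<sub>ij</sub> = β<sub>0j</sub> + β<sub>1j</sub> t<sub>ij</sub> + R<sub>ij</sub>,  t<sub>ij</sub> = M<sub>j</sub> + M<sub>j</sub>·Dur<sub>ij</sub> + Dur<sub>ij</sub>

   β<sub>0j</sub> = γ<sub>00</sub> + γ<sub>01</sub>·genotype<sub>j</sub> + U<sub>0j</sub>,  β<sub>1j</sub> = γ<sub>10</sub> + γ<sub>11</sub>·genotype<sub>j</sub> + U<sub>1j</sub>

   with subject random intercept and duration slope (U<sub>0j</sub>, U<sub>1j</sub>) ~ N(0, D),
   estimated by REML.
3. **Individual prediction** — empirical-Bayes (BLUP) posterior of each
   participant's random effects given their observed visits, a predicted
   trajectory on the 2–25 y grid in 0.1-y bins (231 points), and its grid
   mean, the age-normalized **mean predicted CSS**.
4. **Normalization** — within-genotype empirical cumulative distributions of
   classic-training mean predicted CSS; a participant's nCSS is their
   percentile/100 inside their own genotype's distribution.
5. **Validation & XCI analysis** — pseudo leave-one-out cross-validation with
   per-individual RMSE; Pearson correlations of paternal-XCI percentage
   (pXCI) with raw CSS and nCSS overall and within mild/severe variant
   groups; and a sequential sum-of-squares partition of
   `nCSS ~ SevGroup + pXCI + SevGroup:pXCI`.

A synthetic-cohort generator with known ground truth (genotype frequencies,
visit process, Likert item decomposition, injected pXCI × severity effect,
record corruption) drives all tests.

## Worked example

```python
import numpy as np
import rettnorm as rn
from rettnorm.schema import SEVERITY_MAP

cfg = rn.SimulationConfig(n_participants=300, seed=11, xci_informative_fraction=1.0)
visits, xci, truth = rn.generate_cohort(cfg)

dirty = rn.corrupt_records(visits, cfg.corruption_rates, seed=12)
revised, report = rn.clean_cohort(dirty)
print("cleaning: revised", report.total_revised, "item cells")

model = rn.CSSGrowthModel().fit(revised)          # classic subjects only
print(f"growth model: {model.n_subjects_} training subjects, "
      f"residual SD {model.scale_**0.5:.2f} CSS points")
print("T158M population CSS at ages 3/10/20:",
      np.round(model.population_trajectory("T158M", [3, 10, 20]), 1))

w = revised[(revised.visit_age_years >= 2) & (revised.visit_age_years <= 25)]
preds = rn.predict_cohort(model, w)               # everyone, incl. atypical
scorer = rn.NormativeScorer().fit(preds[preds.diagnosis == "classic"])
preds["ncss"] = scorer.transform(preds)

res = rn.grouped_correlations(preds.rename(columns={"ncss": "score"}), xci, "score")
print(f"severe-group pXCI/nCSS: r={res['severe'].r:.3f}, p={res['severe'].p:.4f}")
merged = preds.merge(xci, on="participant_id")
merged["sev_group"] = [SEVERITY_MAP[g] for g in merged.genotype]
_, part = rn.fit_xci_model(merged)
print(f"interaction variance share: {part.fractions['SevGroup:pXCI']*100:.2f}%")
```

Output:

```
cleaning: revised 312 item cells
growth model: 258 training subjects, residual SD 2.03 CSS points
T158M population CSS at ages 3/10/20: [21.1 24.1 25.8]
severe-group pXCI/nCSS: r=-0.268, p=0.0003
interaction variance share: 2.45%
```

The residual SD of ~2 CSS points says individual trajectories are predicted
to within ±2 points on the 58-point scale; the negative severe-group
correlation recovers the injected effect (higher paternal-X silencing of the
variant allele → milder disease), which is absent in the mild group; the
variance share quantifies how much of the between-person nCSS variation that
severity-dependent XCI effect explains.

The same pipeline is available from the shell:

```bash
rettnorm simulate --seed 11 --n 300 --out runs/sim/
rettnorm run --visits runs/sim/visits.csv --xci runs/sim/xci.csv --out runs/full/
```

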