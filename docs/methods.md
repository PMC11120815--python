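# Methods

## The severity scale and its confounders

The Clinical Severity Score (CSS) sums 13 clinician-rated Likert items
(0–4 or 0–5 each; totals 0–58, higher = more severe). Two structural effects
dominate raw between-person comparisons in Rett syndrome: severity increases
with age — rapidly from early childhood, then decelerating toward a plateau,
well captured on a log-age scale — and *MECP2* variant groups differ in
group-level severity (R133C, R294X, R306C and C-terminal truncations mild;
R106W, T158M, R168X, R255X, R270X, early truncations and large deletions
severe). The package's purpose is a score with both effects removed.

## Longitudinal cleaning

Items carry one of three longitudinal classes. *Historical* items record a
fixed fact; every observation is revised to the earliest reported value.
*Monotone* items can only worsen or plateau; revision is a single
left-to-right pass replacing any value below its revised predecessor with
that predecessor (a running maximum). This is the unique idempotent reading
of "replace with the nearest previous observation" when consecutive
decreases occur. *Free* items are never revised. Revised totals are exact
item sums; a visit with a missing item yields no total (no imputation), and
a participant is dropped only if no visit yields a total.

The published score does not enumerate which items belong to which class, so
the 13-item schema is configuration. The default (2 historical items capped
at 4, 3 monotone at 5, 8 free summing to 35) is arbitrary but immaterial:
every rule depends only on the class, never the identity.

## Growth model

Visit age (restricted to 2–25 years) is log-transformed and decomposed into
a between-person component `mean_lnage_center` (subject mean log-age minus
the training-cohort constant c) and a within-person component `duration`
(log-age minus subject mean; zero-mean within subject). The fixed design is

    CSS ~ genotype * (mean_lnage_center + duration + mean_lnage_center:duration)

with treatment coding (reference = largest training group by default; the
fitted values are invariant to this choice), a subject random intercept and
random `duration` slope with unstructured 2×2 covariance D, and
homoscedastic residual variance σ². The three time terms expand the compact
`β1·t` with `t = M + M:Dur + Dur`; genotype interacts with each, giving
every variant group its own baseline and trajectory. Only the within-person
component carries a random slope — between-person age effects are
population-level by construction of the decomposition.

Estimation is REML via statsmodels `MixedLM` (ML behind the `reml=False`
flag), optimizer sequence L-BFGS → BFGS → Powell; the Powell fallback
rescues near-boundary variance surfaces where gradient methods stall.
Non-convergence raises. Training is restricted to classic-diagnosis
participants; one-subject genotype groups are retained with a reduced
design (their dummy × between-person columns are exactly collinear with the
dummy, so they keep at most a `duration` interaction), which keeps the
design full rank and the fit coding-invariant.

## Individual prediction and the age-normalized score

For a participant with visits y, fixed design X, and Z = [1, duration], the
random-effect posterior is the exact Gaussian conditional

    mean = D Zᵀ V⁻¹ (y − Xγ̂),  cov = D − D Zᵀ V⁻¹ Z D,  V = Z D Zᵀ + σ² I

(the posterior mean is the BLUP; a seed-controlled Monte-Carlo sampling mode
estimates the same quantity). A participant with no visits receives the
prior. Trajectories are evaluated on the inclusive 2.0–25.0 grid in 0.1-y
steps (231 points), holding the participant's own between-person component
fixed — re-centering on each grid age would conflate between- and
within-person effects. The arithmetic grid mean (**mean predicted CSS**)
equals, up to the bin width, the area under the predicted curve divided by
the age span; it summarizes severity with age integrated out. Predictions
are not clamped to [0, 58]: the model is linear and the score bounds are a
display concern.

## Normative score

Per genotype group, the empirical cumulative distribution of mean predicted
CSS is built from classic training participants (raw multiset, no
smoothing). nCSS = (number of training values ≤ value) / n — the
right-continuous ECDF convention, so the training minimum maps to 1/n, not
0, and out-of-support values from non-training (e.g. atypical) participants
map to 0 or 1 rather than erroring. Scored on its own training values each
group's nCSS multiset is exactly {1/n, …, 1}: discrete-uniform, which is
what erases the genotype–phenotype gradient and is what the calibration
tests check.

## Cross-validation

Each participant is scored against a model trained on classic participants
excluding themself (atypical participants always use the full classic
model, so their result is split-independent). The held-out model conditions
on the participant's full observation set and predicts at the same observed
ages; RMSE is per individual. A stricter forward-chaining mode (condition
on the first k visits, predict visit k+1) is available behind a flag; the
default mirrors the single-RMSE-per-subject summary. Quartiles in summaries
use linear interpolation (type 7).

## XCI analysis

pXCI is the percentage of cells silencing the paternal X — in most RTT the
variant-bearing allele — measured in blood; it arrives as input data.
Correlations of pXCI with severity are Pearson r with two-sided t-test p
and Fisher-z 95% CI, computed for all informative participants and within
the mild and severe variant groups. In raw-CSS mode the severity value is
the revised CSS at the visit nearest the informative cohort's mean visit
age (ties to the earlier visit). The simplified model
`nCSS ~ SevGroup + pXCI + SevGroup:pXCI` is ordinary least squares with
sequential (Type-I) sums of squares — main effects entered before the
interaction, the canonical ordering both patsy and R's `terms()` enforce —
each term's SS divided by total SS. pXCI enters uncentered in percent; the
fractions are invariant to its linear rescaling.

## Synthetic cohort generator

Defaults emulate the modelled study cohort: 1178 participants at the
published genotype-group frequencies, ~15% atypical, visit counts
1 + Poisson(4) capped at 17 (mean ≈ 5), first visit uniform on 2–12 y, gaps
0.5 + Exp(0.7) y truncated at 25 y, genotype intercepts ~15–17 (mild) and
~23–25 (severe) CSS points with log-age slopes 3.6–5.2, random-effect
covariance [[16, 2], [2, 1]], residual SD 2 CSS points (matching the
reported ~2-point prediction error), and an informative-pXCI fraction of
198/1178. pXCI is latent-uniform on [0, 100] for everyone; severe-variant
participants receive an intercept shift `xci_effect × (pXCI − 50)` with
default −0.04 CSS points per percentage point, calibrated once so the
severe-group pXCI/nCSS correlation is ≈ −0.2. Totals are the model mean
plus Gaussian noise, rounded and clipped to [0, 58], then decomposed onto
items by multivariate-hypergeometric allocation subject to the class
constraints (historical constant, monotone non-decreasing); in the rare
case a total falls below the floor set by those constraints the total is
redefined as the item sum, keeping sums exact.

The corruption operator perturbs historical items away from their first
value at post-first visits and pushes monotone items below their
predecessor at plateau positions only — the one corruption class the
running-maximum rule can invert exactly, which makes the corrupt→clean
round trip a sharp (zero-mismatch) test. A corrupted genuine increase is
provably unrecoverable by any order-preserving rule and is therefore not
generated.

What the generator does not emulate: real visit-gap and dropout processes
(unpublished), per-genotype atypical fractions, item-level clinical
correlation structure, measurement error in pXCI, and any age dependence of
the XCI effect. Passing tests therefore demonstrate the statistical
machinery is correct under the stated generative model, not that the model
is true of registry data.

## Validation studies and their sizes

- **Parameter recovery**: 30 cohorts of 300 subjects, two genotype groups
  (one severe, one mild — every coefficient block of the model, with
  well-estimated Monte-Carlo error), ~9 visits/subject over wide age spans
  and slope variance 4 so all variance components are identified (under
  clinic-like tight visit spacing the duration-slope variance is weakly
  identified; lme4 reproduces the same estimates, confirming this is a
  design property, not an estimator defect). Checks: each fixed effect
  within 3 Monte-Carlo SEs of truth; variance components within 15%
  relative error of the mean estimate.
- **BLUP exactness**: 25 random 3-visit toys against explicit
  joint-covariance Gaussian conditioning, tolerance 1e-8 (observed ~1e-15).
- **nCSS calibration**: equal-frequency cohort sized for ≥50 classic
  training subjects per group; KS test of each group's training nCSS
  against U(0,1) at α = 0.001; severity-group sequential-SS fraction < 1%
  on null training nCSS.
- **Cleaning round trip**: 150 subjects, 30% corruption rates, zero
  unrecovered cells.
- **Interaction recovery**: 20 cohorts of 600 subjects with xci_effect
  −0.05; the estimated interaction fraction is compared to the fraction
  obtained by applying the identical percentile-and-partition pipeline to
  the generator's latent (noise-free) grid-mean severities, within 30%
  relative error (observed 2–5%).
- **Null controls**: 5 cohorts of 1000 subjects with xci_effect 0;
  severe-group correlations average to ~0 and the interaction fraction
  stays below 1%.
- **Cross-validation**: 60-subject cohort, 4 genotype groups; median
  per-individual RMSE lands between 0.5 and 1.5 residual SDs.

All studies derive their seeds from a single base seed; the full test suite
and the acceptance script each run in about two minutes on one CPU.

## Numerical choices and limitations

Convergence: statsmodels optimizer defaults with maxiter 200 and the
three-stage method sequence; REML surfaces at variance boundaries are the
main failure mode and are rescued by Powell. Ages must be strictly
positive; visits outside 2–25 y are dropped before fitting but retained in
tables. The ECDF tie convention (≤) and the earlier-visit tie-break in
nearest-visit selection are fixed, documented choices. Known limitations:
no heteroscedastic or autocorrelated residual structures, no parametric
percentile smoothing (small training groups make the nCSS grid coarse:
steps of 1/n), no measurement-error model for pXCI, and leave-one-out
cross-validation refits the model per held-out classic subject, which is
the pipeline's only expensive mode (linear in cohort size × fit time).
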