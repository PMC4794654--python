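# Methods

## Analysis model

### Change traits and screening

The efficacy outcomes are change traits Δ = (week-48 value) − (week-0
value) for fasting plasma glucose (FPG, mmol/L), 2-hour post-load glucose
(2hPG, mmol/L) and HbA1c (%); negative values mean improvement. Subjects
without a week-48 measurement (withdrawers, losses to follow-up) have no Δ
and enter only the survival analysis; no last-observation carry-forward is
applied anywhere.

Screening fits, per SNP and trait, the additive model

    Δ ~ β·g + γ₁·age + γ₂·sex + γ₃·BMI₀ + intercept

by ordinary least squares, where g ∈ {0,1,2} counts copies of one allele.
Analyses are complete-case; two-sided p-values come from the t
distribution with residual degrees of freedom (the exact OLS reference;
software using asymptotic Wald normal approximations may differ in far
decimals). A constant allele count after missingness yields an explicit
"inestimable" flag, never a silent zero.

**Effect-allele orientation.** Each SNP gets exactly one effect allele:
the trait with the smallest screening p-value among estimable fits decides
the orientation, and if its β is positive the coding is flipped
(g → 2 − g), which negates all three traits' β while leaving SE and p
unchanged. A β of exactly zero keeps the incoming orientation and is
flagged ambiguous. The smallest-p tie-break across traits is a design
choice (published panels list one effect allele per SNP without stating
the deciding trait); ties on p fall back to the canonical trait order
(ΔFPG, Δ2hPG, ΔHbA1c).

**Selection.** A SNP enters the score when ANY of: β(ΔFPG) ≤ −0.5 mmol/L,
β(Δ2hPG) ≤ −1 mmol/L, β(ΔHbA1c) ≤ −0.5 %, or any trait's p < 0.2. The β
boundary qualifies (≤); the p boundary does not (<); a missing p never
qualifies. The screen is deliberately liberal and uncorrected for multiple
testing — it pre-selects a panel for a joint score rather than declaring
discoveries. Screening and selection run per treatment arm; the two drugs
get independent panels.

### Genetic score and tertiles

The score is the unweighted sum of effect-allele counts over the selected
panel — an integer in [0, 2n] for n SNPs. No β-weighting is used (a
weighted GRS is deliberately out of scope). Subjects missing any panel
genotype are excluded by default; optional per-SNP mean imputation exists
for robustness studies.

Tertile cuts use a cumulative-count rule on the integer score
distribution: s₁ is the smallest score whose cumulative count reaches n/3,
s₂ the smallest score above s₁ reaching 2n/3; labels are T1: score ≤ s₁,
T2: s₁ < score ≤ s₂, T3: score > s₂. Tied scores therefore never split
across tertiles, at the cost of group-size imbalance when ties are heavy
(each group is bounded by n/3 plus the largest tie block; with fewer than
three distinct scores, or ties leaving no room for a non-empty top group,
tertiles are reported as undefined). Tertiles are computed on all scored
subjects, including later withdrawers.

### Score-efficacy association

The primary model regresses each Δ-trait on the tertile index coded 1/2/3
as a single linear trend ("additive across tertiles"); using the raw
integer score as a continuous predictor is the reported sensitivity
analysis, and indicator-coded T2/T3-vs-T1 contrasts are emitted as a
secondary table. Three covariate sets are fitted: base (age, sex, baseline
BMI), base + the week-0 value of the same trait, and base + prescribed
dose. "Dose" defaults to the final titrated dose in mg within the arm,
with a visit-averaged option in configuration, since protocols rarely pin
down which summary is meant. Two-tailed α = 0.05 flags significance in
reports. Per-tertile descriptive output is mean ± SEM (SD/√n) with group
sizes; singleton groups carry an undefined SEM and empty groups are
flagged rather than dropped.

### Time-to-target survival

Two attainment definitions per trait: fixed thresholds (FPG < 7.0 mmol/L,
2hPG < 11.1 mmol/L, HbA1c < 7.0 %) and a relative criterion (decrease
strictly greater than 20% of baseline). The event time is the first
post-baseline visit week at which the criterion holds; event times are
discrete visit weeks. Conventions:

- Subjects already below a fixed threshold at week 0 cannot attain and
  are excluded from that criterion's analysis with a warning (a newly
  diagnosed cohort makes this rare).
- Withdrawers for inadequate glycemic control are non-responders: they
  demonstrably did not attain, so they are carried event-free to week 48
  by default; a censor-at-withdrawal switch is provided because the
  convention is a modelling choice.
- Losses to follow-up are censored at their last observed visit.

Groups are the score tertiles. The overall k-group Mantel-Cox log-rank
test is accompanied by all pairwise two-group tests, reported unadjusted
(the highest-vs-lowest contrast is the comparison of interest; no
multiplicity correction is applied). The Cox proportional-hazards model
enters the tertile as a 1/2/3 trend plus age, sex and baseline BMI, with
Efron's tie handling (many subjects share visit-week event times).
Kaplan-Meier cumulative attainment (1 − survival) per group at each visit
week, with numbers at risk, supports attainment-curve output. Interval
censoring likelihoods, time-varying covariates and competing risks are out
of scope.

## Synthetic cohort simulator

The simulator emulates a 48-week randomized two-arm monotherapy trial in
newly diagnosed T2DM, so downstream stages can be tested against known
truth. What it generates:

- **Genotypes**: i.i.d. Hardy-Weinberg draws per SNP at configured ALT
  frequencies — QC passes by construction, and the null exclusion rate of
  the HWE filter is checkable against its nominal level.
- **Subjects**: age ~ N(52, 10²) years, BMI ~ N(25.5, 3²) kg/m²,
  P(male) = 0.5 with sex coded female = 0 / male = 1, randomized to arms
  (default repaglinide, dose steps 0.5/1/1.5/2 mg; rosiglitazone, 4/8 mg).
  Baselines: FPG ~ N(9.0, 1.5²), 2hPG ~ N(14.5, 3²) mmol/L,
  HbA1c ~ N(8.0, 0.9²) %. These are plausible values for a newly diagnosed
  cohort and fully configurable; they are not calibrated to any specific
  study (no such distributional parameters are published for the design
  emulated).
- **Endpoints**: Δ-trait = arm-level mean response (defaults −2.0, −3.5
  mmol/L, −1.6 %) + Σⱼ effectⱼ·gⱼ + covariate terms (age/BMI centred at
  their means, raw sex; zero by default) + N(0, σ²) with σ = 1.2, 2.5, 0.8
  per trait. The week-48 visit records the endpoint exactly, so change
  traits recover the generative model without attenuation.
- **Trajectories**: intermediate visits approach the endpoint
  exponentially with a 6-week time constant plus small visit noise (0.4,
  0.8, 0.2 per trait). An exponential default (rather than a straight
  line to week 48) reflects the fast early response under active
  titration; under a linear decline, the protocol-withdrawal rule below
  would expel nearly every subject whose baseline HbA1c exceeds ~8.2%,
  which contradicts the trial design being emulated. `trajectory="linear"`
  remains available.
- **Titration**: dose steps up one level after any visit (baseline
  included) at which FPG ≥ 7 or 2hPG ≥ 11 mmol/L, until the arm's maximum.
- **Withdrawal**: HbA1c ≥ 8 % (or FPG > 13 / 2hPG > 18 mmol/L) at two
  consecutive post-baseline visits truncates follow-up with status
  `withdrawn_control`. Week 0 is excluded from the rule (it is
  pre-treatment), and the rule is not applied at the final visit (the
  study is over; such subjects are completers). With the default
  parameters roughly 10% of subjects withdraw — the same order as, though
  somewhat above, typical monotherapy trials of this design.
- **Loss to follow-up**: constant per-visit probability (default 0.015),
  truncating at the last attended visit with status `lost`. Hepatic or
  other adverse-event withdrawals are folded into this stream.

A single integer seed drives deterministic per-stage substreams
(`numpy` `SeedSequence.spawn`), so cohorts are bit-reproducible. The
recorded ground truth (per-SNP effects, per-subject noiseless Δ means, the
oriented true score) supports the recovery experiments in
`pgxscore.validation`.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium between SNPs
(genotypes are independent), pharmacokinetics and within-day glucose
dynamics, adherence and lifestyle confounding, measurement-device error
structure, informative (outcome-dependent) loss to follow-up, or
population stratification. Parameter-recovery results certify the
statistical machinery, not the biology.

## Numerical choices

- OLS via `statsmodels`; p-values from the t distribution with residual
  df. The normal-equations oracle in the tests agrees to 1e-8.
- HWE χ²: Pearson statistic on genotype counts with 1 df, no continuity
  correction; monomorphic SNPs get χ² = 0, p = 1 and fail QC by the
  monomorphism rule. Missing genotypes are dropped from counts; call rate
  < 90% is flagged but not auto-excluded.
- Log-rank and Cox via `lifelines`. Cox Newton tolerances are tightened
  (`precision 1e-13`, relative-ll 1e-14) because the library's default
  stopping rules can leave the coefficient ~1e-6 short of the optimum on
  small, flat-likelihood datasets; zero-variance covariates are dropped
  with a note; non-convergence raises rather than returning estimates.
- Zero events in a log-rank comparison return χ² = 0, p = 1 with a
  warning instead of NaN.
- Tertile ties: the cumulative-count rule above is definitional;
  deterministic tie-breaks throughout (canonical trait order in
  orientation, first-occurrence on equal p).
- Pipeline determinism: all tables are written with a fixed float format
  (`%.10g`), so identical inputs and configuration reproduce output files
  byte for byte.

## Experiment sizes

The shipped Monte-Carlo experiments use 500 replicates of n = 200 cohorts
for tertile-trend recovery/calibration, 200 replicates for log-rank power
and 300 for Cox type-I error — sizes at which the binomial error of the
checked rates is well inside the asserted bands while the whole suite
stays quick to run.

## Known limitations

- The selection screen's p < 0.2 arm makes selected panels cohort-noisy
  by design; panel membership is not a stable biological claim.
- Tertile cut points are cohort-specific; `GeneticScorer.transform`
  deliberately freezes training-cohort cuts when labelling new subjects.
- The non-responder convention (event-free at week 48) slightly penalises
  high-withdrawal groups relative to censoring; both conventions are
  implemented because the choice is not neutral.
- With fewer than ~60 subjects per arm the Cox trend model can sit near
  monotone likelihood for rare-event criteria; such fits are flagged, and
  the pipeline records the failure note instead of a coefficient.
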