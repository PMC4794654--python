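# pgxscore

Joint genetic-score analysis of oral anti-diabetic drug efficacy in type 2
diabetes (T2DM) pharmacogenomics.

Single-SNP pharmacogenomic analyses of insulin secretagogues (e.g.
repaglinide) and sensitizers (e.g. rosiglitazone) are underpowered because
each T2DM-susceptibility locus contributes little to drug response.
`pgxscore` implements the joint-effect alternative as a tested, reusable
pipeline for 48-week two-arm response trials:

1. **Genotype QC** — per-cohort Hardy-Weinberg equilibrium tests (Pearson
   χ², 1 df) excluding SNPs with *P* < 0.01, plus monomorphism filtering.
2. **Additive screening** — for each SNP and each glycemic change trait
   (ΔFPG, Δ2hPG in mmol/L, ΔHbA1c in %, all week-48 minus baseline), OLS of
   Δ on the 0/1/2 allele count adjusted for age, sex and baseline BMI; each
   SNP is oriented to its *effect allele* (the allele with negative β,
   i.e. greater reduction).
3. **Selection** — a SNP enters the score when any trait shows
   β(ΔFPG) ≤ −0.5 mmol/L, β(Δ2hPG) ≤ −1 mmol/L, β(ΔHbA1c) ≤ −0.5%, or any
   screening *P* < 0.2.
4. **Genetic score** — the unweighted sum of effect-allele counts,
   `score = SNP₁ + SNP₂ + … + SNPₙ ∈ [0, 2n]`, stratified into tertiles
   T1/T2/T3 by a cumulative-count rule that never splits tied scores.
5. **Association** — OLS of each Δ-trait on the tertile trend (1/2/3) or
   on the raw score, under three covariate sets (age+sex+BMI; plus the
   baseline trait; plus the prescribed dose).
6. **Time-to-target survival** — per-subject time to glycemic-target
   attainment under two definitions (fixed thresholds FPG < 7.0,
   2hPG < 11.1 mmol/L, HbA1c < 7.0%; or a > 20% drop from baseline), with
   protocol withdrawers for inadequate control carried as event-free
   non-responders; Mantel-Cox log-rank (overall and pairwise) and Cox
   proportional-hazards (tertile trend, Efron ties) comparisons.

Because patient-level trial data of this design are generally not public,
the package ships a first-class **synthetic cohort simulator**
(`pgxscore.simulate`) that emulates the trial — HWE genotypes at configured
frequencies, additive per-allele effects on the Δ-traits, the week
0/2/4/12/24/32/48 visit schedule, stepwise dose titration, withdrawal for
inadequate glycemic control and loss to follow-up — with the generating
truth recorded, so every stage is verifiable by parameter recovery.

The core stages are scikit-learn-style estimators
(`HardyWeinbergFilter`, `AdditiveScreener`, `GeneticScorer`,
`ScoreAssociation`, `AttainmentAnalysis`) with plain-function wrappers, and
a thin CLI (`pgx-jointscore simulate` / `pgx-jointscore run`) orchestrates
whole runs from YAML configs.

## Worked example

Simulate a two-arm study (46 SNPs, 20 causal) and analyse the repaglinide
arm:

```python
from pgxscore import (default_study_config, simulate_cohort, qc_filter,
                      compute_deltas, AdditiveScreener, GeneticScorer,
                      fit_association, tertile_index, AttainmentAnalysis)
from pgxscore.io import GenotypeMatrix
from pgxscore.screening import subject_covariates

config = default_study_config(seed=1, n_per_arm=100)
genotypes, cohort, truth = simulate_cohort(config)

arm = cohort[cohort["arm"] == "repaglinide"]
arm_geno = GenotypeMatrix(dosage=genotypes.dosage.loc[arm["subject_id"].unique()],
                          snp_meta=genotypes.snp_meta)
filtered, qc_report = qc_filter(arm_geno)

deltas, covs = compute_deltas(arm), subject_covariates(arm)
screener = AdditiveScreener().fit(filtered, deltas, covs)
scorer = GeneticScorer(panel=screener.panel_).fit(filtered)
est = fit_association(deltas["d_fpg"],
                      tertile_index(scorer.tertiles_).astype(float), covs)
surv = AttainmentAnalysis(trait="hba1c", criterion="relative20").fit(
    arm, scorer.tertiles_, covs)
```

which prints, via the session's `print` statements:

```
SNPs passing QC: 46/46
SNPs selected for the score: 24
tertile cut points: T1 <= 15 < T2 <= 18 < T3
dFPG ~ tertile trend: beta = -0.66 +/- 0.19 mmol/L, p = 0.0010
HbA1c >20%-drop attainment: log-rank chi2 = 23.13 (df 2), p = 0.0000; Cox HR per tertile = 2.02, p = 0.0000
```

Read: all 46 SNPs are consistent with Hardy-Weinberg equilibrium in this
draw; 24 pass the liberal selection screen; the cohort splits into score
tertiles at ≤15 / 16–18 / ≥19 effect alleles; each tertile step is worth an
extra 0.66 mmol/L fasting-glucose reduction (the planted composite effect
is of this size); and high-score subjects reach the >20% HbA1c-reduction
target about twice as fast per tertile step.

The same analysis from the shell:

```sh
pgx-jointscore simulate --config sim.yaml --out fixture/ --seed 1
pgx-jointscore run --config run.yaml     # points at fixture/, writes out/
```

## Layout

- `src/pgxscore/` — `io`, `qc`, `screening`, `score`, `association`,
  `survival`, `simulate`, `validation`, `pipeline`, `cli`, `datasets`.
- `docs/methods.md` — models, assumptions, defaults and limitations.
- `tests/` — unit, property and whole-method suites with independent
  oracles (normal equations, explicit Mantel-Cox sums, product-limit and
  partial-likelihood computations).
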