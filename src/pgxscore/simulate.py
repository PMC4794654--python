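"""Synthetic two-arm oral anti-diabetic trial cohorts with known genetics.

The simulator emulates a 48-week randomized monotherapy trial in newly
diagnosed type 2 diabetes: subjects are randomized to one of two drug arms,
visited at weeks 0, 2, 4, 12, 24, 32 and 48, titrated upward when fasting
(>= 7 mmol/L) or post-load (>= 11 mmol/L) glucose remains high, withdrawn
when glycemia stays inadequately controlled (HbA1c >= 8% at two consecutive
on-treatment visits; FPG > 13 or 2h glucose > 18 mmol/L analogously), and
lost to follow-up at a constant per-visit hazard.

Genotypes are drawn in Hardy-Weinberg proportions at configured minor
allele frequencies, so QC passes by construction. The week-48 change of
each glycemic trait is the sum of an arm-level mean response, additive
per-allele SNP effects, optional covariate terms and Gaussian noise;
intermediate visits approach the week-48 endpoint along a configurable
trajectory (exponential by default) with per-visit measurement noise.
Everything is driven by a single integer seed through deterministic
per-stage substreams, so runs are exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .io import (
    GenotypeMatrix,
    write_dosage,
    write_phenotypes,
    write_vcf,
)

TRAIT_COLUMNS = ("fpg", "pg2h", "hba1c")
DELTA_NAMES = {"fpg": "d_fpg", "pg2h": "d_2hpg", "hba1c": "d_hba1c"}


@dataclass(frozen=True)
class SNPSpec:
    """One simulated biallelic SNP; ``maf`` is the ALT allele frequency."""

    snp_id: str
    chrom: str
    ref: str
    alt: str
    maf: float


@dataclass(frozen=True)
class ArmPlan:
    """Treatment arm with its ordered dose-titration steps (mg)."""

    name: str
    dose_steps: tuple[float, ...]


DEFAULT_ARMS = (
    ArmPlan("repaglinide", (0.5, 1.0, 1.5, 2.0)),
    ArmPlan("rosiglitazone", (4.0, 8.0)),
)


def _trait_map(**values) -> dict:
    return dict(values)


@dataclass
class SimulationConfig:
    """Full description of one simulated study.

    Baseline distributions default to plausible values for a newly diagnosed
    T2DM cohort (they are not calibrated to any particular study, which
    printed none): FPG ~ N(9.0, 1.5) mmol/L, 2h glucose ~ N(14.5, 3.0)
    mmol/L, HbA1c ~ N(8.0, 0.9)%, age ~ N(52, 10) years, BMI ~ N(25.5, 3.0)
    kg/m2, half the cohort male (sex coded female = 0, male = 1).
    ``effect_sizes`` maps each trait to per-SNP additive effects per ALT
    allele on the week-48 change (negative = greater reduction).
    Covariate effects apply to age and BMI centred at their configured
    means and to raw sex.
    """

    snp_specs: Sequence[SNPSpec]
    effect_sizes: Mapping[str, Sequence[float]]
    n_per_arm: int | Sequence[int] = 104
    arms: Sequence[ArmPlan] = DEFAULT_ARMS
    baseline_means: Mapping[str, float] = field(
        default_factory=lambda: _trait_map(fpg=9.0, pg2h=14.5, hba1c=8.0))
    baseline_sds: Mapping[str, float] = field(
        default_factory=lambda: _trait_map(fpg=1.5, pg2h=3.0, hba1c=0.9))
    delta_means: Mapping[str, float] = field(
        default_factory=lambda: _trait_map(fpg=-2.0, pg2h=-3.5, hba1c=-1.6))
    noise_sds: Mapping[str, float] = field(
        default_factory=lambda: _trait_map(fpg=1.2, pg2h=2.5, hba1c=0.8))
    visit_noise_sds: Mapping[str, float] = field(
        default_factory=lambda: _trait_map(fpg=0.4, pg2h=0.8, hba1c=0.2))
    covariate_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: _trait_map(
            fpg=(0.0, 0.0, 0.0), pg2h=(0.0, 0.0, 0.0), hba1c=(0.0, 0.0, 0.0)))
    age_mean: float = 52.0
    age_sd: float = 10.0
    male_fraction: float = 0.5
    bmi_mean: float = 25.5
    bmi_sd: float = 3.0
    visit_weeks: tuple[int, ...] = (0, 2, 4, 12, 24, 32, 48)
    dropout_rate: float = 0.015
    protocol_withdrawal: bool = True
    withdrawal_hba1c: float = 8.0
    withdrawal_fpg: float = 13.0
    withdrawal_pg2h: float = 18.0
    uptitrate_fpg: float = 7.0
    uptitrate_pg2h: float = 11.0
    trajectory: str = "exponential"
    response_time_constant: float = 6.0  # weeks
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def arm_counts(self) -> list[int]:
        if isinstance(self.n_per_arm, (int, np.integer)):
            return [int(self.n_per_arm)] * len(self.arms)
        counts = [int(c) for c in self.n_per_arm]
        if len(counts) != len(self.arms):
            raise ConfigurationError("n_per_arm sequence length must match arms")
        return counts

    def validate(self) -> None:
        if not self.snp_specs:
            raise ConfigurationError("at least one SNP spec is required")
        seen = set()
        for spec in self.snp_specs:
            if not 0.0 <= spec.maf <= 1.0:
                raise ConfigurationError(
                    f"SNP {spec.snp_id}: allele frequency {spec.maf} outside [0, 1]")
            if spec.snp_id in seen:
                raise ConfigurationError(f"duplicate SNP id {spec.snp_id}")
            seen.add(spec.snp_id)
        m = len(self.snp_specs)
        for trait in TRAIT_COLUMNS:
            effects = self.effect_sizes.get(trait)
            if effects is None or len(effects) != m:
                raise ConfigurationError(
                    f"effect_sizes[{trait!r}] must list one value per SNP ({m})")
        if any(count < 2 for count in self.arm_counts()):
            raise ConfigurationError("n_per_arm must be >= 2")
        weeks = self.visit_weeks
        if len(weeks) < 2 or weeks[0] != 0 or any(
                b <= a for a, b in zip(weeks, weeks[1:])):
            raise ConfigurationError(
                "visit weeks must start at 0 and increase strictly")
        for arm in self.arms:
            steps = arm.dose_steps
            if not steps or any(b <= a for a, b in zip(steps, steps[1:])):
                raise ConfigurationError(
                    f"arm {arm.name}: dose steps must be non-empty and increasing")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.trajectory not in ("exponential", "linear"):
            raise ConfigurationError("trajectory must be 'exponential' or 'linear'")

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        raw["snp_specs"] = [dataclasses.asdict(s) for s in self.snp_specs]
        raw["arms"] = [{"name": a.name, "dose_steps": list(a.dose_steps)}
                       for a in self.arms]
        raw["visit_weeks"] = list(self.visit_weeks)
        if not isinstance(self.n_per_arm, (int, np.integer)):
            raw["n_per_arm"] = list(self.n_per_arm)
        raw["covariate_effects"] = {t: list(v)
                                    for t, v in self.covariate_effects.items()}
        raw["effect_sizes"] = {t: list(v) for t, v in self.effect_sizes.items()}
        return raw

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        data = dict(raw)
        data["snp_specs"] = [SNPSpec(**s) for s in data.get("snp_specs", [])]
        if "arms" in data:
            data["arms"] = tuple(ArmPlan(a["name"], tuple(a["dose_steps"]))
                                 for a in data["arms"])
        if "visit_weeks" in data:
            data["visit_weeks"] = tuple(data["visit_weeks"])
        if "n_per_arm" in data and not isinstance(data["n_per_arm"], (int, np.integer)):
            data["n_per_arm"] = tuple(data["n_per_arm"])
        if "covariate_effects" in data:
            data["covariate_effects"] = {t: tuple(v)
                                         for t, v in data["covariate_effects"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)


@dataclass(frozen=True)
class GroundTruth:
    """Generating quantities recorded for parameter-recovery checks."""

    snp_effects: pd.DataFrame      # SNP x trait, per ALT allele
    effect_alleles: pd.Series      # allele with net negative effect per SNP
    latent_deltas: pd.DataFrame    # per-subject noiseless change means
    true_score: pd.Series          # oriented allele-count score


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(snp_specs: Sequence[SNPSpec], n_subjects: int,
                       seed, subject_ids: Sequence[str] | None = None
                       ) -> GenotypeMatrix:
    """Draw Hardy-Weinberg genotypes at the configured ALT frequencies.

    Genotypes are i.i.d. with probabilities ((1-f)^2, 2f(1-f), f^2) for
    0/1/2 ALT copies; deterministic given the seed.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    for spec in snp_specs:
        if not 0.0 <= spec.maf <= 1.0:
            raise ConfigurationError(
                f"SNP {spec.snp_id}: allele frequency {spec.maf} outside [0, 1]")
    rng = np.random.default_rng(seed)
    freqs = np.array([s.maf for s in snp_specs], dtype=float)
    hom_ref = (1.0 - freqs) ** 2
    het = 2.0 * freqs * (1.0 - freqs)
    uniforms = rng.random((n_subjects, len(snp_specs)))
    codes = (uniforms >= hom_ref).astype(float) + (uniforms >= hom_ref + het)
    if subject_ids is None:
        subject_ids = [f"S{i + 1:04d}" for i in range(n_subjects)]
    dosage = pd.DataFrame(codes, index=pd.Index(subject_ids, name="subject_id"),
                          columns=[s.snp_id for s in snp_specs])
    snp_meta = pd.DataFrame(
        {"chrom": [s.chrom for s in snp_specs],
         "ref": [s.ref for s in snp_specs],
         "alt": [s.alt for s in snp_specs],
         "counted_allele": [s.alt for s in snp_specs]},
        index=pd.Index([s.snp_id for s in snp_specs], name="snp_id"),
    )
    return GenotypeMatrix(dosage=dosage, snp_meta=snp_meta)


# ---------------------------------------------------------------------------
# cohort


def _trajectory_fraction(config: SimulationConfig, weeks: np.ndarray) -> np.ndarray:
    final = weeks[-1]
    if config.trajectory == "linear":
        return weeks / final
    tau = config.response_time_constant
    return (1.0 - np.exp(-weeks / tau)) / (1.0 - np.exp(-final / tau))


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[GenotypeMatrix, pd.DataFrame, GroundTruth]:
    """Generate genotypes, longitudinal phenotypes and the ground truth."""
    config.validate()
    counts = config.arm_counts()
    n = sum(counts)
    weeks = np.asarray(config.visit_weeks, dtype=float)
    n_visits = len(weeks)
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]

    root = np.random.SeedSequence(config.seed)
    s_geno, s_subj, s_delta, s_visit, s_drop = root.spawn(5)
    genotypes = simulate_genotypes(config.snp_specs, n, s_geno,
                                   subject_ids=subject_ids)
    rng_subj = np.random.default_rng(s_subj)
    rng_delta = np.random.default_rng(s_delta)
    rng_visit = np.random.default_rng(s_visit)
    rng_drop = np.random.default_rng(s_drop)

    arm_names = np.repeat([arm.name for arm in config.arms], counts)
    arm_names = arm_names[rng_subj.permutation(n)]
    age = rng_subj.normal(config.age_mean, config.age_sd, n)
    sex = (rng_subj.random(n) < config.male_fraction).astype(int)
    bmi = rng_subj.normal(config.bmi_mean, config.bmi_sd, n)

    dosage = genotypes.dosage.to_numpy()
    baselines, deltas, latents = {}, {}, {}
    for trait in TRAIT_COLUMNS:
        baselines[trait] = rng_subj.normal(
            config.baseline_means[trait], config.baseline_sds[trait], n)
        effects = np.asarray(config.effect_sizes[trait], dtype=float)
        a_coef, s_coef, b_coef = config.covariate_effects[trait]
        latent = (config.delta_means[trait]
                  + dosage @ effects
                  + a_coef * (age - config.age_mean)
                  + s_coef * sex
                  + b_coef * (bmi - config.bmi_mean))
        latents[trait] = latent
        deltas[trait] = latent + rng_delta.normal(0.0, config.noise_sds[trait], n)

    fraction = _trajectory_fraction(config, weeks)
    values = {}
    for trait in TRAIT_COLUMNS:
        path = baselines[trait][:, None] + deltas[trait][:, None] * fraction[None, :]
        noise = rng_visit.normal(0.0, config.visit_noise_sds[trait], (n, n_visits))
        noise[:, 0] = 0.0
        noise[:, -1] = 0.0  # endpoint carries the generative change exactly
        values[trait] = path + noise

    dropout_draws = rng_drop.random((n, n_visits))
    steps_by_arm = {arm.name: arm.dose_steps for arm in config.arms}

    records = []
    for i, subject_id in enumerate(subject_ids):
        # loss to follow-up: first post-baseline visit the subject misses
        lost_at = next((j for j in range(1, n_visits)
                        if dropout_draws[i, j] < config.dropout_rate), None)
        last_observed = (lost_at - 1) if lost_at is not None else n_visits - 1

        withdrawn_at = None
        if config.protocol_withdrawal:
            def poor(j: int) -> bool:
                return (values["hba1c"][i, j] >= config.withdrawal_hba1c
                        or values["fpg"][i, j] > config.withdrawal_fpg
                        or values["pg2h"][i, j] > config.withdrawal_pg2h)
            # two consecutive on-treatment visits, never the final one
            for j in range(2, min(last_observed, n_visits - 2) + 1):
                if poor(j - 1) and poor(j):
                    withdrawn_at = j
                    break
        if withdrawn_at is not None:
            last_observed = withdrawn_at
            status_final = "withdrawn_control"
        elif lost_at is not None:
            status_final = "lost"
        else:
            status_final = "active"

        steps = steps_by_arm[arm_names[i]]
        dose_index = 0
        for j in range(last_observed + 1):
            records.append({
                "subject_id": subject_id,
                "arm": arm_names[i],
                "age": round(float(age[i]), 1),
                "sex": int(sex[i]),
                "bmi0": round(float(bmi[i]), 2),
                "week": int(weeks[j]),
                "fpg": float(values["fpg"][i, j]),
                "pg2h": float(values["pg2h"][i, j]),
                "hba1c": float(values["hba1c"][i, j]),
                "dose_mg": float(steps[dose_index]),
                "status": status_final if j == last_observed else "active",
            })
            if (values["fpg"][i, j] >= config.uptitrate_fpg
                    or values["pg2h"][i, j] >= config.uptitrate_pg2h):
                dose_index = min(dose_index + 1, len(steps) - 1)

    cohort = pd.DataFrame(records)

    snp_ids = [s.snp_id for s in config.snp_specs]
    snp_effects = pd.DataFrame(
        {DELTA_NAMES[t]: np.asarray(config.effect_sizes[t], dtype=float)
         for t in TRAIT_COLUMNS},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    net = snp_effects.sum(axis=1)
    effect_alleles = pd.Series(
        np.where(net.to_numpy() > 0, [s.ref for s in config.snp_specs],
                 [s.alt for s in config.snp_specs]),
        index=snp_effects.index, name="effect_allele",
    )
    oriented = np.where((net.to_numpy() > 0)[None, :], 2.0 - dosage, dosage)
    truth = GroundTruth(
        snp_effects=snp_effects,
        effect_alleles=effect_alleles,
        latent_deltas=pd.DataFrame(
            {DELTA_NAMES[t]: latents[t] for t in TRAIT_COLUMNS},
            index=pd.Index(subject_ids, name="subject_id"),
        ),
        true_score=pd.Series(oriented.sum(axis=1),
                             index=pd.Index(subject_ids, name="subject_id"),
                             name="true_score"),
    )
    return genotypes, cohort, truth


# ---------------------------------------------------------------------------
# fixtures


def write_fixture(genotypes: GenotypeMatrix, cohort: pd.DataFrame, directory,
                  truth: GroundTruth | None = None) -> dict[str, Path]:
    """Write a complete on-disk fixture (both genotype dialects).

    Emits ``genotypes.vcf``, ``genotypes.dosage.tsv`` (+ sidecar),
    ``phenotypes.tsv`` and, when ground truth is supplied, a
    ``ground_truth.json`` sidecar. Round-trips losslessly through the
    readers in :mod:`pgxscore.io`.
    """
    if cohort.empty:
        raise ValueError("refusing to write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": write_vcf(genotypes, directory / "genotypes.vcf")}
    dosage_path, meta_path = write_dosage(genotypes, directory / "genotypes.dosage.tsv")
    paths["dosage"] = dosage_path
    paths["snp_meta"] = meta_path
    paths["phenotypes"] = write_phenotypes(cohort, directory / "phenotypes.tsv")
    if truth is not None:
        payload = {
            "snp_effects": truth.snp_effects.to_dict(orient="index"),
            "effect_alleles": truth.effect_alleles.to_dict(),
            "true_score": truth.true_score.to_dict(),
        }
        path = directory / "ground_truth.json"
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        paths["ground_truth"] = path
    return paths


# ---------------------------------------------------------------------------
# defaults


_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


def default_snp_specs(n_snps: int = 46) -> list[SNPSpec]:
    """A deterministic panel of synthetic SNPs with spread-out frequencies."""
    specs = []
    for i in range(n_snps):
        ref, alt = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        maf = round(0.10 + 0.40 * i / max(n_snps - 1, 1), 3)
        specs.append(SNPSpec(
            snp_id=f"snp{i + 1:03d}",
            chrom=str(i % 22 + 1),
            ref=ref, alt=alt, maf=maf,
        ))
    return specs


def default_study_config(seed: int = 0, n_per_arm=(104, 105), n_snps: int = 46,
                         n_causal: int = 20) -> SimulationConfig:
    """Paper-scale study emulation: 2 arms, 46 SNPs, 20 of them causal.

    Causal per-allele effects (-0.18 mmol/L on the FPG change, -0.35 mmol/L
    on the 2h-glucose change, -0.12% on the HbA1c change) give a composite
    score signal of realistic size for a ~100-subject arm.
    """
    specs = default_snp_specs(n_snps)
    causal = np.zeros(n_snps)
    causal[:n_causal] = 1.0
    effect_sizes = {
        "fpg": (-0.18 * causal).tolist(),
        "pg2h": (-0.35 * causal).tolist(),
        "hba1c": (-0.12 * causal).tolist(),
    }
    return SimulationConfig(snp_specs=specs, effect_sizes=effect_sizes,
                            n_per_arm=n_per_arm, seed=seed)
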