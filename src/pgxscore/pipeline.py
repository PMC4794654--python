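"""End-to-end per-arm orchestration of the joint-score analysis.

The pipeline is a pure function of its inputs and configuration: genotype
QC, change-trait computation, per-SNP screening with orientation and
selection, score construction with tertiles, the association suite, and
both attainment-definition survival analyses per trait. Every intermediate
table is written out, exclusions are logged with row counts, and a manifest
records the configuration hash so reruns are auditable and byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import ScoreAssociation
from .exceptions import ConfigurationError, PipelineError
from .io import read_genotypes, read_phenotypes
from .qc import qc_filter
from .score import GeneticScorer
from .screening import (
    AdditiveScreener,
    baseline_values,
    compute_deltas,
    final_dose,
    mean_dose,
    subject_covariates,
)
from .survival import (
    AttainmentSpec,
    attainment_rates,
    build_survival_data,
    cox_fit,
    logrank,
)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    genotypes: str
    phenotypes: str
    out_dir: str
    dialect: str = "auto"
    meta_path: str | None = None
    arms: list[str] | None = None  # None = every arm in the phenotype table
    hwe_p_threshold: float = 0.01
    beta_threshold_fpg: float = -0.5
    beta_threshold_2hpg: float = -1.0
    beta_threshold_hba1c: float = -0.5
    p_threshold: float = 0.2
    missing_score: str = "exclude"
    nonresponder: str = "week48"
    dose_covariate: str = "final"  # or "mean"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for label, path in (("genotypes", self.genotypes),
                            ("phenotypes", self.phenotypes)):
            if not Path(path).exists():
                raise ConfigurationError(f"{label} file not found: {path}")
        if self.missing_score not in ("exclude", "mean"):
            raise ConfigurationError("missing_score must be 'exclude' or 'mean'")
        if self.nonresponder not in ("week48", "censor"):
            raise ConfigurationError("nonresponder must be 'week48' or 'censor'")
        if self.dose_covariate not in ("final", "mean"):
            raise ConfigurationError("dose_covariate must be 'final' or 'mean'")


@dataclass
class ArmResult:
    """All tables produced for one treatment arm."""

    arm: str
    qc_report: pd.DataFrame
    screening: pd.DataFrame
    selection: pd.DataFrame
    scores: pd.DataFrame | None = None
    cutpoints: tuple | None = None
    association: pd.DataFrame | None = None
    contrasts: pd.DataFrame | None = None
    tertile_summary: pd.DataFrame | None = None
    survival_tests: pd.DataFrame | None = None
    survival_data: pd.DataFrame | None = None
    curves: pd.DataFrame | None = None
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def _write(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def _analyse_arm(config: PipelineConfig, arm: str, genotypes, phenotypes) -> ArmResult:
    counts: dict = {}
    warnings: list[str] = []

    def stage(name, func, *args, **kwargs):
        try:
            return func(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    arm_pheno = phenotypes[phenotypes["arm"] == arm]
    subjects = arm_pheno["subject_id"].unique()
    counts["subjects_in_arm"] = len(subjects)
    arm_genotypes = genotypes.select_snps(genotypes.snp_ids)
    present = [s for s in subjects if s in arm_genotypes.dosage.index]
    missing_geno = len(subjects) - len(present)
    if missing_geno:
        warnings.append(f"{missing_geno} subjects lack genotypes; excluded")
    from .io import GenotypeMatrix
    arm_genotypes = GenotypeMatrix(
        dosage=arm_genotypes.dosage.loc[present],
        snp_meta=arm_genotypes.snp_meta,
    )
    counts["snps_genotyped"] = arm_genotypes.n_snps

    filtered, qc_report = stage("qc", qc_filter, arm_genotypes,
                                config.hwe_p_threshold)
    counts["snps_after_qc"] = filtered.n_snps

    deltas = stage("deltas", compute_deltas, arm_pheno)
    covariates = subject_covariates(arm_pheno)
    counts["subjects_with_deltas"] = int(deltas.notna().all(axis=1).sum())

    screener = AdditiveScreener(
        beta_threshold_fpg=config.beta_threshold_fpg,
        beta_threshold_2hpg=config.beta_threshold_2hpg,
        beta_threshold_hba1c=config.beta_threshold_hba1c,
        p_threshold=config.p_threshold,
    )
    stage("screening", screener.fit, filtered, deltas, covariates)
    counts["snps_selected"] = len(screener.panel_)
    result = ArmResult(arm=arm, qc_report=qc_report,
                       screening=screener.results_,
                       selection=screener.selection_,
                       counts=counts, warnings=warnings)
    if screener.selection_warning_:
        warnings.append(screener.selection_warning_)
        return result

    scorer = GeneticScorer(panel=screener.panel_, missing=config.missing_score)
    stage("score", scorer.fit, filtered)
    result.scores = pd.DataFrame({"score": scorer.scores_,
                                  "tertile": scorer.tertiles_})
    result.scores.index.name = "subject_id"
    result.cutpoints = scorer.cutpoints_
    counts["subjects_scored"] = int(scorer.scores_.notna().sum())

    dose = final_dose(arm_pheno) if config.dose_covariate == "final" \
        else mean_dose(arm_pheno)
    association = ScoreAssociation()
    stage("association", association.fit, deltas, scorer.scores_,
          scorer.tertiles_, covariates, baseline_values(arm_pheno), dose)
    result.association = association.results_
    result.contrasts = association.contrasts_
    result.tertile_summary = association.summary_

    test_rows, data_parts, curve_parts = [], [], []
    for criterion in ("threshold", "relative20"):
        for trait in ("fpg", "pg2h", "hba1c"):
            spec = AttainmentSpec(trait=trait, criterion=criterion)
            data, excl = stage(
                "survival", build_survival_data, arm_pheno, scorer.tertiles_,
                covariates, spec, config.nonresponder)
            warnings.extend(f"[{criterion}/{trait}] {w}" for w in excl)
            if data.empty or data["tertile"].nunique() < 2:
                warnings.append(f"[{criterion}/{trait}] too few groups; skipped")
                continue
            lr = stage("survival", logrank, data["time"], data["tertile"],
                       data["event"])
            try:
                cox = cox_fit(data)
                cox_coef, cox_hr, cox_se, cox_p, cox_note = (
                    cox.coef, cox.hazard_ratio, cox.se, cox.p, cox.note)
            except (ValueError, RuntimeError) as exc:
                cox_coef = cox_hr = cox_se = cox_p = float("nan")
                cox_note = str(exc)
            pairwise = {
                f"p_{row.group_a}_{row.group_b}": row.p
                for row in lr.pairwise.itertuples()
            }
            test_rows.append({
                "criterion": criterion, "trait": trait,
                "n": len(data), "events": int(data["event"].sum()),
                "logrank_chi2": lr.chi2, "logrank_df": lr.df,
                "logrank_p": lr.p, **pairwise,
                "cox_coef": cox_coef, "cox_hr": cox_hr,
                "cox_se": cox_se, "cox_p": cox_p, "cox_note": cox_note,
            })
            tagged = data.reset_index()
            tagged.insert(0, "criterion", criterion)
            tagged.insert(1, "trait_target", trait)
            data_parts.append(tagged)
            curves = attainment_rates(data["time"], data["tertile"], data["event"])
            curves.insert(0, "criterion", criterion)
            curves.insert(1, "trait_target", trait)
            curve_parts.append(curves)
    if test_rows:
        result.survival_tests = pd.DataFrame(test_rows)
        result.survival_data = pd.concat(data_parts, ignore_index=True)
        result.curves = pd.concat(curve_parts, ignore_index=True)
    return result


def run_pipeline(config: PipelineConfig) -> dict[str, ArmResult]:
    """Run the full analysis for every configured arm and write all tables."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    failed_marker = out_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        genotypes = read_genotypes(config.genotypes, dialect=config.dialect,
                                   meta_path=config.meta_path)
        phenotypes = read_phenotypes(config.phenotypes)
    except Exception as exc:
        failed_marker.write_text(f"stage 'input': {exc}\n")
        raise PipelineError("input", str(exc)) from exc
    arms = config.arms or sorted(phenotypes["arm"].unique())
    for arm in arms:
        if arm not in set(phenotypes["arm"]):
            failed_marker.write_text(f"stage 'input': arm {arm!r} absent\n")
            raise PipelineError("input", f"arm {arm!r} absent from phenotype table")

    results: dict[str, ArmResult] = {}
    for arm in arms:
        try:
            result = _analyse_arm(config, arm, genotypes, phenotypes)
        except PipelineError as exc:
            failed_marker.write_text(f"{exc}\n")
            raise
        results[arm] = result
        arm_dir = out_dir / arm
        arm_dir.mkdir(exist_ok=True)
        _write(result.qc_report, arm_dir / "qc_report.tsv")
        _write(result.screening, arm_dir / "screening.tsv")
        _write(result.selection, arm_dir / "selection.tsv")
        if result.scores is not None:
            _write(result.scores.reset_index(), arm_dir / "scores.tsv")
            _write(result.association, arm_dir / "association.tsv")
            _write(result.contrasts, arm_dir / "tertile_contrasts.tsv")
            _write(result.tertile_summary, arm_dir / "tertile_summary.tsv")
        if result.survival_tests is not None:
            _write(result.survival_tests, arm_dir / "survival_tests.tsv")
            _write(result.survival_data, arm_dir / "survival_data.tsv")
            _write(result.curves, arm_dir / "attainment_curves.tsv")
        (arm_dir / "report.txt").write_text(render_report({arm: result}))

    manifest = {
        "config": dataclasses.asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "arms": {arm: results[arm].counts for arm in results},
        "warnings": {arm: results[arm].warnings for arm in results},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    (out_dir / "report.txt").write_text(render_report(results))
    return results


def render_report(results: dict[str, ArmResult]) -> str:
    """Human-readable summary mirroring the analysis structure."""
    lines: list[str] = []
    for arm, result in results.items():
        lines.append(f"=== Arm: {arm} ===")
        for key, value in result.counts.items():
            lines.append(f"  {key}: {value}")
        if result.cutpoints:
            s1, s2 = result.cutpoints
            lines.append(f"  score tertile cut points: T1 <= {s1:g} < T2 <= {s2:g} < T3")
        if result.association is not None:
            lines.append("  -- score-efficacy association (beta per step) --")
            for row in result.association.itertuples():
                lines.append(
                    f"  {row.trait:8s} {row.mode:16s} {row.covariate_set:14s} "
                    f"beta={row.beta:+.3f} se={row.se:.3f} p={row.p:.4f} n={row.n}"
                )
        else:
            lines.append("  [association section absent: no SNPs selected]")
        if result.tertile_summary is not None:
            lines.append("  -- per-tertile mean +/- SEM --")
            for row in result.tertile_summary.itertuples():
                sem = f"{row.sem:.3f}" if pd.notna(row.sem) else "NA"
                mean = f"{row.mean:+.3f}" if pd.notna(row.mean) else "NA"
                lines.append(f"  {row.trait:8s} {row.tertile}  n={row.n:<3d} "
                             f"mean={mean} sem={sem} {row.flag}")
        if result.survival_tests is not None:
            lines.append("  -- time-to-attainment tests --")
            for row in result.survival_tests.itertuples():
                lines.append(
                    f"  {row.criterion:10s} {row.trait:6s} events={row.events:<3d} "
                    f"logrank chi2={row.logrank_chi2:.3f} p={row.logrank_p:.4f} "
                    f"cox HR={row.cox_hr:.3f} p={row.cox_p:.4f}"
                )
        else:
            lines.append("  [survival section absent]")
        if result.warnings:
            lines.append("  -- warnings --")
            lines.extend(f"  {w}" for w in result.warnings)
        lines.append("")
    return "\n".join(lines)
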