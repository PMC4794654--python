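from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pgxscore.pipeline import PipelineConfig, run_pipeline
from pgxscore.simulate import (
    SimulationConfig,
    default_snp_specs,
    default_study_config,
    simulate_cohort,
    write_fixture,
)

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Modest two-arm study: 40 subjects/arm, 12 SNPs (4 causal)."""
    return default_study_config(seed=7, n_per_arm=40, n_snps=12, n_causal=4)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def paper_scale_fixture(tmp_path_factory):
    """Paper-scale on-disk fixture: 209 subjects (104 + 105), 46 SNPs."""
    directory = tmp_path_factory.mktemp("paper_fixture")
    config = default_study_config(seed=11)
    genotypes, cohort, truth = simulate_cohort(config)
    paths = write_fixture(genotypes, cohort, directory, truth=truth)
    return {"config": config, "genotypes": genotypes, "cohort": cohort,
            "truth": truth, "paths": paths}


@pytest.fixture(scope="session")
def pipeline_runs(paper_scale_fixture, tmp_path_factory):
    """The complete pipeline run twice on the paper-scale fixture."""
    paths = paper_scale_fixture["paths"]
    outputs = []
    for label in ("run_a", "run_b"):
        out_dir = tmp_path_factory.mktemp(label)
        config = PipelineConfig(
            genotypes=str(paths["vcf"]),
            phenotypes=str(paths["phenotypes"]),
            out_dir=str(out_dir),
        )
        results = run_pipeline(config)
        outputs.append((out_dir, results))
    return outputs


def make_genotype_matrix(dosage_rows, snp_ids=None, subject_ids=None,
                         ref="A", alt="G"):
    """Hand-built GenotypeMatrix with uniform ref/alt alleles."""
    from pgxscore.io import GenotypeMatrix

    dosage_rows = np.asarray(dosage_rows, dtype=float)
    n, m = dosage_rows.shape
    snp_ids = snp_ids or [f"snp{j + 1}" for j in range(m)]
    subject_ids = subject_ids or [f"S{i + 1}" for i in range(n)]
    dosage = pd.DataFrame(dosage_rows,
                          index=pd.Index(subject_ids, name="subject_id"),
                          columns=snp_ids)
    meta = pd.DataFrame(
        {"chrom": "1", "ref": ref, "alt": alt, "counted_allele": alt},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(dosage=dosage, snp_meta=meta)
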