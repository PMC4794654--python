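"""Genotype quality control: Hardy-Weinberg equilibrium and monomorphism.

Each SNP is tested for departure from Hardy-Weinberg proportions with a
Pearson chi-square on the three genotype counts (1 df, no continuity
correction): with allele frequency estimated as p = (2*n0 + n1) / (2n), the
expected counts are (n*p^2, 2n*p*q, n*q^2). SNPs departing at p < threshold
(default 0.01) or carrying only one allele (monomorphic) are excluded, which
mirrors standard pre-analysis filtering of candidate-SNP panels. Missing
genotypes are omitted from the counts; SNPs with call rate below 90% are
flagged in the report but not excluded automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import EmptyPanelError
from .io import GenotypeMatrix

REPORT_COLUMNS = [
    "snp_id", "n0", "n1", "n2", "chi2", "p",
    "monomorphic", "call_rate", "low_call_rate", "passed",
]


@dataclass(frozen=True)
class HWEResult:
    """Hardy-Weinberg test result for one SNP."""

    snp_id: str
    n0: int
    n1: int
    n2: int
    chi2: float
    p: float
    monomorphic: bool
    passed: bool


def hwe_test(n0: int, n1: int, n2: int, snp_id: str = "",
             p_threshold: float = 0.01) -> HWEResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (1 df).

    ``passed`` is True when the SNP is polymorphic and p >= ``p_threshold``
    (exclusion uses strict p < threshold). Monomorphic SNPs get chi2 = 0 and
    p = 1 but never pass.
    """
    counts = np.array([n0, n1, n2], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("at least one called genotype is required")
    p_hat = (2 * n0 + n1) / (2 * n)
    q_hat = 1.0 - p_hat
    monomorphic = p_hat == 0.0 or p_hat == 1.0
    if monomorphic:
        chi2, p = 0.0, 1.0
    else:
        expected = np.array([n * p_hat ** 2, 2 * n * p_hat * q_hat, n * q_hat ** 2])
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(chi2, df=1))
    passed = (not monomorphic) and p >= p_threshold
    return HWEResult(snp_id, int(n0), int(n1), int(n2), chi2, p, monomorphic, passed)


def _dosage_frame(genotypes) -> pd.DataFrame:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.dosage
    return pd.DataFrame(genotypes)


def hwe_scan(genotypes, p_threshold: float = 0.01,
             call_rate_threshold: float = 0.9) -> pd.DataFrame:
    """Per-SNP QC report for a genotype matrix (dosage-coded 0/1/2/NaN)."""
    dosage = _dosage_frame(genotypes)
    rows = []
    for snp_id in dosage.columns:
        column = dosage[snp_id].to_numpy(dtype=float)
        called = column[~np.isnan(column)]
        if called.size == 0:
            raise ValueError(f"SNP {snp_id} has no called genotypes")
        n0 = int((called == 0).sum())
        n1 = int((called == 1).sum())
        n2 = int((called == 2).sum())
        result = hwe_test(n0, n1, n2, snp_id=snp_id, p_threshold=p_threshold)
        call_rate = called.size / column.size
        rows.append({
            "snp_id": snp_id, "n0": n0, "n1": n1, "n2": n2,
            "chi2": result.chi2, "p": result.p,
            "monomorphic": result.monomorphic,
            "call_rate": call_rate,
            "low_call_rate": call_rate < call_rate_threshold,
            "passed": result.passed,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def qc_filter(matrix: GenotypeMatrix, hwe_p_threshold: float = 0.01,
              call_rate_threshold: float = 0.9) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop monomorphic and HWE-departing SNPs; return (matrix, full report)."""
    if matrix.n_snps == 0:
        raise ValueError("genotype matrix has no SNPs")
    report = hwe_scan(matrix, p_threshold=hwe_p_threshold,
                      call_rate_threshold=call_rate_threshold)
    keep = report.loc[report["passed"], "snp_id"].tolist()
    if not keep:
        raise EmptyPanelError("all SNPs removed by QC")
    return matrix.select_snps(keep), report


class HardyWeinbergFilter(BaseEstimator, TransformerMixin):
    """Transformer that removes monomorphic and HWE-departing SNPs.

    Accepts a :class:`~pgxscore.io.GenotypeMatrix` or a plain dosage
    DataFrame; ``transform`` returns the same type restricted to the SNPs
    retained during ``fit``.
    """

    def __init__(self, p_threshold: float = 0.01, call_rate_threshold: float = 0.9):
        self.p_threshold = p_threshold
        self.call_rate_threshold = call_rate_threshold

    def fit(self, X, y=None):
        self.results_ = hwe_scan(X, p_threshold=self.p_threshold,
                                 call_rate_threshold=self.call_rate_threshold)
        self.keep_ = self.results_.loc[self.results_["passed"], "snp_id"].tolist()
        if not self.keep_:
            raise EmptyPanelError("all SNPs removed by QC")
        return self

    def transform(self, X):
        if not hasattr(self, "keep_"):
            raise RuntimeError("HardyWeinbergFilter is not fitted")
        if isinstance(X, GenotypeMatrix):
            return X.select_snps(self.keep_)
        return _dosage_frame(X)[self.keep_]
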