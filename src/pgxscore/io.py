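"""Genotype and phenotype file handling.

Two genotype dialects are supported:

* ``vcf`` — minimal VCF v4.2 with a per-sample ``GT`` field; biallelic
  records only, one record per SNP, unique IDs required.
* ``dosage`` — tab-delimited matrix, rows = subjects, columns = SNP ids,
  values ``0``/``1``/``2``/``NA``, accompanied by a SNP metadata sidecar
  (``snp_id``, ``chrom``, ``ref``, ``alt``).

Dosage values count copies of the *counted* allele, which on read is always
the ALT allele. Re-orientation to per-SNP effect alleles is a screening-stage
concern and never happens here.

The longitudinal phenotype table is tab-delimited with one row per
subject-visit and columns ``subject_id, arm, age, sex, bmi0, week, fpg,
pg2h, hba1c, dose_mg, status``; missing values are written as ``NA``.
Sex is coded female = 0, male = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ParseError

PHENOTYPE_COLUMNS = [
    "subject_id", "arm", "age", "sex", "bmi0", "week",
    "fpg", "pg2h", "hba1c", "dose_mg", "status",
]
STATUS_VALUES = ("active", "withdrawn_control", "lost")

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class GenotypeMatrix:
    """Subjects x SNPs additive genotype codes plus per-SNP allele metadata.

    Attributes
    ----------
    dosage : pandas.DataFrame
        Float matrix indexed by subject id with one column per SNP id;
        entries are 0/1/2 copies of the counted allele, NaN when missing.
    snp_meta : pandas.DataFrame
        Indexed by SNP id with columns ``chrom``, ``ref``, ``alt`` and
        ``counted_allele``.
    """

    dosage: pd.DataFrame
    snp_meta: pd.DataFrame

    def __post_init__(self):
        if self.dosage.index.duplicated().any():
            raise ValueError("duplicate subject ids in genotype matrix")
        if self.dosage.columns.duplicated().any():
            raise ValueError("duplicate SNP ids in genotype matrix")
        if list(self.dosage.columns) != list(self.snp_meta.index):
            raise ValueError("dosage columns and SNP metadata rows disagree")
        required = {"chrom", "ref", "alt", "counted_allele"}
        missing = required - set(self.snp_meta.columns)
        if missing:
            raise ValueError(f"SNP metadata lacks columns: {sorted(missing)}")
        values = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be 0, 1, 2 or missing")

    @property
    def subject_ids(self) -> list:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list:
        return list(self.dosage.columns)

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def select_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        """Restrict to the given SNPs, preserving subject order."""
        missing = [s for s in snp_ids if s not in self.dosage.columns]
        if missing:
            raise KeyError(f"SNPs absent from matrix: {missing}")
        return GenotypeMatrix(
            dosage=self.dosage[list(snp_ids)].copy(),
            snp_meta=self.snp_meta.loc[list(snp_ids)].copy(),
        )

    def oriented_dosage(self, snp_id: str, allele: str) -> pd.Series:
        """Copies of ``allele`` per subject for one SNP.

        Flips the coding (x -> 2 - x) when ``allele`` is the complement of
        the counted allele.
        """
        meta = self.snp_meta.loc[snp_id]
        counted = meta["counted_allele"]
        other = meta["ref"] if counted == meta["alt"] else meta["alt"]
        column = self.dosage[snp_id]
        if allele == counted:
            return column
        if allele == other:
            return 2.0 - column
        raise ValueError(
            f"allele {allele!r} is neither allele of SNP {snp_id} "
            f"({meta['ref']}/{meta['alt']})"
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.dosage.equals(other.dosage)
            and self.snp_meta.equals(other.snp_meta)
        )


# ---------------------------------------------------------------------------
# genotype reading


def read_genotypes(path, dialect: str = "auto", meta_path=None) -> GenotypeMatrix:
    """Read a genotype file in either supported dialect.

    ``dialect="auto"`` treats ``*.vcf`` files as VCF and anything else as a
    dosage matrix; ``meta_path`` overrides the default sidecar location of
    the dosage dialect (``<file stem>.snps.tsv``).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "vcf" if path.suffix == ".vcf" else "dosage"
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "dosage":
        return _read_dosage(path, meta_path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise ParseError(path, None, f"cannot open VCF: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(path, None, "VCF contains no samples")
    snp_ids, meta_rows, columns = [], [], []
    for variant in vcf:
        if variant.ID is None:
            raise ParseError(path, None, f"record at {variant.CHROM}:{variant.POS} has no ID")
        if len(variant.ALT) != 1:
            raise ParseError(path, None, f"multi-allelic record {variant.ID} rejected")
        if variant.ID in snp_ids:
            raise ParseError(path, None, f"duplicate SNP id {variant.ID}")
        codes = np.asarray(variant.gt_types, dtype=float)  # 0/1/2, 3 = missing
        codes[codes == 3] = np.nan
        snp_ids.append(variant.ID)
        meta_rows.append((variant.CHROM, variant.REF, variant.ALT[0], variant.ALT[0]))
        columns.append(codes)
    dosage = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="subject_id"),
        columns=snp_ids,
    )
    snp_meta = pd.DataFrame(
        meta_rows,
        index=pd.Index(snp_ids, name="snp_id"),
        columns=["chrom", "ref", "alt", "counted_allele"],
    )
    return GenotypeMatrix(dosage=dosage, snp_meta=snp_meta)


def _default_meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".snps.tsv")


def _read_dosage(path: Path, meta_path=None) -> GenotypeMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_path = Path(meta_path) if meta_path is not None else _default_meta_path(path)
    if not meta_path.exists():
        raise ParseError(meta_path, None, "SNP metadata sidecar not found")

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "subject_id":
            raise ParseError(path, 1, "first column must be 'subject_id'")
        snp_ids = header[1:]
        if len(set(snp_ids)) != len(snp_ids):
            raise ParseError(path, 1, "duplicate SNP id in header")
        subjects, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(path, lineno, f"expected {len(header)} fields, got {len(fields)}")
            subjects.append(fields[0])
            row = []
            for value, snp in zip(fields[1:], snp_ids):
                if value == "NA":
                    row.append(np.nan)
                elif value in ("0", "1", "2"):
                    row.append(float(value))
                else:
                    raise ParseError(path, lineno, f"invalid dosage {value!r} for SNP {snp}")
            rows.append(row)
    dosage = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(subjects), len(snp_ids)),
        index=pd.Index(subjects, name="subject_id"),
        columns=snp_ids,
    )
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    expected = ["snp_id", "chrom", "ref", "alt"]
    if list(meta.columns) != expected:
        raise ParseError(meta_path, 1, f"sidecar columns must be {expected}")
    meta = meta.set_index("snp_id")
    if set(meta.index) != set(snp_ids):
        raise ParseError(meta_path, None, "sidecar SNP set disagrees with matrix header")
    meta = meta.loc[snp_ids]
    meta["counted_allele"] = meta["alt"]
    return GenotypeMatrix(dosage=dosage, snp_meta=meta)


# ---------------------------------------------------------------------------
# genotype writing


def write_vcf(matrix: GenotypeMatrix, path) -> Path:
    """Write a minimal VCF v4.2 (GT only). Positions are synthetic ordinals."""
    path = Path(path)
    code_to_gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(matrix.snp_meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in matrix.subject_ids)
            + "\n"
        )
        for position, snp_id in enumerate(matrix.snp_ids, start=1):
            meta = matrix.snp_meta.loc[snp_id]
            genotypes = [
                "./." if np.isnan(v) else code_to_gt[v]
                for v in matrix.dosage[snp_id].to_numpy(dtype=float)
            ]
            fh.write(
                f"{meta['chrom']}\t{position * 1000}\t{snp_id}\t{meta['ref']}\t"
                f"{meta['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(genotypes) + "\n"
            )
    return path


def write_dosage(matrix: GenotypeMatrix, path, meta_path=None) -> tuple[Path, Path]:
    """Write the tab-delimited dosage dialect plus its metadata sidecar."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _default_meta_path(path)
    out = matrix.dosage.copy()
    formatted = out.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    formatted.index.name = "subject_id"
    formatted.to_csv(path, sep="\t")
    meta = matrix.snp_meta[["chrom", "ref", "alt"]].copy()
    meta.index.name = "snp_id"
    meta.to_csv(meta_path, sep="\t")
    return path, meta_path


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate the longitudinal phenotype table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        dtype={"subject_id": str, "arm": str, "status": str},
    )
    if list(table.columns) != PHENOTYPE_COLUMNS:
        raise ParseError(path, 1, f"phenotype columns must be {PHENOTYPE_COLUMNS}")
    bad_status = set(table["status"].dropna()) - set(STATUS_VALUES)
    if bad_status:
        raise ParseError(path, None, f"invalid status values: {sorted(bad_status)}")
    duplicated = table.duplicated(subset=["subject_id", "week"])
    if duplicated.any():
        first = int(np.flatnonzero(duplicated.to_numpy())[0]) + 2
        raise ParseError(path, first, "duplicate (subject_id, week) row")
    return table


def write_phenotypes(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)
    return path
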