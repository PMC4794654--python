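"""Worked-example screening summaries for the two drug cohorts.

Published per-SNP screening estimates (oriented coefficient +/- SE per
change trait, with the effect allele) for the 22-SNP repaglinide panel and
the 23-SNP rosiglitazone panel of the original candidate-gene study. The
source table prints coefficients only for the qualifying traits and no
p-values, so these rows exercise the coefficient-threshold arm of the
selection rule; the p-value arm is inert here (missing p never qualifies).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .screening import TRAITS

# (gene, snp_id, chrom, effect_allele,
#  (beta, se) for d_fpg, d_2hpg, d_hba1c; None where not printed)
REPAGLINIDE_SCREEN = (
    ("PPARG", "rs1801282", "3", "G", (-1.13, 0.71), (-2.92, 1.62), (-1.22, 0.62)),
    ("IGF2BP2", "rs7651090", "3", "G", None, (-1.22, 0.85), None),
    ("WFS1", "rs10010131", "4", "A", None, (-2.05, 1.79), None),
    ("ZBED3-AS1", "rs4457053", "5", "G", (-0.53, 0.77), None, None),
    ("CDKAL1", "rs7756992", "6", "A", (-0.85, 0.34), None, (-0.55, 0.29)),
    ("KCNK16", "rs1535500", "6", "G", None, (-1.11, 0.69), None),
    ("YKT6", "rs917793", "7", "T", (-0.73, 0.38), None, None),
    ("KLF14", "rs972283", "7", "A", None, (-1.3, 0.85), None),
    ("JAZF1", "rs864745", "7", "G", None, (-1.25, 0.72), None),
    ("PAX4", "rs6467136", "7", "A", None, None, (-0.55, 0.27)),
    ("PTPRD", "rs17584499", "9", "T", (-0.53, 0.48), None, None),
    ("VPS26A", "rs1802295", "10", "C", (-0.5093, 0.51), None, (-0.70, 0.42)),
    ("TCF7L2", "rs7903146", "10", "T", (-0.68, 0.56), None, (-0.94, 0.48)),
    ("ARAP1", "rs1552224", "11", "G", (-0.66, 0.49), (-1.03, 1.13), None),
    ("KCNJ11", "rs5219", "11", "T", None, None, (-0.60, 0.26)),
    ("TENM4", "rs10751301", "11", "C", None, (-1.14, 0.88), None),
    ("TSPAN8", "rs7961581", "12", "T", None, (-1.04, 0.82), None),
    ("13q31.1", "rs1359790", "13", "T", (-0.57, 0.34), (-1.20, 0.77), None),
    ("ZFAND6", "rs11634397", "15", "G", (-0.79, 0.64), (-1.80, 1.40), None),
    ("AP3S2", "rs2028299", "15", "A", (-0.68, 0.32), None, None),
    ("MAF", "rs17797882", "16", "T", (-0.52, 0.35), None, None),
    ("SRR", "rs391300", "17", "A", (-0.52, 0.36), (-1.39, 0.86), (-0.70, 0.29)),
)

ROSIGLITAZONE_SCREEN = (
    ("RBMS1", "rs7593730", "2", "T", (-0.52, 0.50), None, None),
    ("GRB14", "rs3923113", "2", "C", (-1.38, 0.45), None, None),
    ("UBE2E2", "rs7612463", "3", "A", (-0.59, 0.40), (-1.14, 0.78), None),
    ("PPARG", "rs1801282", "3", "G", (-1.00, 0.73), (-2.68, 1.39), None),
    ("MAEA", "rs6815464", "4", "C", (-0.54, 0.35), None, None),
    ("WFS1", "rs10010131", "4", "A", None, (-1.30, 1.57), None),
    ("ZBED3-AS1", "rs4457053", "5", "A", None, (-2.40, 1.49), None),
    ("ZFAND3", "rs9470794", "6", "C", (-0.54, 0.34), None, None),
    ("YKT6", "rs917793", "7", "A", (-0.62, 0.34), None, None),
    ("PAX4", "rs6467136", "7", "A", None, (-2.04, 0.84), None),
    ("TP53INP1", "rs896854", "8", "G", None, None, (-0.52, 0.27)),
    ("SLC30A8", "rs13266634", "8", "T", None, (-1.16, 0.60), None),
    ("PTPRD", "rs17584499", "9", "C", None, (-2.18, 1.23), (-0.76, 0.52)),
    ("CDC123", "rs12779790", "10", "A", (-0.63, 0.37), None, None),
    ("TCF7L2", "rs7903146", "10", "C", None, (-1.50, 1.64), None),
    ("KCNQ1", "rs231362", "11", "C", None, (-1.08, 0.94), None),
    ("ARAP1", "rs1552224", "11", "G", None, None, (-0.52, 0.49)),
    ("TENM4", "rs10751301", "11", "G", None, (-1.53, 0.73), None),
    ("13q31.1", "rs1359790", "13", "C", None, (-0.71, 0.67), None),
    ("HMG20A", "rs7178572", "15", "A", (-0.57, 0.28), None, (-0.50, 0.22)),
    ("ZFAND6", "rs11634397", "15", "G", (-0.56, 0.56), (-1.04, 1.10), None),
    ("MAF", "rs17797882", "16", "C", None, (-1.02, 0.64), None),
    ("FTO", "rs8050136", "16", "C", (-0.68, 0.37), None, None),
)

_TABLES = {"repaglinide": REPAGLINIDE_SCREEN, "rosiglitazone": ROSIGLITAZONE_SCREEN}


def load_example_screening(arm: str = "repaglinide") -> pd.DataFrame:
    """Oriented long-format screening results for one drug cohort.

    The frame matches the screening-result layout (one row per SNP x trait)
    so it feeds :func:`pgxscore.screening.select_snps` directly; p-values are
    NaN throughout because the source prints none.
    """
    try:
        table = _TABLES[arm]
    except KeyError:
        raise ValueError(f"unknown arm {arm!r}; choose from {sorted(_TABLES)}")
    rows = []
    for gene, snp_id, chrom, allele, *estimates in table:
        for trait, estimate in zip(TRAITS, estimates):
            beta, se = estimate if estimate is not None else (np.nan, np.nan)
            rows.append({
                "gene": gene, "snp_id": snp_id, "chrom": chrom,
                "trait": trait, "beta": beta, "se": se, "p": np.nan,
                "n": np.nan, "estimable": estimate is not None,
                "effect_allele": allele, "oriented": True,
            })
    return pd.DataFrame(rows)
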