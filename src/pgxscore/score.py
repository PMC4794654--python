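"""Unweighted effect-allele-count genetic score and tertile stratification.

The score of a subject is the plain sum, over the selected SNP panel, of
the subject's effect-allele counts (0/1/2 per SNP), so it is an integer in
[0, 2 * panel size]. No beta weighting is applied. Tertiles are formed on
the score with a cumulative-count rule that never splits tied scores: the
lower cut is the smallest score value whose cumulative count reaches n/3,
the upper cut the smallest value above it reaching 2n/3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import GenotypeMatrix

TERTILE_LABELS = ("T1", "T2", "T3")


def _panel_frame(panel) -> pd.DataFrame:
    """Normalise a panel argument to a frame indexed by snp_id."""
    if isinstance(panel, pd.DataFrame):
        frame = panel.copy()
        if "snp_id" in frame.columns:
            frame = frame.set_index("snp_id")
    else:  # iterable of (snp_id, effect_allele)
        frame = pd.DataFrame(panel, columns=["snp_id", "effect_allele"]).set_index("snp_id")
    if "effect_allele" not in frame.columns:
        raise ValueError("panel must provide an 'effect_allele' column")
    return frame


def compute_score(genotypes: GenotypeMatrix, panel,
                  missing: str = "exclude") -> pd.Series:
    """Sum of effect-allele counts over the panel, per subject.

    ``missing="exclude"`` (default) leaves the score undefined (NaN) for
    subjects with any missing panel genotype; ``missing="mean"`` imputes the
    per-SNP mean oriented dosage instead.
    """
    if missing not in ("exclude", "mean"):
        raise ValueError("missing policy must be 'exclude' or 'mean'")
    frame = _panel_frame(panel)
    absent = [s for s in frame.index if s not in genotypes.dosage.columns]
    if absent:
        raise KeyError(f"panel SNPs absent from genotype matrix: {absent}")
    oriented = pd.DataFrame({
        snp_id: genotypes.oriented_dosage(snp_id, frame.loc[snp_id, "effect_allele"])
        for snp_id in frame.index
    })
    if missing == "mean":
        oriented = oriented.fillna(oriented.mean())
        scores = oriented.sum(axis=1)
    else:
        scores = oriented.sum(axis=1, skipna=False)
    return scores.rename("score")


def assign_tertiles(scores: pd.Series) -> tuple[pd.Series, tuple[float, float]]:
    """Tertile labels and integer cut points under the cumulative-count rule.

    Cut points (s1, s2) satisfy T1: score <= s1 < T2: score <= s2 < T3.
    Subjects sharing a score always share a tertile. Raises when fewer than
    three distinct score values exist or the rule cannot place a non-empty
    top tertile.
    """
    defined = scores.dropna()
    values, counts = np.unique(defined.to_numpy(dtype=float), return_counts=True)
    if values.size < 3:
        raise ValueError("tertiles undefined: fewer than 3 distinct score values")
    n = counts.sum()
    cumulative = np.cumsum(counts)
    s1 = values[np.argmax(cumulative >= n / 3)]
    above = (values > s1) & (cumulative >= 2 * n / 3)
    if not above.any():
        raise ValueError("tertiles undefined: ties leave no room for an upper cut")
    s2 = values[np.argmax(above)]
    if s2 >= values[-1]:
        raise ValueError("tertiles undefined: top tertile would be empty")
    labels = pd.Series(pd.NA, index=scores.index, dtype="object", name="tertile")
    labels[scores <= s1] = "T1"
    labels[(scores > s1) & (scores <= s2)] = "T2"
    labels[scores > s2] = "T3"
    return labels, (float(s1), float(s2))


def tertile_index(tertiles: pd.Series) -> pd.Series:
    """Map T1/T2/T3 labels to the 1/2/3 linear trend coding."""
    mapping = {label: i + 1 for i, label in enumerate(TERTILE_LABELS)}
    return tertiles.map(mapping).rename("tertile_index")


class GeneticScorer(BaseEstimator, TransformerMixin):
    """Transformer computing the allele-count score and tertile labels.

    ``fit`` computes scores on the training cohort and freezes the tertile
    cut points; ``transform`` scores any genotype matrix containing the
    panel and labels it with the fitted cuts, so held-out subjects can be
    placed on the training cohort's scale.

    Attributes
    ----------
    scores_ : pandas.Series
        Training-cohort scores (NaN where the missing policy excludes).
    tertiles_ : pandas.Series
        Training-cohort tertile labels.
    cutpoints_ : tuple of float
        The (s1, s2) score cut points.
    """

    def __init__(self, panel=None, missing: str = "exclude"):
        self.panel = panel
        self.missing = missing

    def fit(self, X: GenotypeMatrix, y=None):
        if self.panel is None:
            raise ValueError("GeneticScorer requires a panel of (snp_id, effect_allele)")
        self.panel_ = _panel_frame(self.panel)
        self.scores_ = compute_score(X, self.panel_, missing=self.missing)
        self.tertiles_, self.cutpoints_ = assign_tertiles(self.scores_)
        return self

    def transform(self, X: GenotypeMatrix) -> pd.DataFrame:
        if not hasattr(self, "cutpoints_"):
            raise RuntimeError("GeneticScorer is not fitted")
        scores = compute_score(X, self.panel_, missing=self.missing)
        s1, s2 = self.cutpoints_
        labels = pd.Series(pd.NA, index=scores.index, dtype="object", name="tertile")
        labels[scores <= s1] = "T1"
        labels[(scores > s1) & (scores <= s2)] = "T2"
        labels[scores > s2] = "T3"
        return pd.DataFrame({"score": scores, "tertile": labels})
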