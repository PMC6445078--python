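"""Weighted additive genetic risk scores.

Builds the expanded (all panel SNPs) and conservative (pleiotropy-screened)
weighted GRS used as instrumental variables.  Scoring applies the cohort
missingness policy: individuals missing more than ``max_missing`` (default 2)
subset SNPs are excluded; for one or two missing SNPs the missing term is
replaced by that SNP's mean weighted contribution among non-missing
individuals (a whole-score mean substitution is available behind
``impute="whole_score"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import SnpAnnotation
from .simulate import GenotypeMatrix

__all__ = [
    "ScoreSet",
    "GeneticRiskScorer",
    "build_grs",
    "select_conservative_set",
    "quartile_assign",
]


@dataclass
class ScoreSet:
    """Per-individual GRS values with the inclusion flag of the missingness policy."""

    scores: np.ndarray
    included: np.ndarray
    snp_subset: list[str]
    weighted: bool
    sd: float

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def per_sd(self) -> np.ndarray:
        """Scores divided by the sample SD among included individuals."""
        return self.scores / self.sd


def select_conservative_set(panel: Sequence[SnpAnnotation]) -> list[str]:
    """SNPs without reported pleiotropy that pass HWE and are associated with
    the exposure either in-sample or in East Asian populations; panel order."""
    return [
        s.rsid
        for s in panel
        if not s.pleiotropy_reported
        and s.hwe_pass
        and (s.assoc_significant or s.east_asian_identified)
    ]


class GeneticRiskScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping a :class:`GenotypeMatrix` to GRS values.

    Parameters
    ----------
    panel : list of SnpAnnotation
        Annotation supplying weights; required.
    subset : "expanded" | "conservative" | list of rsid
        SNPs entering the score.
    weighted : bool
        If False, unit weights (allele count score).
    impute : "per_snp" | "whole_score"
        Policy for individuals with 1..max_missing missing subset SNPs.
    max_missing : int
        Individuals missing more than this many subset SNPs are excluded.
    """

    def __init__(self, panel=None, subset="expanded", weighted=True,
                 impute="per_snp", max_missing=2):
        self.panel = panel
        self.subset = subset
        self.weighted = weighted
        self.impute = impute
        self.max_missing = max_missing

    def _resolve_subset(self) -> list[str]:
        panel_rsids = [s.rsid for s in self.panel]
        if isinstance(self.subset, str):
            if self.subset == "expanded":
                return panel_rsids
            if self.subset == "conservative":
                return select_conservative_set(self.panel)
            raise ValueError(f"unknown subset {self.subset!r}")
        unknown = set(self.subset) - set(panel_rsids)
        if unknown:
            raise ValueError(f"subset names SNPs not in panel: {sorted(unknown)}")
        return list(self.subset)

    def fit(self, X: GenotypeMatrix, y=None):
        if self.panel is None:
            raise ValueError("panel is required")
        if self.impute not in ("per_snp", "whole_score"):
            raise ValueError(f"unknown impute policy {self.impute!r}")
        rsids = self._resolve_subset()
        weight_by_rsid = {s.rsid: (s.weight if self.weighted else 1.0) for s in self.panel}
        cols = [X.snp_order.index(r) for r in rsids]
        dosages = X.dosages[:, cols].astype(float)
        mask = X.missing_mask[:, cols]
        observed_n = (~mask).sum(axis=0)
        empty = [r for r, c in zip(rsids, observed_n) if c == 0]
        if empty:
            raise ValueError(f"SNP column(s) entirely missing: {empty}")
        means = np.array(
            [dosages[~mask[:, j], j].mean() for j in range(len(rsids))]
        )
        self.rsids_ = rsids
        self.weights_ = np.array([weight_by_rsid[r] for r in rsids])
        self.snp_means_ = means  # mean observed dosage per subset SNP
        return self

    def transform(self, X: GenotypeMatrix) -> np.ndarray:
        """Scores as a float array; excluded individuals are NaN."""
        return self.score_set(X).scores

    def score_set(self, X: GenotypeMatrix) -> ScoreSet:
        cols = [X.snp_order.index(r) for r in self.rsids_]
        dosages = X.dosages[:, cols].astype(float)
        mask = X.missing_mask[:, cols]
        n_missing = mask.sum(axis=1)
        included = n_missing <= self.max_missing
        filled = np.where(mask, self.snp_means_, dosages)
        scores = filled @ self.weights_
        if self.impute == "whole_score":
            complete = n_missing == 0
            if not complete.any():
                raise ValueError("whole-score imputation requires at least one complete individual")
            mean_score = scores[complete].mean()
            scores = np.where(complete, scores, mean_score)
        scores = np.where(included, scores, np.nan)
        if included.sum() >= 2:
            sd = float(np.nanstd(scores[included], ddof=1))
        else:
            sd = float("nan")
        if not sd > 0:
            warnings.warn("degenerate score set: zero or undefined SD", stacklevel=2)
        return ScoreSet(scores, included, list(self.rsids_), bool(self.weighted), sd)


def build_grs(
    g: GenotypeMatrix,
    panel: Sequence[SnpAnnotation],
    subset=None,
    weighted: bool = True,
    impute: str = "per_snp",
    max_missing: int = 2,
) -> ScoreSet:
    """Score a genotype matrix; thin wrapper over :class:`GeneticRiskScorer`."""
    scorer = GeneticRiskScorer(
        panel=list(panel),
        subset="expanded" if subset is None else subset,
        weighted=weighted,
        impute=impute,
        max_missing=max_missing,
    )
    return scorer.fit(g).score_set(g)


def quartile_assign(scores: np.ndarray, included: np.ndarray | None = None) -> np.ndarray:
    """Quartile labels 1-4 from the 25/50/75 percentiles of included scores.

    Boundary values join the lower quartile; excluded individuals get label 0.
    Requires at least 4 included individuals.
    """
    scores = np.asarray(scores, dtype=float)
    if included is None:
        included = np.isfinite(scores)
    included = np.asarray(included, dtype=bool) & np.isfinite(scores)
    if included.sum() < 4:
        raise ValueError("quartile assignment requires at least 4 included individuals")
    cuts = np.percentile(scores[included], [25, 50, 75], method="linear")
    labels = np.zeros(scores.shape, dtype=int)
    labels[included] = 1 + np.searchsorted(cuts, scores[included], side="left")
    return labels
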