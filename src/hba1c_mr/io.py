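"""Plain-text I/O: genotype, phenotype, score and summary-statistic tables.

Genotype tables use a PLINK .raw-style additive dialect: one row per
individual, an ``id`` column, rsid-named dosage columns (0/1/2) and ``NA``
for missing calls.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grs import ScoreSet
from .simulate import GenotypeMatrix

__all__ = [
    "write_genotypes", "read_genotypes",
    "write_phenotypes", "read_phenotypes",
    "write_scores", "read_summary_stats", "write_summary_stats",
    "write_truth",
]


def write_genotypes(g: GenotypeMatrix, path, ids=None) -> None:
    g.to_frame(ids=ids).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    snp_cols = [c for c in df.columns if c != "id"]
    values = df[snp_cols].to_numpy(dtype=float)
    mask = ~np.isfinite(values)
    dosages = np.where(mask, 0, values).astype(np.int8)
    return GenotypeMatrix(dosages, mask, snp_cols)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_scores(s: ScoreSet, path, quartile=None, ids=None) -> None:
    df = pd.DataFrame(
        {
            "id": ids if ids is not None else np.arange(len(s.scores)),
            "score": s.scores,
            "included": s.included.astype(int),
        }
    )
    if quartile is not None:
        df["quartile"] = quartile
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_summary_stats(ss: pd.DataFrame, path) -> None:
    ss.to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2))
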