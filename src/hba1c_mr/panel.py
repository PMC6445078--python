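"""Instrument SNP annotations.

A genetic risk score (GRS) instrument is defined by a panel of SNPs, each with
a risk allele, a published per-allele effect (weight) on HbA1c in percent
units, a risk-allele frequency, and eligibility flags used to derive the
pleiotropy-conservative sub-panel.

The shipped default panel lists the 17 HbA1c-associated loci used to build the
expanded score.  Its weights and frequencies are synthetic placeholders (the
source GWAS effect sizes are not bundled); replace the annotation file with
your own to use literature values.  All computations read weights from the
annotation, never from hard-coded constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["SnpAnnotation", "load_panel", "default_panel", "panel_to_frame", "write_panel"]

_FLAG_COLUMNS = (
    "pleiotropy_reported",
    "hwe_pass",
    "assoc_significant",
    "east_asian_identified",
)


@dataclass(frozen=True)
class SnpAnnotation:
    """One instrument SNP.

    Parameters
    ----------
    rsid : str
        dbSNP identifier; must be unique within a panel.
    locus : str
        Gene or region label (reporting only).
    risk_allele : str
        The HbA1c-increasing allele; dosages are counted on this allele.
    weight : float
        Published per-allele effect on HbA1c, percent units.
    freq : float
        Risk-allele frequency, open interval (0, 1).
    pleiotropy_reported, hwe_pass, assoc_significant, east_asian_identified : bool
        Eligibility flags feeding the conservative-set selection rule.
    """

    rsid: str
    locus: str = ""
    risk_allele: str = "A"
    weight: float = 0.0
    freq: float = 0.5
    pleiotropy_reported: bool = False
    hwe_pass: bool = True
    assoc_significant: bool = True
    east_asian_identified: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.weight):
            raise ValueError(f"{self.rsid}: weight must be finite, got {self.weight}")
        # frequencies within 1e-8 of a boundary are degenerate (monomorphic)
        if not 1e-8 < self.freq < 1.0 - 1e-8:
            raise ValueError(
                f"{self.rsid}: risk-allele frequency must lie strictly inside (0, 1), "
                f"got {self.freq}"
            )


def load_panel(path: str | Path) -> list[SnpAnnotation]:
    """Read a SNP annotation TSV (``#`` lines are comments) into a panel."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"rsid": str})
    required = {"rsid", "weight", "freq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    panel = []
    for row in df.itertuples(index=False):
        kwargs = {
            "rsid": row.rsid,
            "locus": getattr(row, "locus", ""),
            "risk_allele": getattr(row, "risk_allele", "A"),
            "weight": float(row.weight),
            "freq": float(row.freq),
            "note": "" if pd.isna(getattr(row, "note", "")) else str(getattr(row, "note", "")),
        }
        for flag in _FLAG_COLUMNS:
            if hasattr(row, flag):
                kwargs[flag] = bool(getattr(row, flag))
        panel.append(SnpAnnotation(**kwargs))
    rsids = [s.rsid for s in panel]
    if len(set(rsids)) != len(rsids):
        raise ValueError("duplicate rsids in annotation file")
    return panel


def default_panel() -> list[SnpAnnotation]:
    """The shipped 17-SNP panel (placeholder weights and frequencies)."""
    with resources.as_file(
        resources.files("hba1c_mr.data").joinpath("default_panel.tsv")
    ) as path:
        return load_panel(path)


def panel_to_frame(panel: list[SnpAnnotation]) -> pd.DataFrame:
    rows = []
    for s in panel:
        rows.append(
            {
                "rsid": s.rsid,
                "locus": s.locus,
                "risk_allele": s.risk_allele,
                "weight": s.weight,
                "freq": s.freq,
                **{flag: int(getattr(s, flag)) for flag in _FLAG_COLUMNS},
                "note": s.note,
            }
        )
    return pd.DataFrame(rows)


def write_panel(panel: list[SnpAnnotation], path: str | Path) -> None:
    panel_to_frame(panel).to_csv(path, sep="\t", index=False)
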