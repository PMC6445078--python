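"""Report tables: quartile descriptives, estimator grids, forest-plot data.

Machine-readable outputs keep full float precision (display rounding is a
separate formatting step), so parsing a written grid recovers every estimate
exactly.  Significance stars follow the two-level convention: * for P < 0.05,
** for P < 0.01.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import cochran_armitage, trend_test_continuous
from .mr import MrResult
from .presso import PressoResult

__all__ = [
    "significance_stars",
    "quartile_table",
    "estimator_grid",
    "format_grid",
    "forest_data",
    "build_reports",
    "write_reports",
]


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def quartile_table(
    df: pd.DataFrame,
    quartile: np.ndarray,
    continuous: Sequence[str],
    binary: Sequence[str] = (),
) -> pd.DataFrame:
    """Mean +/- SD (or n (%)) per quartile with the trend p-value.

    Continuous traits use the linear trend over the quartile score; binary
    traits use the Cochran-Armitage trend chi-square.
    """
    quartile = np.asarray(quartile)
    rows = []
    for var in continuous:
        y = df[var].to_numpy(dtype=float)
        cells = {}
        for q in (1, 2, 3, 4):
            vals = y[(quartile == q) & np.isfinite(y)]
            cells[f"Q{q}"] = f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}" if vals.size else "NA"
        res = trend_test_continuous(y, quartile)
        rows.append({"variable": var, **cells, "p_trend": res.p,
                     "stars": significance_stars(res.p)})
    for var in binary:
        y = df[var].to_numpy(dtype=float)
        cases, totals = [], []
        cells = {}
        for q in (1, 2, 3, 4):
            sel = (quartile == q) & np.isfinite(y)
            cases.append(int(y[sel].sum()))
            totals.append(int(sel.sum()))
            pct = 100 * cases[-1] / totals[-1] if totals[-1] else float("nan")
            cells[f"Q{q}"] = f"{cases[-1]} ({pct:.1f})"
        _, p = cochran_armitage(cases, totals)
        rows.append({"variable": var, **cells, "p_trend": p,
                     "stars": significance_stars(p)})
    return pd.DataFrame(rows)


def estimator_grid(results: Sequence[tuple[str, str, MrResult]]) -> pd.DataFrame:
    """Tidy method x outcome x GRS grid from (grs, outcome, MrResult) triples."""
    rows = [
        {
            "grs": grs,
            "outcome": outcome,
            "method": res.method,
            "beta": res.beta,
            "se": res.se,
            "stat": res.stat,
            "p": res.p,
            "ci_low": res.ci95[0],
            "ci_high": res.ci95[1],
            "stars": significance_stars(res.p),
        }
        for grs, outcome, res in results
    ]
    columns = ["grs", "outcome", "method", "beta", "se", "stat", "p",
               "ci_low", "ci_high", "stars"]
    return pd.DataFrame(rows, columns=columns)


def format_grid(grid: pd.DataFrame) -> pd.DataFrame:
    """Display rounding: 2 decimals for beta/SE/stat, 2 significant figures for p."""
    out = grid.copy()
    for col in ("beta", "se", "stat", "ci_low", "ci_high"):
        out[col] = out[col].map(lambda v: f"{v:.2f}" if np.isfinite(v) else "NA.")
    out["p"] = out["p"].map(lambda v: f"{v:.2g}" if np.isfinite(v) else "NA.")
    return out


def forest_data(grid: pd.DataFrame, method: str = "grs_ratio") -> pd.DataFrame:
    """Forest-plot input: beta and 95% CI per outcome per GRS for one method."""
    sub = grid.loc[grid["method"] == method, ["grs", "outcome", "beta", "ci_low", "ci_high"]]
    return sub.reset_index(drop=True)


def build_reports(
    mr_results: Sequence[tuple[str, str, MrResult]],
    presso_results: Mapping[tuple[str, str], PressoResult] | None = None,
    quartiles: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the report tables; PRESSO labels must match the MR grid.

    Returns {"grid", "forest"} plus "quartiles" when supplied; the grid gains
    presso rows (global p carried in the ``p`` column, NA elsewhere).
    """
    grid = estimator_grid(mr_results)
    if presso_results:
        known = set(zip(grid["grs"], grid["outcome"]))
        rows = []
        for (grs, outcome), pres in presso_results.items():
            if known and (grs, outcome) not in known:
                raise ValueError(f"presso label ({grs!r}, {outcome!r}) not present in MR results")
            est = pres.reported_estimate
            rows.append({"grs": grs, "outcome": outcome, "method": "presso_mr",
                         "beta": est.beta, "se": est.se, "stat": est.stat, "p": est.p,
                         "ci_low": est.ci95[0], "ci_high": est.ci95[1],
                         "stars": significance_stars(est.p)})
            rows.append({"grs": grs, "outcome": outcome, "method": "presso_global",
                         "beta": float("nan"), "se": float("nan"), "stat": float("nan"),
                         "p": pres.global_p, "ci_low": float("nan"),
                         "ci_high": float("nan"), "stars": significance_stars(pres.global_p)})
        grid = pd.concat([grid, pd.DataFrame(rows, columns=grid.columns)], ignore_index=True)
    out = {"grid": grid, "forest": forest_data(grid)}
    if quartiles is not None:
        out["quartiles"] = quartiles
    return out


def write_reports(reports: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  manifest: Mapping | None = None) -> None:
    """Write each table as TSV (full precision) plus an optional run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, table in reports.items():
        # %.17g guarantees float64 round-trips when the table is re-parsed
        table.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                     float_format="%.17g")
    if manifest is not None:
        (out_dir / "run_manifest.json").write_text(json.dumps(dict(manifest), indent=2))
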