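"""End-to-end analysis drivers: cohort -> GRS -> associations -> MR estimates.

Glue used by the command-line interface and reproduction scripts; each step
is a thin call into the corresponding module, so everything here is also
reachable piecewise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import MODEL_COVARIATES, fit_model, make_summary_stats
from .grs import build_grs, select_conservative_set
from .mr import MrResult, grs_ratio_estimate, ivw, mr_egger, weighted_median
from .presso import PressoResult, mr_presso
from .simulate import GenotypeMatrix, OUTCOME_NAMES

__all__ = ["grs_mr_from_cohort", "summary_mr", "mr_table"]

OUTCOME_COLUMNS = {"log_tg": "log_tg", "tc": "tc", "ldl": "ldl", "hdl": "hdl"}


def grs_mr_from_cohort(
    g: GenotypeMatrix,
    df: pd.DataFrame,
    panel,
    subset="expanded",
    weighted: bool = True,
    model: int = 3,
    outcomes=OUTCOME_NAMES,
) -> dict[str, MrResult]:
    """GRS ratio causal estimates per outcome, per 1-SD exposure.

    The score (per its own SD) instruments the exposure standardized by its
    sample SD; the ratio of covariate-adjusted coefficients is the causal
    effect per 1-SD HbA1c with a delta-method SE.
    """
    scores = build_grs(g, panel, subset=subset, weighted=weighted)
    keep = scores.included
    sub = df.loc[keep].reset_index(drop=True)
    x = scores.per_sd()[keep]
    exposure_sd = sub["hba1c"].std(ddof=1)
    exposure_assoc = fit_model(
        sub.assign(hba1c_std=sub["hba1c"] / exposure_sd), "hba1c_std", x, model=model
    )
    results = {}
    for name in outcomes:
        outcome_assoc = fit_model(sub, OUTCOME_COLUMNS[name], x, model=model)
        results[name] = grs_ratio_estimate(exposure_assoc, outcome_assoc)
    return results


def summary_mr(
    ss: pd.DataFrame,
    methods=("ivw", "median", "egger", "presso"),
    seed: int = 0,
    n_boot: int = 1000,
    n_sim: int = 1000,
) -> dict[str, object]:
    """Run the sensitivity estimators on one summary-statistics table."""
    out: dict[str, object] = {}
    if "ivw" in methods:
        out["ivw"] = ivw(ss)
    if "median" in methods:
        out["weighted_median"] = weighted_median(ss, n_boot=n_boot, seed=seed)
    if "egger" in methods:
        slope, intercept = mr_egger(ss)
        out["egger_slope"] = slope
        out["egger_intercept"] = intercept
    if "presso" in methods:
        out["presso"] = mr_presso(ss, n_sim=n_sim, seed=seed)
    return out


def mr_table(results: dict[str, object]) -> pd.DataFrame:
    """Flatten a summary_mr result dict into a tidy frame."""
    rows = []
    for name, res in results.items():
        if isinstance(res, PressoResult):
            est = res.reported_estimate
            rows.append({"method": "presso_mr", "beta": est.beta, "se": est.se,
                         "stat": est.stat, "p": est.p})
            rows.append({"method": "presso_global", "beta": np.nan, "se": np.nan,
                         "stat": np.nan, "p": res.global_p})
        else:
            rows.append({"method": name, "beta": res.beta, "se": res.se,
                         "stat": res.stat, "p": res.p})
    return pd.DataFrame(rows, columns=["method", "beta", "se", "stat", "p"])
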