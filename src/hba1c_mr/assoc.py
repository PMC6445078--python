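"""Covariate-adjusted association models and screening statistics.

Provides the adjustment models used throughout the analysis (Model 1: age,
sex, BMI; Model 2 adds blood pressure and lifestyle; Model 3 adds diabetes),
per-SNP instrument-strength statistics feeding the summary-statistic MR
estimators, the Hardy-Weinberg chi-square screen, and the quartile trend
tests (linear for continuous traits, Cochran-Armitage for proportions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import GenotypeMatrix

__all__ = [
    "AssocResult",
    "MODEL_COVARIATES",
    "linear_assoc",
    "fit_model",
    "snp_trait_stats",
    "snp_exposure_stats",
    "make_summary_stats",
    "hwe_test",
    "genotype_counts",
    "trend_test_continuous",
    "cochran_armitage",
]

MODEL_COVARIATES = {
    1: ["age", "sex", "bmi"],
    2: ["age", "sex", "bmi", "sbp", "dbp", "smoking", "drinking", "physical_activity"],
    3: ["age", "sex", "bmi", "sbp", "dbp", "smoking", "drinking", "physical_activity", "diabetes"],
}


@dataclass
class AssocResult:
    """One covariate-adjusted association fit for a single predictor term."""

    beta: float
    se: float
    stat: float
    p: float
    n: int
    r2: float
    f_stat: float


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name the first column linearly dependent on its predecessors
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
            raise ValueError(f"design matrix is rank deficient at column {names[j]!r}")
    raise ValueError("design matrix is rank deficient")


def linear_assoc(y, x, covariates=None, per_sd: bool = False) -> AssocResult:
    """OLS of ``y`` on ``x`` plus covariates (listwise deletion).

    ``r2`` is the added-last variance share of ``x`` (increment in model R^2
    when ``x`` joins the covariates); ``f_stat`` is the squared t value of the
    ``x`` term.  With ``per_sd`` the predictor is divided by its sample SD so
    the coefficient is per SD of ``x``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if covariates is None:
        cov = np.empty((len(y), 0))
        cov_names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        cov_names = [str(c) for c in covariates.columns]
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov_names = [f"cov{j}" for j in range(cov.shape[1])]
    keep = np.isfinite(y) & np.isfinite(x) & np.isfinite(cov).all(axis=1)
    y, x, cov = y[keep], x[keep], cov[keep]
    n = len(y)
    k = 2 + cov.shape[1]
    if n <= k:
        raise ValueError(f"n = {n} too small for {k} parameters")
    if per_sd:
        sd = x.std(ddof=1)
        if not sd > 0:
            raise ValueError("cannot scale per SD: predictor has zero variance")
        x = x / sd
    X = np.column_stack([np.ones(n), x, cov])
    _check_full_rank(X, ["const", "x", *cov_names])
    fit = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, np.column_stack([np.ones(n), cov])).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    t = float(fit.tvalues[1])
    return AssocResult(
        beta=beta,
        se=se,
        stat=t,
        p=float(fit.pvalues[1]),
        n=n,
        r2=float(fit.rsquared - reduced.rsquared),
        f_stat=t * t,
    )


def fit_model(df: pd.DataFrame, outcome: str, predictor, model: int = 3,
              per_sd: bool = False) -> AssocResult:
    """Fit one of the numbered adjustment models on a cohort table.

    ``predictor`` is a column name or an aligned array (e.g. a GRS).
    """
    covs = df[MODEL_COVARIATES[model]]
    x = df[predictor] if isinstance(predictor, str) else predictor
    return linear_assoc(df[outcome], x, covariates=covs, per_sd=per_sd)


def _ols(y: np.ndarray, X: np.ndarray):
    """Minimal OLS: (beta, se, df_resid). X includes the intercept."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df_resid = len(y) - X.shape[1]
    sigma2 = resid @ resid / df_resid
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se, df_resid


def snp_trait_stats(g: GenotypeMatrix, trait, covariates=None) -> pd.DataFrame:
    """Per-SNP covariate-adjusted regression of a trait on risk-allele dosage.

    Returns one row per polymorphic SNP: beta, se, stat (t), p, f (= t^2), n.
    Monomorphic SNPs are flagged with a warning and skipped.
    """
    trait = np.asarray(trait, dtype=float)
    if covariates is None:
        cov = np.empty((len(trait), 0))
    else:
        cov = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        if cov.ndim == 1:
            cov = cov[:, None]
    base_keep = np.isfinite(trait) & np.isfinite(cov).all(axis=1)
    rows = []
    for j, rsid in enumerate(g.snp_order):
        keep = base_keep & ~g.missing_mask[:, j]
        x = g.dosages[keep, j].astype(float)
        if x.size == 0 or x.std() == 0:
            warnings.warn(f"SNP {rsid} is monomorphic in the analysis rows; skipped",
                          stacklevel=2)
            continue
        X = np.column_stack([np.ones(keep.sum()), x, cov[keep]])
        beta, se, df_resid = _ols(trait[keep], X)
        t = beta[1] / se[1]
        rows.append(
            {
                "rsid": rsid,
                "beta": beta[1],
                "se": se[1],
                "stat": t,
                "p": 2 * stats.t.sf(abs(t), df_resid),
                "f": t * t,
                "n": int(keep.sum()),
            }
        )
    return pd.DataFrame(rows)


def snp_exposure_stats(
    g: GenotypeMatrix, exposure, covariates=None, f_threshold: float = 10.0
) -> pd.DataFrame:
    """Gene-exposure statistics per SNP with the weak-instrument flag (F < threshold)."""
    df = snp_trait_stats(g, exposure, covariates)
    df["weak"] = df["f"] < f_threshold
    return df


def make_summary_stats(
    g: GenotypeMatrix, exposure, outcome, covariates=None
) -> pd.DataFrame:
    """Aligned per-SNP gene-exposure / gene-outcome summary statistics.

    Columns: rsid, bx, sx, by, sy, n.  All SNPs are oriented to the
    risk (exposure-increasing by annotation) allele.
    """
    ex = snp_trait_stats(g, exposure, covariates).rename(
        columns={"beta": "bx", "se": "sx"}
    )[["rsid", "bx", "sx", "n"]]
    out = snp_trait_stats(g, outcome, covariates).rename(
        columns={"beta": "by", "se": "sy"}
    )[["rsid", "by", "sy"]]
    return ex.merge(out, on="rsid", how="inner")[["rsid", "bx", "sx", "by", "sy", "n"]]


def genotype_counts(g: GenotypeMatrix, rsid: str) -> tuple[int, int, int]:
    """(n with 2, 1, 0 risk alleles) among non-missing individuals."""
    j = g.snp_order.index(rsid)
    d = g.dosages[~g.missing_mask[:, j], j]
    return int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())


def hwe_test(counts) -> tuple[float, float]:
    """1-df chi-square Hardy-Weinberg test on (n_AA, n_Aa, n_aa) counts."""
    n_aa_hom, n_het, n_bb_hom = (int(c) for c in counts)
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    total = n_aa_hom + n_het + n_bb_hom
    if total == 0:
        raise ValueError("zero total genotype count")
    p = (2 * n_aa_hom + n_het) / (2 * total)
    q = 1 - p
    if p == 0 or q == 0:
        return 0.0, 1.0
    expected = np.array([p * p, 2 * p * q, q * q]) * total
    observed = np.array([n_aa_hom, n_het, n_bb_hom], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, 1))


def trend_test_continuous(y, quartile) -> AssocResult:
    """Linear trend of a continuous trait over quartile labels 1-4 (label 0 excluded)."""
    y = np.asarray(y, dtype=float)
    q = np.asarray(quartile, dtype=float)
    keep = np.isfinite(y) & (q > 0)
    if len(np.unique(q[keep])) < 2:
        raise ValueError("trend test requires at least 2 occupied quartiles")
    return linear_assoc(y[keep], q[keep])


def cochran_armitage(cases, totals, scores=None) -> tuple[float, float]:
    """Cochran-Armitage 1-df trend chi-square for proportions over ordered groups.

    ``scores`` defaults to 0..k-1.  Degenerate tables (no cases or all cases)
    return statistic 0 with a warning.
    """
    r = np.asarray(cases, dtype=float)
    n = np.asarray(totals, dtype=float)
    if r.shape != n.shape or r.ndim != 1 or len(r) < 2:
        raise ValueError("cases and totals must be 1-D, same length >= 2")
    if (r > n).any() or (r < 0).any() or (n <= 0).any():
        raise ValueError("need 0 <= cases <= totals and totals > 0")
    s = np.arange(len(r), dtype=float) if scores is None else np.asarray(scores, dtype=float)
    N = n.sum()
    R = r.sum()
    if R == 0 or R == N:
        warnings.warn("degenerate trend table: all or no cases", stacklevel=2)
        return 0.0, 1.0
    pbar = R / N
    num = (s * (r - n * pbar)).sum() ** 2
    den = pbar * (1 - pbar) * ((n * s**2).sum() - (n * s).sum() ** 2 / N)
    if den <= 0:
        warnings.warn("degenerate trend scores", stacklevel=2)
        return 0.0, 1.0
    chi2 = float(num / den)
    return chi2, float(stats.chi2.sf(chi2, 1))
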