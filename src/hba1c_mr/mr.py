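"""Causal estimators for Mendelian randomization.

Implements the GRS ratio (Wald) estimator with delta-method standard error,
per-SNP Wald ratios, fixed-effect inverse-variance weighted (IVW) pooling with
Cochran's Q heterogeneity, the weighted median estimator with parametric
bootstrap SE, and MR-Egger regression with its intercept-based test of
directional pleiotropy.

Summary statistics are a DataFrame with columns ``rsid, bx, sx, by, sy`` (and
optionally ``n``): per-SNP gene-exposure and gene-outcome coefficients with
standard errors, all oriented to the exposure-increasing allele.  Estimator
classes follow the sklearn convention (``fit`` + trailing-underscore
attributes); module functions are thin wrappers returning :class:`MrResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .assoc import AssocResult

__all__ = [
    "MrResult",
    "validate_summary_stats",
    "grs_ratio_estimate",
    "wald_ratios",
    "ivw",
    "ivw_regression",
    "weighted_median",
    "mr_egger",
    "leave_one_out",
    "IVWEstimator",
    "WeightedMedianEstimator",
    "MREggerEstimator",
]


@dataclass
class MrResult:
    """One causal estimate: method tag, effect, SE, test statistic and p-value."""

    method: str
    beta: float
    se: float
    stat: float
    p: float
    ci95: tuple[float, float]
    extras: dict = field(default_factory=dict)


def _z_result(method: str, beta: float, se: float, extras: dict | None = None) -> MrResult:
    z = beta / se
    return MrResult(
        method=method,
        beta=float(beta),
        se=float(se),
        stat=float(z),
        p=float(2 * stats.norm.sf(abs(z))),
        ci95=(float(beta - 1.96 * se), float(beta + 1.96 * se)),
        extras=extras or {},
    )


def validate_summary_stats(ss: pd.DataFrame, min_snps: int = 1) -> pd.DataFrame:
    for col in ("rsid", "bx", "sx", "by", "sy"):
        if col not in ss.columns:
            raise ValueError(f"summary statistics missing column {col!r}")
    if len(ss) < min_snps:
        raise ValueError(f"need at least {min_snps} SNPs, got {len(ss)}")
    if (ss["sx"] <= 0).any() or (ss["sy"] <= 0).any():
        raise ValueError("standard errors must be positive")
    return ss


def grs_ratio_estimate(
    exposure_assoc: AssocResult, outcome_assoc: AssocResult, tol: float = 1e-10
) -> MrResult:
    """Ratio (Wald) causal estimate beta_GY / beta_GX with delta-method SE.

    SE = sqrt(se_GY^2/beta_GX^2 + beta_GY^2 * se_GX^2 / beta_GX^4); two-sided
    normal p.  Both fits must come from the same rows, model and GRS scaling.
    """
    bx, sx = exposure_assoc.beta, exposure_assoc.se
    by, sy = outcome_assoc.beta, outcome_assoc.se
    if abs(bx) < tol:
        raise ValueError("weak-instrument degenerate: |gene-exposure beta| below tolerance")
    beta = by / bx
    se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return _z_result(
        "grs_ratio", beta, se,
        extras={"f_stat": exposure_assoc.f_stat, "n": exposure_assoc.n},
    )


def _ratio_arrays(ss: pd.DataFrame, order: int = 1):
    bx = ss["bx"].to_numpy(dtype=float)
    by = ss["by"].to_numpy(dtype=float)
    sy = ss["sy"].to_numpy(dtype=float)
    theta = by / bx
    se = np.abs(sy / bx)
    if order == 2:
        sx = ss["sx"].to_numpy(dtype=float)
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return theta, se


def wald_ratios(ss: pd.DataFrame, order: int = 1) -> list[MrResult]:
    """Per-SNP Wald ratios.  ``order=1`` uses first-order SEs (sy/|bx|),
    matching the fixed-effect IVW weighting; ``order=2`` adds the
    gene-exposure uncertainty term.  SNPs with bx = 0 are dropped."""
    validate_summary_stats(ss)
    keep = ss["bx"] != 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} SNP(s) with zero gene-exposure beta",
            stacklevel=2,
        )
    ss = ss.loc[keep]
    theta, se = _ratio_arrays(ss, order=order)
    return [
        _z_result("wald", t, s, extras={"rsid": r})
        for r, t, s in zip(ss["rsid"], theta, se)
    ]


class _SummaryEstimator(BaseEstimator):
    """Shared fit plumbing for summary-statistic MR estimators."""

    _min_snps = 1

    def fit(self, X: pd.DataFrame, y=None):
        ss = validate_summary_stats(X, min_snps=self._min_snps)
        ss = ss.loc[ss["bx"] != 0]
        if len(ss) < self._min_snps:
            raise ValueError(f"need at least {self._min_snps} SNPs with nonzero bx")
        self.n_snps_ = len(ss)
        self._fit(ss)
        self.result_ = self._result()
        self.beta_ = self.result_.beta
        self.se_ = self.result_.se
        self.stat_ = self.result_.stat
        self.pvalue_ = self.result_.p
        self.ci95_ = self.result_.ci95
        return self


class IVWEstimator(_SummaryEstimator):
    """Fixed-effect inverse-variance weighted pooling of Wald ratios.

    Weights are 1/se(theta_j)^2 with first-order ratio SEs, algebraically
    identical to a zero-intercept regression of by on bx weighted by 1/sy^2.
    ``random_effects`` switches to the multiplicative random-effects SE
    (inflated by sqrt(Q/df) when Q/df > 1).
    """

    def __init__(self, random_effects: bool = False):
        self.random_effects = random_effects

    def _fit(self, ss: pd.DataFrame) -> None:
        theta, se = _ratio_arrays(ss, order=1)
        w = 1.0 / se**2
        beta = float(np.sum(w * theta) / np.sum(w))
        pooled_se = float(1.0 / np.sqrt(np.sum(w)))
        q = float(np.sum(w * (theta - beta) ** 2))
        q_df = len(theta) - 1
        q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else float("nan")
        if self.random_effects and q_df > 0 and q / q_df > 1:
            pooled_se *= float(np.sqrt(q / q_df))
        self.Q_ = q
        self.Q_df_ = q_df
        self.Q_pvalue_ = q_p
        self._beta, self._se = beta, pooled_se

    def _result(self) -> MrResult:
        return _z_result(
            "ivw", self._beta, self._se,
            extras={"Q": self.Q_, "Q_df": self.Q_df_, "Q_p": self.Q_pvalue_,
                    "n_snps": self.n_snps_},
        )


class WeightedMedianEstimator(_SummaryEstimator):
    """Weighted median of ordered Wald ratios, parametric-bootstrap SE.

    The estimate interpolates the ordered ratios at the 50% point of the
    normalized inverse-variance weights (cumulative-midpoint convention); it
    stays consistent while under half of the weight comes from invalid
    instruments.  The SE resamples bx ~ N(bx, sx), by ~ N(by, sy) and takes
    the SD of the recomputed estimate over ``n_boot`` replicates.
    """

    _min_snps = 3

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    @staticmethod
    def _point(theta: np.ndarray, w: np.ndarray) -> float:
        order = np.argsort(theta, kind="stable")
        theta, w = theta[order], w[order]
        w = w / w.sum()
        p = np.cumsum(w) - w / 2
        return float(np.interp(0.5, p, theta))

    def _fit(self, ss: pd.DataFrame) -> None:
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        theta, se = _ratio_arrays(ss, order=1)
        w = 1.0 / se**2
        beta = self._point(theta, w)
        rng = np.random.default_rng(self.seed)
        bx = ss["bx"].to_numpy(dtype=float)
        sx = ss["sx"].to_numpy(dtype=float)
        by = ss["by"].to_numpy(dtype=float)
        sy = ss["sy"].to_numpy(dtype=float)
        bx_star = rng.normal(bx, sx, size=(self.n_boot, len(bx)))
        by_star = rng.normal(by, sy, size=(self.n_boot, len(by)))
        with np.errstate(divide="ignore", invalid="ignore"):
            theta_star = by_star / bx_star
            w_star = (bx_star / sy) ** 2
        boots = np.array(
            [self._point(t, wt) for t, wt in zip(theta_star, w_star)]
        )
        self._beta = beta
        self._se = float(boots.std(ddof=1))

    def _result(self) -> MrResult:
        return _z_result(
            "weighted_median", self._beta, self._se,
            extras={"n_snps": self.n_snps_, "bootstrap_reps": self.n_boot,
                    "seed": self.seed},
        )


class MREggerEstimator(_SummaryEstimator):
    """MR-Egger: weighted regression of by on bx with a free intercept.

    SNPs are pre-oriented so bx > 0; weights are 1/sy^2.  The slope is the
    causal estimate and the intercept the average directional pleiotropy.
    Standard errors use the multiplicative random-effects convention (residual
    variance factor floored at 1); inference is t on J - 2 df.
    """

    _min_snps = 3

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def _fit(self, ss: pd.DataFrame) -> None:
        bx = ss["bx"].to_numpy(dtype=float)
        by = ss["by"].to_numpy(dtype=float)
        sy = ss["sy"].to_numpy(dtype=float)
        flip = np.sign(bx)
        bx, by = bx * flip, by * flip
        if np.allclose(bx, bx[0]):
            raise ValueError("slope unidentified: no spread in gene-exposure betas")
        w = 1.0 / sy**2
        X = np.column_stack([np.ones_like(bx), bx]) if self.fit_intercept else bx[:, None]
        WX = X * w[:, None]
        xtwx = X.T @ WX
        coef = np.linalg.solve(xtwx, WX.T @ by)
        resid = by - X @ coef
        df_resid = len(bx) - X.shape[1]
        sigma2 = float(w @ resid**2 / df_resid) if df_resid > 0 else 0.0
        infl = max(1.0, sigma2)
        cov = infl * np.linalg.inv(xtwx)
        se = np.sqrt(np.diag(cov))
        self._df_resid = df_resid
        self._sigma2 = sigma2
        if self.fit_intercept:
            self._intercept, self._beta = coef
            self._intercept_se, self._se = se
        else:
            self._intercept, self._intercept_se = 0.0, float("nan")
            self._beta, self._se = coef[0], se[0]

    def _t_result(self, method, beta, se) -> MrResult:
        t = beta / se
        tq = stats.t.ppf(0.975, self._df_resid) if self._df_resid > 0 else float("nan")
        return MrResult(
            method=method,
            beta=float(beta),
            se=float(se),
            stat=float(t),
            p=float(2 * stats.t.sf(abs(t), self._df_resid)),
            ci95=(float(beta - tq * se), float(beta + tq * se)),
            extras={"n_snps": self.n_snps_, "df": self._df_resid,
                    "residual_variance_factor": max(1.0, self._sigma2)},
        )

    def _result(self) -> MrResult:
        self.intercept_ = float(self._intercept)
        self.intercept_se_ = float(self._intercept_se)
        if self.fit_intercept:
            self.intercept_result_ = self._t_result(
                "egger_intercept", self._intercept, self._intercept_se
            )
        return self._t_result("egger_slope", self._beta, self._se)


def ivw(ss: pd.DataFrame, random_effects: bool = False) -> MrResult:
    """Fixed-effect IVW estimate (see :class:`IVWEstimator`)."""
    return IVWEstimator(random_effects=random_effects).fit(ss).result_


def ivw_regression(ss: pd.DataFrame) -> MrResult:
    """IVW in its zero-intercept weighted-regression form (weights 1/sy^2).

    Algebraically identical to :func:`ivw` with first-order weights; kept as a
    separate code path for the equivalence checks.
    """
    validate_summary_stats(ss)
    bx = ss["bx"].to_numpy(dtype=float)
    by = ss["by"].to_numpy(dtype=float)
    sy = ss["sy"].to_numpy(dtype=float)
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    beta = float(np.sum(w * bx * by) / denom)
    se = float(1.0 / np.sqrt(denom))
    return _z_result("ivw_regression", beta, se, extras={"n_snps": len(ss)})


def weighted_median(ss: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MrResult:
    return WeightedMedianEstimator(n_boot=n_boot, seed=seed).fit(ss).result_


def mr_egger(ss: pd.DataFrame, fit_intercept: bool = True):
    """(slope MrResult, intercept MrResult or None) from MR-Egger regression."""
    est = MREggerEstimator(fit_intercept=fit_intercept).fit(ss)
    return est.result_, (est.intercept_result_ if fit_intercept else None)


def leave_one_out(ss: pd.DataFrame, random_effects: bool = False) -> pd.DataFrame:
    """IVW excluding each SNP in turn; columns rsid, beta, se."""
    validate_summary_stats(ss, min_snps=2)
    rows = []
    for rsid in ss["rsid"]:
        sub = ss.loc[ss["rsid"] != rsid]
        res = ivw(sub, random_effects=random_effects)
        rows.append({"rsid": rsid, "beta": res.beta, "se": res.se})
    return pd.DataFrame(rows)
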