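"""Simulation-based horizontal-pleiotropy diagnostics (MR-PRESSO style).

Three connected tests on per-SNP summary statistics:

* **global test** — the observed weighted residual sum of squares around
  leave-one-out IVW expectations is compared with its parametric-simulation
  null distribution;
* **outlier test** — each SNP's weighted squared residual is compared with its
  own simulated distribution, with Bonferroni (or FDR) multiplicity control;
* **distortion test** — the percent change of the causal estimate after
  removing flagged outliers is compared with the change from removing the same
  number of random SNPs.

All Monte-Carlo p-values use the add-one rule and are reproducible given the
seed.  Raw and corrected causal estimates use the inverse-variance weighted
regression with t statistics on J - 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .mr import MrResult, validate_summary_stats

__all__ = ["PressoResult", "MRPressoEstimator", "mr_presso",
           "presso_global", "presso_outlier", "presso_distortion"]


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outliers: pd.DataFrame
    raw_estimate: MrResult
    corrected_estimate: MrResult | None
    distortion_stat: float | None
    distortion_p: float | None
    n_sim: int
    seed: int
    outlier_pvalues: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def reported_estimate(self) -> MrResult:
        """Corrected estimate when outliers were detected, else the raw one."""
        return self.corrected_estimate if self.corrected_estimate is not None else self.raw_estimate


def _arrays(ss: pd.DataFrame):
    return (
        ss["bx"].to_numpy(dtype=float),
        ss["sx"].to_numpy(dtype=float),
        ss["by"].to_numpy(dtype=float),
        ss["sy"].to_numpy(dtype=float),
    )


def _loo_betas(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW (regression form, weights 1/sy^2) per SNP, O(J)."""
    w = 1.0 / sy**2
    num = w * bx * by
    den = w * bx**2
    return (num.sum() - num) / (den.sum() - den)


def _loo_betas_matrix(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Row-wise leave-one-out IVW for an (n_sim, J) stack of replicates."""
    w = 1.0 / sy**2
    num = w * bx * by
    den = w * bx**2
    return (num.sum(axis=1, keepdims=True) - num) / (den.sum(axis=1, keepdims=True) - den)


def _wls_estimate(bx, by, sy, method: str) -> MrResult:
    """Weighted no-intercept regression with residual-variance-scaled SE, t on J-1 df."""
    w = 1.0 / np.asarray(sy, dtype=float) ** 2
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    den = np.sum(w * bx**2)
    beta = float(np.sum(w * bx * by) / den)
    df_resid = len(bx) - 1
    sigma2 = float(np.sum(w * (by - beta * bx) ** 2) / df_resid)
    se = float(np.sqrt(sigma2 / den))
    t = beta / se
    tq = stats.t.ppf(0.975, df_resid)
    return MrResult(
        method=method, beta=beta, se=se, stat=float(t),
        p=float(2 * stats.t.sf(abs(t), df_resid)),
        ci95=(beta - tq * se, beta + tq * se),
        extras={"df": df_resid, "n_snps": len(bx)},
    )


def _simulate_residuals(ss: pd.DataFrame, n_sim: int, rng: np.random.Generator,
                        perturb_bx: bool = True):
    """Observed and simulated per-SNP weighted squared residuals.

    Returns (obs (J,), sim (n_sim, J)).  Residuals are taken around
    leave-one-out IVW expectations; replicates redraw by (and optionally bx)
    from their sampling distributions under the no-pleiotropy model.
    """
    bx, sx, by, sy = _arrays(ss)
    w = 1.0 / sy**2
    loo = _loo_betas(bx, by, sy)
    obs = w * (by - loo * bx) ** 2
    expected_by = loo * bx
    by_star = rng.normal(expected_by, sy, size=(n_sim, len(bx)))
    bx_star = rng.normal(bx, sx, size=(n_sim, len(bx))) if perturb_bx else np.broadcast_to(
        bx, (n_sim, len(bx))
    )
    loo_star = _loo_betas_matrix(bx_star, by_star, sy)
    sim = w * (by_star - loo_star * bx_star) ** 2
    return obs, sim


def _mc_p(count_geq: int, n_sim: int) -> float:
    return (1 + count_geq) / (n_sim + 1)


class MRPressoEstimator(BaseEstimator):
    """Run the global, outlier and distortion tests on summary statistics.

    Parameters
    ----------
    n_sim : int
        Monte-Carlo replicates (>= 100); p-value granularity is 1/(n_sim+1).
    seed : int
        Seed for every random draw.
    alpha : float
        Family-wise significance level of the outlier test.
    perturb_bx : bool
        Redraw gene-exposure betas in replicates (full parametric scheme);
        False perturbs by only (faster, slightly anti-conservative).
    multiplicity : "bonferroni" | "fdr"
        Multiplicity control for per-SNP outlier p-values.
    """

    _min_snps = 4

    def __init__(self, n_sim: int = 1000, seed: int = 0, alpha: float = 0.05,
                 perturb_bx: bool = True, multiplicity: str = "bonferroni"):
        self.n_sim = n_sim
        self.seed = seed
        self.alpha = alpha
        self.perturb_bx = perturb_bx
        self.multiplicity = multiplicity

    def fit(self, X: pd.DataFrame, y=None):
        ss = validate_summary_stats(X, min_snps=self._min_snps)
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        if self.multiplicity not in ("bonferroni", "fdr"):
            raise ValueError(f"unknown multiplicity control {self.multiplicity!r}")
        rng = np.random.default_rng(self.seed)
        J = len(ss)
        obs, sim = _simulate_residuals(ss, self.n_sim, rng, self.perturb_bx)

        rss_obs = float(obs.sum())
        rss_sim = sim.sum(axis=1)
        global_p = _mc_p(int((rss_sim >= rss_obs).sum()), self.n_sim)

        p_raw = np.array(
            [_mc_p(int((sim[:, j] >= obs[j]).sum()), self.n_sim) for j in range(J)]
        )
        if self.multiplicity == "bonferroni":
            p_adj = np.minimum(1.0, p_raw * J)
        else:
            p_adj = _fdr(p_raw)
        pvals = pd.DataFrame({"rsid": ss["rsid"].to_numpy(), "p": p_raw, "p_adj": p_adj})
        outliers = pvals.loc[p_adj <= self.alpha].reset_index(drop=True)

        bx, sx, by, sy = _arrays(ss)
        raw = _wls_estimate(bx, by, sy, "presso_raw")

        corrected = None
        distortion_stat = None
        distortion_p = None
        is_out = ss["rsid"].isin(outliers["rsid"]).to_numpy()
        if len(outliers) and not is_out.all():
            # all-flagged tables leave the corrected estimate undefined
            keep = ~is_out
            corrected = _wls_estimate(bx[keep], by[keep], sy[keep], "presso_corrected")
            distortion_stat = float(100.0 * (raw.beta - corrected.beta) / abs(corrected.beta))
            k = int(is_out.sum())
            idx_keep = np.flatnonzero(keep)
            if len(idx_keep) > k:  # else: distortion null undefined, p stays absent
                d_null = np.empty(self.n_sim)
                for i in range(self.n_sim):
                    drop = rng.choice(idx_keep, size=k, replace=False)
                    m = np.ones(J, dtype=bool)
                    m[drop] = False
                    b_star = _wls_estimate(bx[m], by[m], sy[m], "tmp").beta
                    d_null[i] = 100.0 * (raw.beta - b_star) / abs(b_star)
                distortion_p = _mc_p(
                    int((np.abs(d_null) >= abs(distortion_stat)).sum()), self.n_sim
                )

        self.result_ = PressoResult(
            global_rss=rss_obs,
            global_p=global_p,
            outliers=outliers,
            raw_estimate=raw,
            corrected_estimate=corrected,
            distortion_stat=distortion_stat,
            distortion_p=distortion_p,
            n_sim=self.n_sim,
            seed=self.seed,
            outlier_pvalues=pvals,
        )
        self.global_rss_ = rss_obs
        self.global_pvalue_ = global_p
        self.outliers_ = outliers
        self.beta_ = self.result_.reported_estimate.beta
        self.se_ = self.result_.reported_estimate.se
        self.pvalue_ = self.result_.reported_estimate.p
        return self


def _fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def mr_presso(ss: pd.DataFrame, n_sim: int = 1000, seed: int = 0, alpha: float = 0.05,
              perturb_bx: bool = True, multiplicity: str = "bonferroni") -> PressoResult:
    """Full global + outlier + distortion analysis; see :class:`MRPressoEstimator`."""
    est = MRPressoEstimator(n_sim=n_sim, seed=seed, alpha=alpha,
                            perturb_bx=perturb_bx, multiplicity=multiplicity)
    return est.fit(ss).result_


def presso_global(ss: pd.DataFrame, n_sim: int = 1000, seed: int = 0,
                  perturb_bx: bool = True) -> PressoResult:
    """Global test only (outlier fields still populated at alpha = 0)."""
    return mr_presso(ss, n_sim=n_sim, seed=seed, alpha=0.0, perturb_bx=perturb_bx)


def presso_outlier(ss: pd.DataFrame, n_sim: int = 1000, seed: int = 0,
                   alpha: float = 0.05, perturb_bx: bool = True,
                   multiplicity: str = "bonferroni") -> pd.DataFrame:
    """Flagged outliers (rsid, p, p_adj) at family-wise level ``alpha``."""
    return mr_presso(ss, n_sim=n_sim, seed=seed, alpha=alpha,
                     perturb_bx=perturb_bx, multiplicity=multiplicity).outliers


def presso_distortion(ss: pd.DataFrame, outliers, n_sim: int = 1000, seed: int = 0):
    """Distortion test for a given outlier list.

    Returns (distortion_stat percent, distortion_p, corrected MrResult).
    """
    ss = validate_summary_stats(ss, min_snps=2)
    outliers = list(outliers)
    if not outliers:
        raise ValueError("distortion test requires a non-empty outlier list")
    is_out = ss["rsid"].isin(outliers).to_numpy()
    if is_out.all():
        raise ValueError("all SNPs flagged as outliers; corrected estimate undefined")
    bx, sx, by, sy = _arrays(ss)
    raw = _wls_estimate(bx, by, sy, "presso_raw")
    keep = ~is_out
    corrected = _wls_estimate(bx[keep], by[keep], sy[keep], "presso_corrected")
    stat = float(100.0 * (raw.beta - corrected.beta) / abs(corrected.beta))
    rng = np.random.default_rng(seed)
    idx_keep = np.flatnonzero(keep)
    k = int(is_out.sum())
    if len(idx_keep) <= k:
        raise ValueError("too few non-outlier SNPs for the distortion null")
    d_null = np.empty(n_sim)
    J = len(ss)
    for i in range(n_sim):
        drop = rng.choice(idx_keep, size=k, replace=False)
        m = np.ones(J, dtype=bool)
        m[drop] = False
        b_star = _wls_estimate(bx[m], by[m], sy[m], "tmp").beta
        d_null[i] = 100.0 * (raw.beta - b_star) / abs(b_star)
    p = _mc_p(int((np.abs(d_null) >= abs(stat)).sum()), n_sim)
    return stat, p, corrected
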