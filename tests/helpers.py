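"""Independent oracles and shared simulation drivers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from hba1c_mr import SimulationConfig, default_panel
from hba1c_mr.assoc import make_summary_stats


def residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    return v - C @ np.linalg.lstsq(C, v, rcond=None)[0]


def tsls_beta(y, x, z, covariates=None) -> float:
    """Just-identified two-stage least squares (single instrument) oracle.

    Residualizes y, x and z on [1, covariates] and returns (z~.y~)/(z~.x~),
    the textbook IV estimate; independent of the package's ratio code path.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(y)
    C = np.ones((n, 1))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        C = np.column_stack([C, cov])
    yr, xr, zr = residualize(y, C), residualize(x, C), residualize(z, C)
    return float(zr @ yr / (zr @ xr))


def ca_chi2_vectorized(r: np.ndarray, n: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Cochran-Armitage statistic for a stack of case-count rows (oracle copy)."""
    N = n.sum()
    R = r.sum(axis=-1, keepdims=True)
    pbar = R / N
    num = (s * (r - n * pbar)).sum(axis=-1) ** 2
    den = (pbar[..., 0] * (1 - pbar[..., 0])) * ((n * s**2).sum() - (n * s).sum() ** 2 / N)
    return num / den


def ca_permutation_p(cases, totals, scores, n_perm: int = 20_000, seed: int = 0):
    """Monte-Carlo permutation p-value for the trend statistic.

    Shuffles the pooled case labels over individuals and recomputes the
    statistic; returns (p, monte-carlo SE).
    """
    rng = np.random.default_rng(seed)
    r = np.asarray(cases, dtype=float)
    n = np.asarray(totals, dtype=int)
    s = np.asarray(scores, dtype=float)
    obs = float(ca_chi2_vectorized(r, n.astype(float), s))
    labels = np.zeros(int(n.sum()), dtype=np.int8)
    labels[: int(r.sum())] = 1
    edges = np.concatenate([[0], np.cumsum(n)])
    perms = np.tile(labels, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    r_perm = np.stack(
        [perms[:, edges[i]: edges[i + 1]].sum(axis=1) for i in range(len(n))], axis=1
    ).astype(float)
    stats_perm = ca_chi2_vectorized(r_perm, n.astype(float), s)
    p = float((stats_perm >= obs - 1e-12).mean())
    se = float(np.sqrt(p * (1 - p) / n_perm))
    return p, se


def recovery_config(seed: int, n: int = 2000, beta: float = 0.3,
                    pleiotropy: dict | None = None) -> SimulationConfig:
    """Study conditions for estimator-recovery experiments.

    Exposure SD is set to 1 so the causal effect per exposure unit equals the
    effect per SD; the generic outcome is TC with unit total SD.
    """
    cfg = SimulationConfig(
        n_individuals=n,
        seed=seed,
        missing_rate=0.0,
        causal_effects={"tc": beta},
        exposure_sd=1.0,
        pleiotropy=pleiotropy or {},
    )
    cfg.outcome_sds = {**cfg.outcome_sds, "tc": 1.0}
    return cfg


def cohort_summary_stats(g, df, outcome: str = "tc") -> pd.DataFrame:
    return make_summary_stats(g, df["hba1c"], df[outcome])


def directional_pleiotropy_map(alpha: float = 0.06, n_invalid: int = 7) -> dict:
    """Constant per-allele direct effects on TC for ~40% of the panel.

    The invalid subset is chosen (exhaustively over all subsets) to minimize
    the weighted covariance between pleiotropy status and instrument strength,
    so the InSIDE condition holds by construction and the directional shift
    loads on the regression intercept rather than the slope.
    """
    from itertools import combinations

    panel = default_panel()
    w = np.array([s.weight for s in panel])
    freq = np.array([s.freq for s in panel])
    var_d = 2 * freq * (1 - freq)
    bx = w  # instrument strength proportional to the weight
    wt = var_d  # outcome-side precision weights 1/sy^2 proportional to 2pq
    best, best_cov = None, np.inf
    for subset in combinations(range(len(panel)), n_invalid):
        ind = np.zeros(len(panel))
        ind[list(subset)] = 1.0
        wbar = wt / wt.sum()
        cov = np.sum(wbar * ind * bx) - np.sum(wbar * ind) * np.sum(wbar * bx)
        if abs(cov) < best_cov:
            best, best_cov = subset, abs(cov)
    return {panel[i].rsid: {"tc": alpha} for i in best}


def two_sample_summary_base(beta: float = 0.3, n_outcome: int = 11_473,
                            n_discovery: int = 150_000) -> pd.DataFrame:
    """Expected summary statistics implied by the default panel.

    Gene-exposure effects come from the generator's scaling at instrument
    R^2 = 0.03 (exposure SD 1); SEs follow the usual 1/sqrt(n * 2pq)
    approximation with a large discovery sample on the exposure side and the
    emulated cohort size on the outcome side (outcome SD 1).
    """
    panel = default_panel()
    w = np.array([s.weight for s in panel])
    freq = np.array([s.freq for s in panel])
    var_d = 2 * freq * (1 - freq)
    lam = np.sqrt(0.03 / np.sum(w**2 * var_d))
    bx = lam * w
    return pd.DataFrame(
        {
            "rsid": [s.rsid for s in panel],
            "bx": bx,
            "sx": 1.0 / np.sqrt(n_discovery * var_d),
            "by": beta * bx,
            "sy": 1.0 / np.sqrt(n_outcome * var_d),
        }
    )


def draw_summary_stats(base: pd.DataFrame, rng: np.random.Generator,
                       by_shift: np.ndarray | None = None) -> pd.DataFrame:
    """Sample observed summary statistics around a truth table."""
    out = base.copy()
    out["bx"] = rng.normal(base["bx"], base["sx"])
    by_mean = base["by"].to_numpy() + (by_shift if by_shift is not None else 0.0)
    out["by"] = rng.normal(by_mean, base["sy"])
    return out
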