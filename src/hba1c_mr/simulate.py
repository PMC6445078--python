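"""Synthetic genotype-phenotype cohort generator.

Generates cohorts with the statistical structure the Mendelian-randomization
analysis assumes: independent biallelic SNPs at configurable risk-allele
frequencies (Hardy-Weinberg proportions, optionally distorted by an
inbreeding-style coefficient), an exposure (HbA1c, percent units) whose
weighted genetic component explains a target share of variance, and lipid
outcomes driven by a configurable causal effect of the standardized exposure
plus shared confounders, optional per-SNP pleiotropic leakage, and Gaussian
noise.  Triglycerides are generated on the log scale and exponentiated, so the
downstream log transform is exercised.

Every draw is controlled by a single integer seed; the generator returns a
truth record carrying the rescaled per-allele effects and causal parameters so
recovery tests can compare estimates against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import SnpAnnotation, default_panel

__all__ = [
    "GenotypeMatrix",
    "SimulationConfig",
    "simulate_genotypes",
    "apply_missingness",
    "simulate_cohort",
    "compute_homa",
    "add_derived_columns",
    "OUTCOME_NAMES",
]

OUTCOME_NAMES = ("log_tg", "tc", "ldl", "hdl")

#: Population parameters used to generate (and standardize) shared covariates:
#: name -> (mean, sd).  Binary covariates carry their Bernoulli rate as mean.
COVARIATE_PARAMS: dict[str, tuple[float, float]] = {
    "age": (63.2, 9.8),
    "bmi": (25.16, 3.37),
    "sex": (0.3554, float(np.sqrt(0.3554 * (1 - 0.3554)))),
    "sbp": (137.0, 20.0),
    "dbp": (77.0, 10.0),
    "smoking": (0.25, float(np.sqrt(0.25 * 0.75))),
    "drinking": (0.15, float(np.sqrt(0.15 * 0.85))),
    "physical_activity": (0.40, float(np.sqrt(0.40 * 0.60))),
}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class GenotypeMatrix:
    """n x J risk-allele dosage table with a missingness mask.

    ``dosages`` holds the drawn dosage even under the mask (masked entries are
    flagged, not altered), so ground-truth scores remain computable in tests.
    """

    dosages: np.ndarray
    missing_mask: np.ndarray
    snp_order: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        if self.dosages.shape != self.missing_mask.shape:
            raise ValueError("dosages and missing_mask shapes differ")
        if len(self.snp_order) != self.dosages.shape[1]:
            raise ValueError("snp_order length does not match number of columns")
        if len(set(self.snp_order)) != len(self.snp_order):
            raise ValueError("snp_order contains duplicate rsids")
        observed = self.dosages[~self.missing_mask]
        if observed.size and not np.isin(observed, (0, 1, 2)).all():
            raise ValueError("observed dosages must be 0, 1 or 2")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def column(self, rsid: str) -> np.ndarray:
        j = self.snp_order.index(rsid)
        return self.dosages[:, j]

    def to_frame(self, ids: Sequence | None = None) -> pd.DataFrame:
        """PLINK .raw-style additive table; masked entries become NA."""
        values = self.dosages.astype(float)
        values[self.missing_mask] = np.nan
        df = pd.DataFrame(values, columns=self.snp_order)
        df.insert(0, "id", ids if ids is not None else np.arange(self.n))
        return df


def _genotype_probs(freq: float, f: float) -> tuple[float, float, float]:
    """(P0, P1, P2) for risk-allele dosage under inbreeding coefficient f."""
    p, q = freq, 1.0 - freq
    p0 = q * q + f * p * q
    p1 = 2 * p * q * (1 - f)
    p2 = p * p + f * p * q
    if min(p0, p1, p2) < -1e-12:
        raise ValueError(f"HWE distortion coefficient {f} gives negative genotype probability")
    return max(p0, 0.0), max(p1, 0.0), max(p2, 0.0)


def simulate_genotypes(
    panel: Sequence[SnpAnnotation],
    n: int,
    hwe_violation: Mapping[str, float] | None = None,
    seed=0,
) -> GenotypeMatrix:
    """Draw independent per-SNP dosages.

    Under no violation, genotype counts follow Hardy-Weinberg proportions in
    expectation; a violation coefficient ``f`` for a SNP deflates the
    heterozygote probability by (1 - f), preserving the allele frequency.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    hwe_violation = dict(hwe_violation or {})
    rsids = [s.rsid for s in panel]
    unknown = set(hwe_violation) - set(rsids)
    if unknown:
        raise ValueError(f"hwe_violation names SNPs not in panel: {sorted(unknown)}")
    rng = _rng(seed)
    c0 = np.empty(len(panel))
    c1 = np.empty(len(panel))
    for j, snp in enumerate(panel):
        p0, p1, _ = _genotype_probs(snp.freq, hwe_violation.get(snp.rsid, 0.0))
        c0[j] = p0
        c1[j] = p0 + p1
    u = rng.random((n, len(panel)))
    dosages = (u >= c0).astype(np.int8) + (u >= c1).astype(np.int8)
    mask = np.zeros_like(dosages, dtype=bool)
    return GenotypeMatrix(dosages, mask, rsids)


def apply_missingness(g: GenotypeMatrix, missing_rate: float, seed=0) -> GenotypeMatrix:
    """Mask each dosage independently with probability ``missing_rate``.

    Masked values are flagged, not altered; the returned matrix is new.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError(f"missing_rate must lie in [0, 1), got {missing_rate}")
    rng = _rng(seed)
    new_mask = g.missing_mask | (rng.random(g.dosages.shape) < missing_rate)
    return GenotypeMatrix(g.dosages.copy(), new_mask, list(g.snp_order))


def compute_homa(fins, fpg):
    """Homeostasis-model indices from fasting insulin (mIU/L) and FPG (mmol/L).

    HOMA-beta = 20 * fins / (fpg - 3.5), undefined (NaN) where fpg <= 3.5;
    HOMA-IR = fins * fpg / 22.5.
    """
    fins = np.asarray(fins, dtype=float)
    fpg = np.asarray(fpg, dtype=float)
    if (fins <= 0).any() or (fpg <= 0).any():
        raise ValueError("fins and fpg must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        homa_beta = np.where(fpg > 3.5, 20.0 * fins / (fpg - 3.5), np.nan)
    homa_ir = fins * fpg / 22.5
    return homa_beta, homa_ir


def add_derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute log-TG, HOMA indices and their logs from raw columns."""
    df = df.copy()
    if (df["tg"] <= 0).any():
        raise ValueError("tg must be positive before log transform")
    df["log_tg"] = np.log(df["tg"].to_numpy())
    homa_beta, homa_ir = compute_homa(df["fins"].to_numpy(), df["fpg"].to_numpy())
    df["homa_beta"] = homa_beta
    df["homa_ir"] = homa_ir
    with np.errstate(divide="ignore", invalid="ignore"):
        df["log_homa_beta"] = np.where(homa_beta > 0, np.log(homa_beta), np.nan)
        df["log_homa_ir"] = np.where(homa_ir > 0, np.log(homa_ir), np.nan)
    return df


def _default_causal_effects() -> dict[str, float]:
    # Causal effect of a 1-SD increase in HbA1c on each outcome, outcome units.
    return {"log_tg": 0.19, "tc": 0.42, "ldl": 0.33, "hdl": 0.0}


def _default_confounders() -> dict[str, tuple[float, float]]:
    # covariate -> (effect on exposure in % per SD of covariate,
    #               effect on each outcome in outcome-SD units per SD of covariate)
    return {"age": (0.05, 0.02), "bmi": (0.08, 0.05)}


def _default_outcome_means() -> dict[str, float]:
    return {"log_tg": 0.28, "tc": 4.94, "ldl": 2.88, "hdl": 1.21}


def _default_outcome_sds() -> dict[str, float]:
    return {"log_tg": 0.52, "tc": 1.18, "ldl": 0.88, "hdl": 0.33}


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the emulated study: ~11,473 adults, a 17-SNP instrument
    explaining 3% of HbA1c variance (HbA1c mean ~6.0%, SD 1.06%), and causal
    effects per 1-SD HbA1c of 0.19 on log-TG, 0.42 mmol/L on TC, 0.33 mmol/L
    on LDL-C and 0 on HDL-C.  ``pleiotropy`` maps rsid -> {outcome: direct
    per-allele effect in outcome units}, contaminating the instrument.
    """

    n_individuals: int = 11_473
    snp_panel: list[SnpAnnotation] = field(default_factory=default_panel)
    target_instrument_r2: float = 0.03
    causal_effects: dict[str, float] = field(default_factory=_default_causal_effects)
    confounder_effects: dict[str, tuple[float, float]] = field(
        default_factory=_default_confounders
    )
    pleiotropy: dict[str, dict[str, float]] = field(default_factory=dict)
    missing_rate: float = 0.01
    hwe_violation: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    exposure_mean: float = 5.98
    exposure_sd: float = 1.06
    outcome_means: dict[str, float] = field(default_factory=_default_outcome_means)
    outcome_sds: dict[str, float] = field(default_factory=_default_outcome_sds)
    diabetes_hba1c: float = 6.5
    diabetes_fpg: float = 7.0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not 0.0 < self.target_instrument_r2 < 1.0:
            raise ValueError("target_instrument_r2 must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        rsids = {s.rsid for s in self.snp_panel}
        for name, mapping in (("pleiotropy", self.pleiotropy), ("hwe_violation", self.hwe_violation)):
            unknown = set(mapping) - rsids
            if unknown:
                raise ValueError(f"{name} names SNPs not in panel: {sorted(unknown)}")
        unknown = set(self.causal_effects) - set(OUTCOME_NAMES)
        if unknown:
            raise ValueError(f"causal_effects names unknown outcomes: {sorted(unknown)}")
        for rsid, effects in self.pleiotropy.items():
            unknown = set(effects) - set(OUTCOME_NAMES)
            if unknown:
                raise ValueError(f"pleiotropy[{rsid}] names unknown outcomes: {sorted(unknown)}")
        unknown = set(self.confounder_effects) - set(COVARIATE_PARAMS)
        if unknown:
            raise ValueError(f"confounder_effects names unknown covariates: {sorted(unknown)}")
        conf_var = sum(gx**2 for gx, _ in self.confounder_effects.values())
        if conf_var >= self.exposure_sd**2 * (1 - self.target_instrument_r2):
            raise ValueError("confounder effects leave no room for exposure noise variance")


def simulate_cohort(config: SimulationConfig):
    """Generate (GenotypeMatrix, cohort DataFrame, truth record).

    The exposure is built as ``lambda * sum_j w_j g_ij`` with the scaling
    ``lambda`` chosen so the genetic component explains
    ``target_instrument_r2`` of the theoretical exposure variance, plus
    confounder terms and Gaussian noise.  Each outcome adds the causal effect
    of the standardized realized exposure, per-SNP pleiotropic leakage,
    confounder terms and noise; residual variances are set so total outcome
    variances match the configured SDs (pleiotropy adds on top).
    """
    cfg = config
    panel = cfg.snp_panel
    n = cfg.n_individuals
    ss = np.random.SeedSequence(cfg.seed)
    rng_g, rng_miss, rng_ph = (np.random.default_rng(s) for s in ss.spawn(3))

    g = simulate_genotypes(panel, n, cfg.hwe_violation, seed=rng_g)

    weights = np.array([s.weight for s in panel])
    freqs = np.array([s.freq for s in panel])
    f_coef = np.array([cfg.hwe_violation.get(s.rsid, 0.0) for s in panel])
    # theoretical dosage variance 2pq(1+f); mean dosage 2p regardless of f
    dosage_var = 2 * freqs * (1 - freqs) * (1 + f_coef)
    var_score = float(np.sum(weights**2 * dosage_var))
    if var_score <= 0:
        raise ValueError("weighted score has zero theoretical variance")
    lam = cfg.exposure_sd * np.sqrt(cfg.target_instrument_r2 / var_score)
    genetic = lam * (g.dosages @ weights - np.sum(weights * 2 * freqs))

    # shared covariates
    cov = {}
    cov["age"] = rng_ph.normal(*COVARIATE_PARAMS["age"], size=n)
    cov["bmi"] = rng_ph.normal(*COVARIATE_PARAMS["bmi"], size=n)
    cov["sex"] = (rng_ph.random(n) < COVARIATE_PARAMS["sex"][0]).astype(float)
    cov["sbp"] = rng_ph.normal(*COVARIATE_PARAMS["sbp"], size=n)
    cov["dbp"] = rng_ph.normal(*COVARIATE_PARAMS["dbp"], size=n)
    for name in ("smoking", "drinking", "physical_activity"):
        cov[name] = (rng_ph.random(n) < COVARIATE_PARAMS[name][0]).astype(float)
    z_cov = {
        name: (values - COVARIATE_PARAMS[name][0]) / COVARIATE_PARAMS[name][1]
        for name, values in cov.items()
    }

    conf_exposure = np.zeros(n)
    for name, (gx, _) in cfg.confounder_effects.items():
        conf_exposure += gx * z_cov[name]
    conf_var = sum(gx**2 for gx, _ in cfg.confounder_effects.values())
    noise_sd = np.sqrt(cfg.exposure_sd**2 * (1 - cfg.target_instrument_r2) - conf_var)
    hba1c = cfg.exposure_mean + genetic + conf_exposure + rng_ph.normal(0, noise_sd, n)
    z_exposure = (hba1c - cfg.exposure_mean) / cfg.exposure_sd

    outcomes: dict[str, np.ndarray] = {}
    for name in OUTCOME_NAMES:
        beta = cfg.causal_effects.get(name, 0.0)
        sd_total = cfg.outcome_sds[name]
        conf_term = np.zeros(n)
        conf_out_var = 0.0
        for cov_name, (_, gy) in cfg.confounder_effects.items():
            conf_term += gy * sd_total * z_cov[cov_name]
            conf_out_var += (gy * sd_total) ** 2
        pleio = np.zeros(n)
        for rsid, effects in cfg.pleiotropy.items():
            alpha = effects.get(name, 0.0)
            if alpha:
                pleio += alpha * g.column(rsid)
        resid_var = sd_total**2 - beta**2 - conf_out_var
        if resid_var <= 0:
            raise ValueError(f"outcome {name}: causal/confounder effects exceed total variance")
        outcomes[name] = (
            cfg.outcome_means[name]
            + beta * z_exposure
            + pleio
            + conf_term
            + rng_ph.normal(0, np.sqrt(resid_var), n)
        )

    fpg = 6.0 + 0.9 * z_exposure + rng_ph.normal(0, np.sqrt(1.7**2 - 0.81), n)
    fpg = np.clip(fpg, 0.5, None)  # physiological floor; keeps HOMA inputs positive
    pg2h = 8.9 + 1.5 * z_exposure + rng_ph.normal(0, np.sqrt(4.1**2 - 2.25), n)
    fins = np.exp(rng_ph.normal(np.log(8.0), 0.5, n))

    df = pd.DataFrame(
        {
            "hba1c": hba1c,
            "tg": np.exp(outcomes["log_tg"]),
            "tc": outcomes["tc"],
            "ldl": outcomes["ldl"],
            "hdl": outcomes["hdl"],
            **cov,
            "fpg": fpg,
            "pg2h": pg2h,
            "fins": fins,
        }
    )
    df["diabetes"] = ((df["hba1c"] >= cfg.diabetes_hba1c) | (df["fpg"] >= cfg.diabetes_fpg)).astype(
        float
    )
    df = add_derived_columns(df)

    if cfg.missing_rate > 0:
        g = apply_missingness(g, cfg.missing_rate, seed=rng_miss)

    truth = {
        "lambda": float(lam),
        "scaled_weights": {s.rsid: float(lam * s.weight) for s in panel},
        "causal_effects": {name: float(cfg.causal_effects.get(name, 0.0)) for name in OUTCOME_NAMES},
        "exposure_mean": cfg.exposure_mean,
        "exposure_sd": cfg.exposure_sd,
        "target_instrument_r2": cfg.target_instrument_r2,
        "confounder_effects": {k: list(v) for k, v in cfg.confounder_effects.items()},
        "pleiotropy": {k: dict(v) for k, v in cfg.pleiotropy.items()},
        "seed": cfg.seed,
    }
    return g, df, truth
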