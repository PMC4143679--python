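"""Synthetic data generation and the simulation study.

Two jobs live here.  First, pleiotropic bivariate phenotype models over HWE
genotypes, with a Monte-Carlo driver that estimates type-I error and power of
four competing analyses of the same data: the bivariate reverse binomial
regression (k=2), each univariate regression (k=1), and a k=1 regression on
the first principal component of the two traits.  Second, a generator for a
complete synthetic study (longitudinal phenotypes, covariates, a genotype
panel with one causal SNP) exercising the full impute -> adjust -> scan
pipeline.

Phenotype models
----------------
``bivariate_normal``   trait_j = effect_j * N + e_j with (e_1, e_2) bivariate
                       standard normal, correlation rho (per-allele additive
                       mean shift in residual-SD units).
``bivariate_chisq``    trait_j = sum of squares of 3 latent normals; each
                       latent pair across traits is bivariate normal with
                       correlation sqrt(rho), so the trait correlation is
                       approximately rho (squares of correlated normals have
                       correlation rho).  The genotype shifts the mean of one
                       latent component by effect_j * N, i.e. a noncentrality
                       shift — the direction of the effect on the trait scale
                       is always positive, so opposite-direction scenarios
                       use the normal model.
``normal_binary``      trait 1 as in the normal model; trait 2 is the
                       indicator that a latent normal (correlation rho with
                       e_1) shifted by effect_2 * N exceeds the threshold
                       giving 30% prevalence under the null.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDesignError, MonomorphicError
from .model import GenotypeCounts, _lrt_arrays

__all__ = [
    "SimConfig",
    "PowerReport",
    "ANALYSIS_MODES",
    "simulate_genotypes",
    "simulate_phenotypes",
    "estimate_type1_power",
    "simulate_study_dataset",
]

PHENOTYPE_MODELS = ("bivariate_normal", "bivariate_chisq", "normal_binary")
ANALYSIS_MODES = (
    "bivariate_binomial", "univariate_trait1", "univariate_trait2",
    "pc1_binomial",
)


@dataclass
class SimConfig:
    """One Monte-Carlo scenario.

    ``effect_sizes`` are per-allele mean shifts for the two traits in
    residual-SD units; their signs encode the direction of the pleiotropic
    effect.  ``rho`` is the residual (null) correlation between the traits.
    """

    model: str = "bivariate_normal"
    n: int = 500
    reps: int = 1000
    maf: float = 0.3
    effect_sizes: tuple[float, float] = (0.0, 0.0)
    rho: float = 0.2
    alpha: float = 0.05
    seed: int = 0
    binary_prevalence: float = 0.3

    def __post_init__(self) -> None:
        if self.model not in PHENOTYPE_MODELS:
            raise ValueError(f"unknown phenotype model {self.model!r}")
        if self.n < 50:
            raise ValueError("n must be at least 50")
        if self.reps < 100:
            raise ValueError("reps must be at least 100")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if self.model == "bivariate_chisq" and self.rho < 0.0:
            raise ValueError(
                "bivariate_chisq induces correlation through shared latent "
                "components and supports rho in [0, 1) only"
            )
        if not 0.0 < self.binary_prevalence < 1.0:
            raise ValueError("binary_prevalence must lie in (0, 1)")
        self.effect_sizes = (float(self.effect_sizes[0]), float(self.effect_sizes[1]))


@dataclass
class PowerReport:
    """Monte-Carlo rejection rates per analysis mode for one scenario."""

    rejection_rates: dict[str, float]
    mc_standard_errors: dict[str, float]
    n_fit_failures: dict[str, int]
    config: SimConfig
    statistics: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        modes = list(self.rejection_rates)
        return pd.DataFrame({
            "analysis": modes,
            "rejection_rate": [self.rejection_rates[m] for m in modes],
            "mc_se": [self.mc_standard_errors[m] for m in modes],
            "fit_failures": [self.n_fit_failures[m] for m in modes],
        })

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "rejection_rates": self.rejection_rates,
            "mc_standard_errors": self.mc_standard_errors,
            "n_fit_failures": self.n_fit_failures,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def simulate_genotypes(n: int, maf: float, rng=None, snp_id: str = "sim",
                       ) -> GenotypeCounts:
    """HWE genotypes: each count is the sum of two Bernoulli(maf) draws."""
    if not 0.0 <= maf <= 1.0:
        raise ValueError("maf must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    counts = rng.binomial(2, maf, size=n)
    return GenotypeCounts(counts, snp_id=snp_id)


def simulate_phenotypes(N: GenotypeCounts, config: SimConfig, rng=None,
                        ) -> np.ndarray:
    """Draw the (n, 2) trait matrix for one replicate under ``config``."""
    rng = np.random.default_rng(rng)
    counts = N.counts.astype(float)
    n = counts.shape[0]
    e1, e2 = config.effect_sizes
    rho = config.rho

    if config.model == "bivariate_normal":
        cov = [[1.0, rho], [rho, 1.0]]
        eps = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        return np.column_stack([e1 * counts + eps[:, 0],
                                e2 * counts + eps[:, 1]])

    if config.model == "bivariate_chisq":
        r = math.sqrt(rho)
        cov = [[1.0, r], [r, 1.0]]
        traits = np.zeros((n, 2))
        for m in range(3):
            w = rng.multivariate_normal([0.0, 0.0], cov, size=n)
            if m == 0:  # genotype shifts the first latent's mean
                w[:, 0] += e1 * counts
                w[:, 1] += e2 * counts
            traits += w ** 2
        return traits

    # normal_binary
    cov = [[1.0, rho], [rho, 1.0]]
    eps = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    trait1 = e1 * counts + eps[:, 0]
    threshold = stats.norm.ppf(1.0 - config.binary_prevalence)
    trait2 = (eps[:, 1] + e2 * counts > threshold).astype(float)
    return np.column_stack([trait1, trait2])


def _pc1_scores(traits: np.ndarray) -> np.ndarray:
    centered = traits - traits.mean(axis=0)
    cov = centered.T @ centered / (traits.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    v = eigvec[:, np.argmax(eigval)]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return centered @ v


def estimate_type1_power(config: SimConfig) -> PowerReport:
    """Monte-Carlo rejection rates of the four analyses under ``config``.

    Each replicate simulates one SNP and one bivariate trait matrix, then
    runs all four analyses on the SAME data (common random numbers), so power
    comparisons between modes are paired.  Per-replicate seeds are spawned
    deterministically from ``config.seed``.  Replicates where a fit fails
    (monomorphic SNP, non-convergence) count as non-rejections for that mode
    and are tallied in ``n_fit_failures``.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.reps)
    rejections = {m: 0 for m in ANALYSIS_MODES}
    failures = {m: 0 for m in ANALYSIS_MODES}
    stats_by_mode: dict[str, list[float]] = {m: [] for m in ANALYSIS_MODES}

    for child in children:
        rng = np.random.default_rng(child)
        geno = simulate_genotypes(config.n, config.maf, rng)
        traits = simulate_phenotypes(geno, config, rng)
        designs = {
            "bivariate_binomial": traits,
            "univariate_trait1": traits[:, :1],
            "univariate_trait2": traits[:, 1:],
            "pc1_binomial": _pc1_scores(traits)[:, None],
        }
        for mode, X in designs.items():
            try:
                stat, _, pval, converged = _lrt_arrays(X, geno.counts)
            except (MonomorphicError, DegenerateDesignError):
                failures[mode] += 1
                continue
            if not converged or np.isnan(pval):
                failures[mode] += 1
                continue
            stats_by_mode[mode].append(stat)
            if pval < config.alpha:
                rejections[mode] += 1

    rates = {m: rejections[m] / config.reps for m in ANALYSIS_MODES}
    ses = {
        m: math.sqrt(rates[m] * (1.0 - rates[m]) / config.reps)
        for m in ANALYSIS_MODES
    }
    return PowerReport(
        rejection_rates=rates,
        mc_standard_errors=ses,
        n_fit_failures=failures,
        config=config,
        statistics={m: np.asarray(v) for m, v in stats_by_mode.items()},
    )


# ---------------------------------------------------------------------- #
# full synthetic study for the end-to-end pipeline

def simulate_study_dataset(
    n: int = 150,
    n_snps: int = 500,
    n_timepoints: int = 4,
    maf: float = 0.3,
    causal_index: int = 0,
    causal_effect: float = 0.8,
    missing_rates: tuple[float, ...] = (0.08, 0.35, 0.35, 0.75),
    covariate_missing_rate: float = 0.07,
    genotype_missing_rate: float = 0.02,
    seed: int = 0,
) -> dict:
    """Generate a complete synthetic association study.

    Emulates a longitudinal blood-pressure design: log-normal SBP/DBP at
    ``n_timepoints`` examinations with a shared per-subject component (so the
    first principal component dominates), age/smoking/medication covariates
    with real effects on the traits, per-time-point MCAR phenotype
    missingness at ``missing_rates``, a fraction of individuals with an
    incomplete covariate record, and ``n_snps`` HWE SNPs of which the one at
    ``causal_index`` shifts the subject-level component of BOTH traits by
    ``causal_effect`` within-trait SDs per minor allele (a pleiotropic
    signal).

    Returns a dict with long-format ``phenotypes`` and ``covariates``
    DataFrames, a ``dosages`` DataFrame (dosage-TSV schema), ``sample_ids``,
    and a ``truth`` dict recording the generating parameters.
    """
    if len(missing_rates) != n_timepoints:
        raise ValueError("missing_rates must give one rate per time point")
    rng = np.random.default_rng(seed)
    ids = [f"ind{i + 1:04d}" for i in range(n)]
    times = np.arange(1, n_timepoints + 1)

    # covariates: age advances between exams; smoking constant per subject;
    # medication may start and then persists
    age0 = rng.normal(50.0, 10.0, size=n)
    age = age0[:, None] + 2.5 * (times - 1)[None, :] + rng.normal(0, 0.2, (n, n_timepoints))
    smoke = np.repeat(rng.binomial(1, 0.25, size=n)[:, None], n_timepoints, axis=1).astype(float)
    med_start = rng.integers(0, 2 * n_timepoints, size=n)  # >= T means never medicated
    med = (np.arange(n_timepoints)[None, :] >= med_start[:, None]).astype(float)

    # genotypes
    geno = rng.binomial(2, maf, size=(n_snps, n))
    causal = geno[causal_index].astype(float)

    # log-scale traits: subject effect (shared across time) + time noise,
    # chi-square-like variance split giving PC1 ~55% of the variance
    sd_total = 0.12
    icc = 0.4
    sd_u = sd_total * math.sqrt(icc)
    sd_e = sd_total * math.sqrt(1.0 - icc)
    truth_beta = {"age": 0.002, "smoke": 0.02, "med": -0.04}
    base = {"sbp": math.log(125.0), "dbp": math.log(80.0)}
    phen = {}
    for trait, mu0 in base.items():
        u = rng.normal(0.0, sd_u, size=n) + causal_effect * sd_total * causal
        eps = rng.normal(0.0, sd_e, size=(n, n_timepoints))
        log_vals = (
            mu0
            + truth_beta["age"] * (age - 50.0)
            + truth_beta["smoke"] * smoke
            + truth_beta["med"] * med
            + u[:, None]
            + eps
        )
        phen[trait] = np.exp(log_vals)

    # MCAR phenotype missingness per time point (joint for both traits,
    # mimicking a missed examination)
    miss = rng.random((n, n_timepoints)) < np.asarray(missing_rates)[None, :]
    for trait in phen:
        phen[trait][miss] = np.nan

    # some individuals lack a covariate somewhere -> dropped at adjustment
    cov_missing = rng.random(n) < covariate_missing_rate
    for i in np.flatnonzero(cov_missing):
        t = rng.integers(0, n_timepoints)
        which = rng.integers(0, 3)
        if which == 0:
            age[i, t] = np.nan
        elif which == 1:
            smoke[i, t] = np.nan
        else:
            med[i, t] = np.nan

    # genotype missingness
    geno_f = geno.astype(float)
    geno_f[rng.random((n_snps, n)) < genotype_missing_rate] = np.nan

    pheno_rows = []
    covar_rows = []
    for i, iid in enumerate(ids):
        for t in range(n_timepoints):
            pheno_rows.append((iid, int(times[t]),
                               phen["sbp"][i, t], phen["dbp"][i, t]))
            covar_rows.append((iid, int(times[t]), age[i, t],
                               smoke[i, t], med[i, t]))
    pheno_df = pd.DataFrame(pheno_rows, columns=["iid", "timepoint", "sbp", "dbp"])
    covar_df = pd.DataFrame(covar_rows, columns=["iid", "timepoint", "age", "smoke", "med"])

    dosage_rows = []
    for s in range(n_snps):
        dosage_rows.append([
            f"snp{s + 1:04d}", str(1 + s % 22), 10_000 + 1000 * s,
            *geno_f[s],
        ])
    dosage_df = pd.DataFrame(dosage_rows, columns=["snp_id", "chrom", "pos", *ids])

    truth = {
        "causal_snp_id": f"snp{causal_index + 1:04d}",
        "causal_index": causal_index,
        "causal_effect_sd_per_allele": causal_effect,
        "maf": maf,
        "missing_rates": list(missing_rates),
        "covariate_effects": truth_beta,
        "seed": seed,
    }
    return {
        "phenotypes": pheno_df,
        "covariates": covar_df,
        "dosages": dosage_df,
        "sample_ids": ids,
        "truth": truth,
    }
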