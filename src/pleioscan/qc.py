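"""SNP quality control: minor-allele-frequency floor and Hardy-Weinberg
equilibrium screening.

The HWE check uses the exact conditional test: conditioning on the observed
allele counts, the number of heterozygotes follows a known distribution under
random mating, and the p-value is the total probability of configurations no
more probable than the observed one.  At sample sizes of a few hundred the
asymptotic chi-square test is unreliable for rare alleles, so the exact test
is the default; a chi-square option is kept behind a flag.  HWE exclusion is
Bonferroni-corrected across all SNPs entering QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .model import GenotypeCounts

__all__ = [
    "SnpQCRecord",
    "minor_allele_freq",
    "ensure_minor_coding",
    "hwe_exact_test",
    "hwe_chisq_test",
    "filter_snps",
    "qc_report_frame",
]


@dataclass
class SnpQCRecord:
    """Outcome of QC for one SNP. ``kept`` is true iff ``reason == "ok"``."""

    snp_id: str
    chromosome: str
    position: int
    maf: float
    hwe_pvalue: float
    kept: bool
    reason: str  # ok | low_maf | hwe_fail | monomorphic

    def __post_init__(self) -> None:
        if self.kept != (self.reason == "ok"):
            raise ValueError("kept flag inconsistent with reason")


def minor_allele_freq(N: GenotypeCounts) -> float:
    """Sample frequency of the minor allele among non-missing genotypes.

    If the coded allele turns out to be the major one (frequency > 0.5) the
    complementary frequency is returned; use :func:`ensure_minor_coding` to
    actually flip the coding.
    """
    obs = N.observed()
    if obs.size == 0:
        raise ValueError(f"SNP {N.snp_id!r}: all genotypes missing")
    freq = obs.sum() / (2.0 * obs.size)
    return float(min(freq, 1.0 - freq))


def ensure_minor_coding(N: GenotypeCounts) -> tuple[GenotypeCounts, bool]:
    """Recode counts to the minor allele if needed; returns (counts, recoded).

    A coded-allele frequency of exactly 0.5 is left as-is (tie broken by the
    input coding).  Idempotent: recoding twice equals recoding once.
    """
    obs = N.observed()
    if obs.size == 0:
        raise ValueError(f"SNP {N.snp_id!r}: all genotypes missing")
    freq = obs.sum() / (2.0 * obs.size)
    if freq <= 0.5:
        return N, False
    flipped = GenotypeCounts(
        2 - N.counts, N.missing_mask.copy(), N.snp_id, N.chromosome, N.position,
    )
    return flipped, True


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and enumerates every compatible
    heterozygote count; the p-value is the sum of the conditional
    probabilities of all configurations at most as probable as the observed
    one.  Probabilities are computed on the log scale so genotype tables of
    thousands of individuals remain exact.
    """
    for v in (n_hom_major, n_het, n_hom_minor):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotype")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    rare = min(n_minor, n_major)
    # heterozygote count shares the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # conditional log-probability of each configuration
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        np.log(2.0) * hets
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_het]
    if p_obs.size != 1:
        raise ValueError("observed heterozygote count incompatible with allele counts")
    return float(min(p[p <= p_obs[0] * (1.0 + 1e-12)].sum(), 1.0))


def hwe_chisq_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """One-df asymptotic chi-square HWE test (no continuity correction)."""
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotype")
    q = (2 * n_hom_minor + n_het) / (2.0 * n)
    p = 1.0 - q
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    if (expected == 0).any():
        return 1.0
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, 1))


def _genotype_table(N: GenotypeCounts) -> tuple[int, int, int]:
    obs = N.observed()
    return (
        int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum()),
    )


def filter_snps(genotypes, maf_min: float = 0.01, hwe_alpha: float = 0.05,
                hwe_method: str = "exact",
                ) -> tuple[list[int], list[SnpQCRecord]]:
    """Apply MAF and HWE filters to a collection of SNPs.

    A SNP is kept iff its MAF is at least ``maf_min`` AND its HWE p-value is
    at least ``hwe_alpha / M`` where M is the number of SNPs entering QC
    (Bonferroni at the genome-wide level).  Monomorphic SNPs are removed with
    their own reason.  Returns kept indices (input order) and a QC record
    for every SNP.
    """
    genotypes = list(genotypes)
    M = len(genotypes)
    if M < 1:
        raise ValueError("no SNPs supplied to QC")
    hwe_fn = {"exact": hwe_exact_test, "chisq": hwe_chisq_test}[hwe_method]
    threshold = hwe_alpha / M
    kept: list[int] = []
    records: list[SnpQCRecord] = []
    for i, geno in enumerate(genotypes):
        recoded, _ = ensure_minor_coding(geno)
        maf = minor_allele_freq(recoded)
        hwe_p = hwe_fn(*_genotype_table(recoded))
        if maf == 0.0:
            reason = "monomorphic"
        elif maf < maf_min:
            reason = "low_maf"
        elif hwe_p < threshold:
            reason = "hwe_fail"
        else:
            reason = "ok"
            kept.append(i)
        records.append(SnpQCRecord(
            geno.snp_id, geno.chromosome, geno.position, maf, hwe_p,
            reason == "ok", reason,
        ))
    return kept, records


def qc_report_frame(records: list[SnpQCRecord]) -> pd.DataFrame:
    """QC records as a tidy table (snp_id, chrom, pos, maf, hwe_p, kept, reason)."""
    return pd.DataFrame({
        "snp_id": [r.snp_id for r in records],
        "chrom": [r.chromosome for r in records],
        "pos": [r.position for r in records],
        "maf": [r.maf for r in records],
        "hwe_p": [r.hwe_pvalue for r in records],
        "kept": [r.kept for r in records],
        "reason": [r.reason for r in records],
    })
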