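"""Genome-wide association scan with FDR control.

Applies the binomial reverse-regression LRT to every QC-passing SNP, corrects
the resulting p-values with the Benjamini-Hochberg step-up procedure at an
overall FDR (default 0.05), and reports the top findings ranked by p-value.
SNPs whose fits fail to converge carry NA p-values and are excluded from the
number of tests entering the FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import __version__
from .exceptions import DegenerateDesignError, MonomorphicError
from .model import GenotypeBinomialModel, GenotypeCounts, PhenotypeVectorSet
from .qc import ensure_minor_coding, filter_snps, qc_report_frame

__all__ = ["ScanResult", "scan", "bh_fdr", "rank_report"]

RESULT_COLUMNS = [
    "snp_id", "chrom", "pos", "k", "lrt_statistic", "pvalue", "qvalue",
    "rejected", "n_used", "converged",
]


@dataclass
class ScanResult:
    """Per-SNP association records plus analysis metadata.

    ``records`` has one row per QC-passing SNP in input (file) order;
    ``qc`` one row per input SNP.
    """

    records: pd.DataFrame
    qc: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        """Write records with fixed formatting (byte-stable across runs)."""
        df = self.records.copy()
        for col in ("lrt_statistic", "pvalue", "qvalue"):
            df[col] = df[col].map(
                lambda v: "NA" if pd.isna(v) else f"{v:.3e}"
            )
        df.to_csv(path, sep="\t", index=False)


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: monotone q-values and rejection flags.

    ``q_(i) = min_{j >= i} M p_(j) / j`` (clipped at 1) on the sorted
    p-values; every p at or below the largest p_(i) with p_(i) <= i q / M is
    rejected.  Missing p-values must be excluded by the caller.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.isnan(p).any():
        raise ValueError("bh_fdr received missing p-values; filter them out first")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def scan(genotypes, phenotypes: PhenotypeVectorSet,
         genotype_sample_ids: list[str] | None = None,
         maf_min: float = 0.01, hwe_alpha: float = 0.05,
         fdr_q: float = 0.05, hwe_method: str = "exact",
         metadata: dict | None = None) -> ScanResult:
    """Run the association scan over a collection of SNPs.

    Parameters
    ----------
    genotypes : sequence of GenotypeCounts
        SNPs in file order; counts may be coded to either allele (recoded to
        the minor allele internally).
    phenotypes : PhenotypeVectorSet
        Adjusted phenotype vectors for the analysis sample.
    genotype_sample_ids : list of str, optional
        Individual ids of the genotype columns.  When given, each SNP is
        subset/reordered to the phenotype individuals (which must all be
        present); when omitted, genotypes are assumed pre-aligned.
    """
    genotypes = list(genotypes)
    if genotype_sample_ids is not None:
        index = {s: i for i, s in enumerate(genotype_sample_ids)}
        missing = [s for s in phenotypes.individual_ids if s not in index]
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped individuals absent from the "
                f"genotype data (first: {missing[0]!r})"
            )
        sel = np.array([index[s] for s in phenotypes.individual_ids])
        genotypes = [
            GenotypeCounts(g.counts[sel], g.missing_mask[sel], g.snp_id,
                           g.chromosome, g.position)
            for g in genotypes
        ]
    else:
        for g in genotypes:
            if g.n != phenotypes.n:
                raise ValueError(
                    f"SNP {g.snp_id!r} has {g.n} genotypes but the phenotype "
                    f"set has {phenotypes.n} individuals"
                )

    kept_idx, qc_records = filter_snps(
        genotypes, maf_min=maf_min, hwe_alpha=hwe_alpha, hwe_method=hwe_method,
    )
    if not kept_idx:
        warnings.warn("no SNPs passed QC; scan result is empty", stacklevel=2)

    rows = []
    for i in kept_idx:
        geno, _ = ensure_minor_coding(genotypes[i])
        try:
            res = GenotypeBinomialModel(
                geno, phenotypes, drop_constant=True,
            ).lr_test()
            rows.append((geno.snp_id, geno.chromosome, geno.position, res.df,
                         res.statistic, res.pvalue, res.fit_full.n_used,
                         res.converged))
        except (MonomorphicError, DegenerateDesignError):
            rows.append((geno.snp_id, geno.chromosome, geno.position,
                         phenotypes.k, np.nan, np.nan, geno.n_nonmissing,
                         False))
    records = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "k", "lrt_statistic", "pvalue",
                 "n_used", "converged"],
    )
    records["qvalue"] = np.nan
    records["rejected"] = False
    valid = records["pvalue"].notna().to_numpy()
    if valid.any():
        qvals, reject = bh_fdr(records.loc[valid, "pvalue"].to_numpy(), q=fdr_q)
        records.loc[valid, "qvalue"] = qvals
        records.loc[valid, "rejected"] = reject
    records = records[RESULT_COLUMNS]

    meta = {
        "software": "pleioscan",
        "version": __version__,
        "n_individuals": int(phenotypes.n),
        "k": int(phenotypes.k),
        "component_labels": list(phenotypes.component_labels),
        "n_snps_input": len(genotypes),
        "n_snps_tested": len(kept_idx),
        "n_tests_in_fdr": int(valid.sum()),
        "maf_min": maf_min,
        "hwe_alpha": hwe_alpha,
        "hwe_method": hwe_method,
        "fdr_q": fdr_q,
    }
    if metadata:
        meta.update(metadata)
    return ScanResult(records, qc_report_frame(qc_records), meta)


def rank_report(result: ScanResult, top_n: int = 5) -> pd.DataFrame:
    """Top associations sorted by ascending p-value (ties: chrom, then pos).

    Mirrors a "most significant findings" table: unadjusted p alongside the
    FDR q-value.  SNPs without a valid p-value sort last and are excluded.
    """
    df = result.records.copy()
    df = df[df["pvalue"].notna()]
    df = df.sort_values(
        ["pvalue", "chrom", "pos"], kind="mergesort"
    ).head(top_n)
    return df.reset_index(drop=True)
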