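"""Readers and writers for the package's plain-text interchange formats.

Phenotypes and covariates travel as long-format TSVs (one row per individual
and time point); genotypes as either a dosage TSV
(``snp_id  chrom  pos  <iid1>  <iid2> ...`` with entries 0/1/2/NA) or a VCF
whose diploid GT field is parsed to counted-allele dosages.  Missing values
in TSVs are empty fields or the string ``NA``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import GenotypeCounts
from .preprocess import CovariatePanel, LongitudinalPanel

__all__ = [
    "read_phenotype_table",
    "read_covariate_table",
    "read_dosage_table",
    "write_dosage_table",
    "read_vcf",
    "write_metadata",
]

_NA = ["", "NA", "na", "NaN"]


def read_phenotype_table(path, trait_cols: list[str] | None = None) -> LongitudinalPanel:
    """Long-format phenotype TSV (``iid  timepoint  sbp  dbp``) -> panel."""
    df = pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=False)
    for col in ("iid", "timepoint"):
        if col not in df.columns:
            raise ValueError(f"phenotype table is missing required column {col!r}")
    return LongitudinalPanel.from_long_dataframe(df, trait_cols=trait_cols)


def read_covariate_table(path) -> CovariatePanel:
    """Long-format covariate TSV (``iid  timepoint  age  smoke  med``)."""
    df = pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=False)
    required = {"iid", "timepoint", "age", "smoke", "med"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate table is missing columns {sorted(missing)}")
    return CovariatePanel.from_long_dataframe(df)


def read_dosage_table(path) -> tuple[list[GenotypeCounts], list[str]]:
    """Dosage TSV -> (list of per-SNP counts, sample ids in column order)."""
    df = pd.read_csv(path, sep="\t", na_values=_NA, keep_default_na=False)
    meta_cols = ["snp_id", "chrom", "pos"]
    for col in meta_cols:
        if col not in df.columns:
            raise ValueError(f"dosage table is missing required column {col!r}")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    snps = []
    for _, row in df.iterrows():
        dosages = pd.to_numeric(row[sample_ids], errors="coerce").to_numpy(dtype=float)
        snps.append(GenotypeCounts(
            dosages, snp_id=str(row["snp_id"]), chromosome=str(row["chrom"]),
            position=int(row["pos"]),
        ))
    return snps, sample_ids


def write_dosage_table(path, snps: list[GenotypeCounts], sample_ids: list[str]) -> None:
    """Inverse of :func:`read_dosage_table` (missing written as NA)."""
    rows = []
    for s in snps:
        vals = s.counts.astype(object)
        vals[s.missing_mask] = "NA"
        rows.append([s.snp_id, s.chromosome, s.position, *vals])
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", *sample_ids])
    df.to_csv(path, sep="\t", index=False)


def read_vcf(path) -> tuple[list[GenotypeCounts], list[str]]:
    """Biallelic VCF -> per-SNP ALT-allele dosages (1-based coordinates).

    Half-calls and missing GT become missing; multiallelic sites are skipped
    with a warning.  Uses cyvcf2 when importable, otherwise a minimal parser
    for plain-text VCFs.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snps = []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multiallelic site {var.ID or var.POS}",
                          stacklevel=2)
            continue
        gts = np.asarray(var.genotype.array())[:, :2]
        missing = (gts < 0).any(axis=1)
        dosage = np.where(missing, np.nan, gts.clip(min=0).sum(axis=1)).astype(float)
        snps.append(GenotypeCounts(
            dosage, snp_id=var.ID or f"{var.CHROM}:{var.POS}",
            chromosome=str(var.CHROM), position=int(var.POS),
        ))
    return snps, sample_ids


def _read_vcf_text(path) -> tuple[list[GenotypeCounts], list[str]]:
    sample_ids: list[str] = []
    snps: list[GenotypeCounts] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                sample_ids = fields[9:]
                continue
            chrom, pos, vid, _ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                warnings.warn(f"skipping multiallelic site {vid or pos}", stacklevel=2)
                continue
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            dosage = np.full(len(sample_ids), np.nan)
            for i, cell in enumerate(fields[9:]):
                gt = cell.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles or len(alleles) != 2:
                    continue
                dosage[i] = sum(int(a) for a in alleles)
            snps.append(GenotypeCounts(
                dosage, snp_id=vid if vid != "." else f"{chrom}:{pos}",
                chromosome=chrom, position=int(pos),
            ))
    return snps, sample_ids


def write_metadata(path, metadata: dict) -> None:
    """JSON run-metadata sidecar with stable key order."""
    Path(path).write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
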