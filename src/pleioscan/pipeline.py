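"""End-to-end orchestration: impute -> adjust -> build phenotype vector -> scan.

A convenience layer tying the preprocessing and scan stages together so the
CLI, tests and scripts run the identical sequence.
"""

from __future__ import annotations

import numpy as np

from .model import GenotypeCounts
from .preprocess import (
    CovariatePanel,
    LongitudinalPanel,
    PhenotypeVectorSpec,
    adjust_covariates,
    build_phenotype_vector,
    impute_panel,
    log_transform,
)
from .scan import ScanResult, scan

__all__ = ["prepare_phenotypes", "run_study"]


def prepare_phenotypes(panel: LongitudinalPanel, covariates: CovariatePanel,
                       spec: PhenotypeVectorSpec, *, already_logged: bool = False,
                       single_pass_impute: bool = False):
    """Log-transform, impute, adjust and assemble the phenotype vector.

    Returns ``(phenotype_set, residuals, kept_ids)`` where ``residuals`` maps
    trait name to its (n', T) adjusted matrix over the kept individuals.
    """
    if len(panel.trait_labels) != 2:
        raise ValueError("expected a two-trait (e.g. SBP/DBP) panel")
    logged = panel if already_logged else log_transform(panel)
    imputed, _ = impute_panel(logged, single_pass=single_pass_impute)
    residuals, kept = adjust_covariates(imputed, covariates)
    kept_ids = [panel.individual_ids[i] for i in kept]
    trait_a, trait_b = panel.trait_labels
    pheno = build_phenotype_vector(
        residuals[trait_a], residuals[trait_b], spec,
        individual_ids=kept_ids,
        trait_labels=(trait_a.upper(), trait_b.upper()),
    )
    return pheno, residuals, kept_ids


def run_study(panel: LongitudinalPanel, covariates: CovariatePanel,
              genotypes: list[GenotypeCounts], genotype_sample_ids: list[str],
              spec: PhenotypeVectorSpec, *, maf_min: float = 0.01,
              hwe_alpha: float = 0.05, fdr_q: float = 0.05,
              hwe_method: str = "exact", already_logged: bool = False,
              ) -> ScanResult:
    """The full association study on one dataset."""
    pheno, _, _ = prepare_phenotypes(
        panel, covariates, spec, already_logged=already_logged,
    )
    return scan(
        genotypes, pheno, genotype_sample_ids=genotype_sample_ids,
        maf_min=maf_min, hwe_alpha=hwe_alpha, fdr_q=fdr_q,
        hwe_method=hwe_method,
        metadata={"phenotype_mode": spec.mode, "n_pcs": spec.n_components},
    )
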