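"""End-to-end orchestration: qualify, collapse, test, correct, report.

Two analyses are run per binary outcome:

* **burden** — the per-patient count of qualifying variants in the whole
  26-gene set (its own single-test family) and in each of the five
  functional subgroups (Bonferroni family of 5) is compared between
  outcome groups with the Mann-Whitney U test; a descriptive logistic
  odds ratio per unit count is attached.
* **collapse** — per gene, carrier status (at least one qualifying
  variant) is tested against the outcome with the Fisher exact test;
  the conditional-MLE odds ratio and central exact CI are attached and
  the Bonferroni family size is the full 26-gene catalog, including
  genes without carriers (reported as untestable rows).

Bonferroni correction is applied within each analysis family per
outcome, by thresholding at ``alpha / m``; ``min(1, m * p)`` is also
derivable from the emitted columns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import __version__
from .io import load_catalog, read_annotation, read_phenotypes, read_vcf, write_results
from .qualify import (
    CarrierAndBurden,
    QualifyingVariantSet,
    build_carrier_and_burden,
    qualify_variants,
    write_audit,
)
from .stats import (
    TwoByTwoTable,
    bonferroni,
    burden_or_logistic,
    conditional_mle_or,
    exact_or_ci,
    fisher_two_sided_p,
    mann_whitney_u,
)
from .types import (
    OUTCOMES,
    AnalysisConfig,
    AssociationResult,
    GeneSetCatalog,
    GenotypeMatrix,
    PhenotypeTable,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LoadedInputs",
    "RunManifest",
    "load_inputs",
    "run_all",
    "run_burden_analysis",
    "run_collapse_analysis",
]


@dataclass
class LoadedInputs:
    """Validated inputs with genotype rows aligned to the phenotype order."""

    variants: list[VariantRecord]
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    catalog: GeneSetCatalog


def load_inputs(
    vcf_path: str,
    sidecar_path: str,
    phenotype_path: str,
    catalog_path: Optional[str] = None,
) -> LoadedInputs:
    """Read and cross-validate the three input files plus the catalog.

    Every phenotype patient must be genotyped; genotype rows are
    reordered to the phenotype order so downstream statistics are
    invariant to the on-disk sample order.
    """
    stubs, genotypes = read_vcf(vcf_path)
    variants = read_annotation(sidecar_path, stubs)
    phenotypes = read_phenotypes(phenotype_path, genotypes)
    genotypes = genotypes.reorder_patients(phenotypes.patient_ids)
    catalog = load_catalog(catalog_path)
    return LoadedInputs(variants, genotypes, phenotypes, catalog)


def _prepare(inputs: LoadedInputs, config: AnalysisConfig) -> tuple[QualifyingVariantSet, CarrierAndBurden]:
    qs = qualify_variants(inputs.variants, config, inputs.catalog)
    cab = build_carrier_and_burden(qs, inputs.genotypes, inputs.catalog, config)
    return qs, cab


def _outcome_usable(y: np.ndarray, outcome: str) -> bool:
    if y.min() == y.max():
        logger.warning("outcome %s has a single class; skipping its tests", outcome)
        return False
    return True


def run_burden_analysis(
    inputs: LoadedInputs,
    config: Optional[AnalysisConfig] = None,
    collapsed: Optional[CarrierAndBurden] = None,
) -> list[AssociationResult]:
    """Mann-Whitney burden tests per outcome: whole gene set plus subgroups.

    The whole-set test is its own family (nominal threshold alpha); the
    five subgroup tests share a Bonferroni family of five.  Tests with
    no burden variation are emitted as untestable rows, except that a
    cohort with no qualifying variant anywhere yields an empty result.
    """
    config = config or AnalysisConfig()
    if collapsed is None:
        _, collapsed = _prepare(inputs, config)
    if collapsed.burden.max() == 0:
        logger.warning("no qualifying variant in any patient; burden analysis is empty")
        return []
    group_names = [s for s in collapsed.gene_sets if s != "all"]
    results: list[AssociationResult] = []
    for outcome in OUTCOMES:
        y = inputs.phenotypes.outcome(outcome)
        if not _outcome_usable(y, outcome):
            continue
        for unit, family in [("all", 1)] + [(g, len(group_names)) for g in group_names]:
            counts = collapsed.burden_vector(unit)
            threshold = bonferroni(config.alpha, family)
            if np.ptp(counts) == 0:
                results.append(
                    AssociationResult(
                        unit=unit, unit_kind="group", outcome=outcome, test="mann_whitney",
                        statistic=math.nan, odds_ratio=math.nan, ci_low=math.nan,
                        ci_high=math.nan, p_value=math.nan, bonferroni_threshold=threshold,
                        significant_nominal=False, significant_adjusted=False,
                        note="untestable_constant_burden",
                    )
                )
                continue
            u, p = mann_whitney_u(counts[y == 1], counts[y == 0], mode="auto")
            companion = burden_or_logistic(counts, y, level=config.ci_level)
            note = "companion_logistic_or"
            if companion.separated:
                note += ";separation"
            results.append(
                AssociationResult(
                    unit=unit, unit_kind="group", outcome=outcome, test="mann_whitney",
                    statistic=u, odds_ratio=companion.odds_ratio,
                    ci_low=companion.ci_low, ci_high=companion.ci_high, p_value=p,
                    bonferroni_threshold=threshold,
                    significant_nominal=p < config.alpha,
                    significant_adjusted=p < threshold,
                    note=note,
                )
            )
    return results


def run_collapse_analysis(
    inputs: LoadedInputs,
    config: Optional[AnalysisConfig] = None,
    collapsed: Optional[CarrierAndBurden] = None,
) -> list[AssociationResult]:
    """Fisher exact gene-collapse tests per outcome across the catalog.

    Genes with zero carriers are reported as untestable rows and do not
    count toward significance, but the Bonferroni family size remains
    the catalog size (26 by default).
    """
    config = config or AnalysisConfig()
    if collapsed is None:
        _, collapsed = _prepare(inputs, config)
    m = len(inputs.catalog.all_genes)
    threshold = bonferroni(config.alpha, m)
    results: list[AssociationResult] = []
    for outcome in OUTCOMES:
        y = inputs.phenotypes.outcome(outcome)
        if not _outcome_usable(y, outcome):
            continue
        for gene in inputs.catalog.all_genes:
            carrier = collapsed.carrier_vector(gene)
            if carrier.sum() == 0:
                results.append(
                    AssociationResult(
                        unit=gene, unit_kind="gene", outcome=outcome, test="fisher_exact",
                        statistic=math.nan, odds_ratio=math.nan, ci_low=math.nan,
                        ci_high=math.nan, p_value=math.nan, bonferroni_threshold=threshold,
                        significant_nominal=False, significant_adjusted=False,
                        note="untestable_no_carriers",
                    )
                )
                continue
            t = TwoByTwoTable(
                int(((y == 1) & (carrier == 1)).sum()),
                int(((y == 1) & (carrier == 0)).sum()),
                int(((y == 0) & (carrier == 1)).sum()),
                int(((y == 0) & (carrier == 0)).sum()),
            )
            p = fisher_two_sided_p(t)
            psi = conditional_mle_or(t)
            lo, hi = exact_or_ci(t, config.ci_level)
            note = ""
            if psi == 0.0 or math.isinf(psi):
                note = "boundary_odds_ratio"
            results.append(
                AssociationResult(
                    unit=gene, unit_kind="gene", outcome=outcome, test="fisher_exact",
                    statistic=float(t.a), odds_ratio=psi, ci_low=lo, ci_high=hi,
                    p_value=p, bonferroni_threshold=threshold,
                    significant_nominal=p < config.alpha,
                    significant_adjusted=p < threshold,
                    note=note,
                )
            )
    return results


@dataclass
class RunManifest:
    """Provenance and reconciliation counts for one pipeline run."""

    input_digests: dict[str, str]
    config: dict
    catalog_groups: dict[str, int]
    variants_loaded: int
    variants_qualified: int
    genes_with_carrier: int
    burden_tests_run: int
    collapse_tests_run: int
    n_patients: int
    software_version: str = field(default=__version__)

    def validate(self) -> None:
        if self.variants_qualified > self.variants_loaded:
            raise ValidationError("manifest inconsistency: qualified > loaded")
        if self.genes_with_carrier > sum(self.catalog_groups.values()):
            raise ValidationError("manifest inconsistency: carrier genes exceed catalog")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    vcf_path: str,
    sidecar_path: str,
    phenotype_path: str,
    out_dir: str,
    config: Optional[AnalysisConfig] = None,
    catalog_path: Optional[str] = None,
) -> tuple[str, str, str]:
    """Run both analyses end to end; write results, audit and manifest.

    Returns the paths ``(results.tsv, audit.tsv, manifest.json)``.
    Identical inputs and configuration produce byte-identical outputs.
    """
    config = config or AnalysisConfig()
    inputs = load_inputs(vcf_path, sidecar_path, phenotype_path, catalog_path)
    qs, cab = _prepare(inputs, config)
    burden = run_burden_analysis(inputs, config, collapsed=cab)
    collapse = run_collapse_analysis(inputs, config, collapsed=cab)
    results = burden + collapse
    if not results:
        raise ValidationError("no testable outcome or unit: nothing to report")

    os.makedirs(out_dir, exist_ok=True)
    results_path = os.path.join(out_dir, "results.tsv")
    audit_path = os.path.join(out_dir, "audit.tsv")
    manifest_path = os.path.join(out_dir, "manifest.json")
    write_results(results, results_path)
    write_audit(qs, audit_path)
    manifest = RunManifest(
        input_digests={
            "vcf": _sha256(vcf_path),
            "sidecar": _sha256(sidecar_path),
            "phenotypes": _sha256(phenotype_path),
        },
        config={
            "maf_threshold": config.maf_threshold,
            "alpha": config.alpha,
            "ci_level": config.ci_level,
            "burden_mode": config.burden_mode,
            "missing_genotype_policy": config.missing_genotype_policy,
            "seed": config.seed,
        },
        catalog_groups={g: len(v) for g, v in inputs.catalog.groups.items()},
        variants_loaded=len(inputs.variants),
        variants_qualified=qs.n_pass,
        genes_with_carrier=int((cab.carrier.sum(axis=0) > 0).sum()),
        burden_tests_run=len(burden),
        collapse_tests_run=len(collapse),
        n_patients=len(inputs.phenotypes.patient_ids),
    )
    manifest.validate()
    with open(manifest_path, "w", newline="\n") as fh:
        fh.write(manifest.to_json())
    logger.info("wrote %s, %s, %s", results_path, audit_path, manifest_path)
    return results_path, audit_path, manifest_path
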