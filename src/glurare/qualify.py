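"""Rare-variant qualification and gene-level collapsing.

A variant qualifies when it is rare in the reference population
(``pop_af`` null or at most the threshold — a variant absent from the
frequency resource is rarer than any cutoff), is not a synonymous SNV,
and maps to a catalog gene.  Qualifying variants are collapsed into a
per-patient per-gene carrier indicator and per-gene-set burden counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    AnalysisConfig,
    GeneSetCatalog,
    GenotypeMatrix,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CarrierAndBurden",
    "QualifyingVariantSet",
    "build_carrier_and_burden",
    "qualify_variants",
    "write_audit",
]

#: Reason codes, checked in this order; the first failing rule wins.
REASONS = ("pass", "fail_maf", "fail_synonymous", "fail_no_gene", "fail_gene_not_in_catalog")


@dataclass
class QualifyingVariantSet:
    """Per-variant qualification verdicts.

    ``verdicts`` maps variant key -> reason code; ``passing`` preserves
    the input variant order.
    """

    variants: list[VariantRecord]
    verdicts: dict[str, str]

    @property
    def passing(self) -> list[VariantRecord]:
        return [v for v in self.variants if self.verdicts[v.key] == "pass"]

    @property
    def n_pass(self) -> int:
        return sum(1 for v in self.verdicts.values() if v == "pass")

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variant_key": v.key,
                    "gene": v.gene if v.gene is not None else "NA",
                    "consequence": v.consequence,
                    "pop_af": "NA" if v.pop_af is None else format(v.pop_af, ".6g"),
                    "verdict": "pass" if self.verdicts[v.key] == "pass" else "fail",
                    "reason": self.verdicts[v.key],
                }
                for v in self.variants
            ]
        )


def qualify_variants(
    variants: list[VariantRecord],
    config: AnalysisConfig,
    catalog: GeneSetCatalog,
) -> QualifyingVariantSet:
    """Assign a qualification verdict to every variant.

    The frequency cutoff is inclusive (``pop_af <= maf_threshold``
    passes) and a null ``pop_af`` counts as rare.  Synonymous SNVs are
    excluded; so are variants with no gene or a gene outside the
    candidate catalog.
    """
    verdicts: dict[str, str] = {}
    for v in variants:
        if v.pop_af is not None and v.pop_af > config.maf_threshold:
            verdicts[v.key] = "fail_maf"
        elif v.consequence == "synonymous_snv":
            verdicts[v.key] = "fail_synonymous"
        elif v.gene is None:
            verdicts[v.key] = "fail_no_gene"
        elif v.gene not in catalog:
            verdicts[v.key] = "fail_gene_not_in_catalog"
        else:
            verdicts[v.key] = "pass"
    qs = QualifyingVariantSet(list(variants), verdicts)
    logger.info("qualified %d / %d variants", qs.n_pass, len(variants))
    return qs


@dataclass
class CarrierAndBurden:
    """Collapsed per-patient genotype summaries.

    ``carrier[p, g]`` is 1 iff patient ``p`` carries at least one
    qualifying variant in gene ``g``.  ``burden[p, s]`` counts
    qualifying variants per gene set: one per distinct carried site
    (``distinct_sites`` mode) or the summed allele count
    (``allele_dosage`` mode).  Gene sets are the five functional groups
    plus the whole catalog under the name ``all``.
    """

    patient_ids: list[str]
    genes: list[str]
    gene_sets: list[str]  # group names + "all"
    carrier: np.ndarray  # uint8 (n_patients, n_genes)
    burden: np.ndarray  # int32 (n_patients, n_gene_sets)
    n_missing_as_reference: int = 0

    def carrier_vector(self, gene: str) -> np.ndarray:
        return self.carrier[:, self.genes.index(gene)]

    def burden_vector(self, gene_set: str) -> np.ndarray:
        return self.burden[:, self.gene_sets.index(gene_set)]


def build_carrier_and_burden(
    qualifying: QualifyingVariantSet,
    genotypes: GenotypeMatrix,
    catalog: GeneSetCatalog,
    config: AnalysisConfig,
) -> CarrierAndBurden:
    """Collapse qualifying variants into carrier and burden matrices.

    Missing genotypes are treated as homozygous reference under the
    default policy (``as_reference``, counted and logged) or abort the
    run under ``error``.
    """
    genes = list(catalog.all_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    group_names = list(catalog.group_names)
    set_names = group_names + ["all"]
    n_p = len(genotypes.patient_ids)
    key_col = {k: j for j, k in enumerate(genotypes.variant_keys)}

    contrib = np.zeros((n_p, len(genes)), dtype=np.int32)  # per-gene counts
    n_missing = 0
    for v in qualifying.passing:
        if v.key not in key_col:
            raise ValidationError(f"qualifying variant {v.key} absent from genotype matrix")
        col = genotypes.allele_counts[:, key_col[v.key]].astype(np.int32)
        miss = col == MISSING
        if miss.any():
            if config.missing_genotype_policy == "error":
                p = genotypes.patient_ids[int(np.flatnonzero(miss)[0])]
                raise ValidationError(
                    f"missing genotype for patient {p!r} at qualifying variant {v.key}"
                )
            n_missing += int(miss.sum())
            col = np.where(miss, 0, col)
        if config.burden_mode == "distinct_sites":
            contrib[:, gene_index[v.gene]] += (col >= 1).astype(np.int32)
        else:  # allele_dosage
            contrib[:, gene_index[v.gene]] += col

    carrier = (contrib >= 1).astype(np.uint8)
    burden = np.zeros((n_p, len(set_names)), dtype=np.int32)
    for si, name in enumerate(group_names):
        cols = [gene_index[g] for g in catalog.groups[name]]
        burden[:, si] = contrib[:, cols].sum(axis=1)
    burden[:, -1] = burden[:, :-1].sum(axis=1)  # partition additivity

    if n_missing:
        logger.warning("%d missing genotypes treated as homozygous reference", n_missing)
    return CarrierAndBurden(
        patient_ids=list(genotypes.patient_ids),
        genes=genes,
        gene_sets=set_names,
        carrier=carrier,
        burden=burden,
        n_missing_as_reference=n_missing,
    )


def write_audit(qualifying: QualifyingVariantSet, path: str) -> None:
    """Write the per-variant filtering audit trail as TSV."""
    qualifying.audit_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")
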