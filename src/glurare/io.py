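"""Readers and writers for the pipeline's file formats.

Inputs are a multi-sample VCF (genotypes of the candidate-gene variants),
a tab-separated annotation sidecar (variant key, gene, consequence,
reference-population allele frequency), a tab-separated phenotype table
and an optional YAML gene-set catalog.  Results are written as a
deterministic TSV.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .types import (
    CONSEQUENCES,
    MISSING,
    OUTCOMES,
    AssociationResult,
    GeneSetCatalog,
    GenotypeMatrix,
    PhenotypeTable,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_annotation",
    "read_phenotypes",
    "read_vcf",
    "load_catalog",
    "write_results",
    "RESULT_COLUMNS",
]


def _check_vcf_sample_header(path: str) -> None:
    # htslib aborts on duplicated samples with a generic parse failure;
    # inspect the #CHROM line first so the error names the offenders
    with open(path, "rt", errors="replace") as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                if len(set(samples)) != len(samples):
                    dups = sorted({s for s in samples if samples.count(s) > 1})
                    raise ValidationError(
                        f"duplicate sample IDs in VCF {path} (header line {line_no}): {dups}"
                    )
                return
            if not line.startswith("#"):
                break
    raise ValidationError(f"malformed VCF {path}: missing #CHROM header line")


def read_vcf(path: str) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Load a VCF into variant stubs plus a patients x variants matrix.

    Multi-allelic sites are split into one record per alternate allele;
    a genotype contributes to a split record the number of its alleles
    equal to that record's alternate index (so ``1/2`` counts once for
    each of the two alternates).  Genotypes with any missing allele are
    coded :data:`~glurare.types.MISSING`.
    """
    if not os.path.exists(path):
        raise ValidationError(f"VCF not found: {path}")
    _check_vcf_sample_header(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib reports its own diagnostics
        raise ValidationError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise ValidationError(f"VCF {path} has no sample columns (GT required)")
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValidationError(f"duplicate sample IDs in VCF: {dups}")

    records: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    n_missing = 0
    for line_no, site in enumerate(vcf, start=1):
        try:
            genotypes = site.genotypes  # [[allele1, allele2, phased], ...]
        except Exception as exc:
            raise ValidationError(
                f"malformed VCF {path}: cannot decode GT at record {line_no} "
                f"({site.CHROM}:{site.POS})"
            ) from exc
        alleles = np.array([[g[0], g[1]] for g in genotypes], dtype=int)
        missing_mask = (alleles < 0).any(axis=1)
        for alt_index, alt in enumerate(site.ALT, start=1):
            counts = (alleles == alt_index).sum(axis=1).astype(np.int8)
            counts[missing_mask] = MISSING
            n_missing += int(missing_mask.sum())
            records.append(VariantRecord(str(site.CHROM), int(site.POS), str(site.REF), str(alt)))
            columns.append(counts)
    if not records:
        raise ValidationError(f"VCF {path} contains no variant records")
    keys = [r.key for r in records]
    if len(set(keys)) != len(keys):
        dups = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate variant records in VCF: {dups}")
    matrix = GenotypeMatrix(samples, keys, np.column_stack(columns))
    if n_missing:
        logger.warning("VCF %s: %d missing genotype entries", path, n_missing)
    logger.info("loaded %d variants x %d samples from %s", len(keys), len(samples), path)
    return records, matrix


def read_annotation(path: str, variants: list[VariantRecord]) -> list[VariantRecord]:
    """Join the annotation sidecar onto VCF variant stubs by variant key.

    The sidecar is a TSV with header columns ``variant_key``, ``gene``,
    ``consequence`` and ``pop_af``; ``NA`` (or an empty field) marks a
    gene or frequency that is absent from the resource.  Variants missing
    from the sidecar are kept with consequence ``unannotated`` and a null
    frequency.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_key": str, "gene": str}, na_values=["NA", ""])
    required = ["variant_key", "gene", "consequence", "pop_af"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"annotation sidecar {path} missing columns: {missing_cols}")
    if df["variant_key"].duplicated().any():
        dups = sorted(df.loc[df["variant_key"].duplicated(), "variant_key"])
        raise ValidationError(f"duplicate variant keys in sidecar: {dups}")
    bad = set(df["consequence"].dropna()) - CONSEQUENCES
    if bad:
        raise ValidationError(
            f"unknown consequence tokens {sorted(bad)}; allowed vocabulary: {sorted(CONSEQUENCES)}"
        )
    rows = df.set_index("variant_key")
    annotated: list[VariantRecord] = []
    n_unannotated = 0
    for rec in variants:
        if rec.key in rows.index:
            row = rows.loc[rec.key]
            gene = None if pd.isna(row["gene"]) else str(row["gene"])
            consequence = "unannotated" if pd.isna(row["consequence"]) else str(row["consequence"])
            pop_af = None if pd.isna(row["pop_af"]) else float(row["pop_af"])
            annotated.append(rec.with_annotation(gene, consequence, pop_af))
        else:
            n_unannotated += 1
            annotated.append(rec.with_annotation(None, "unannotated", None))
    if n_unannotated:
        logger.info("%d VCF variants absent from sidecar %s", n_unannotated, path)
    return annotated


def read_phenotypes(path: str, genotypes: Optional[GenotypeMatrix] = None) -> PhenotypeTable:
    """Load and validate the binary phenotype table.

    When a genotype matrix is given, every phenotype patient must also be
    present in the VCF (candidate-gene design: genotypes exist for the
    whole cohort).
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if len(df) == 0:
        raise ValidationError(f"phenotype table {path} has no patients")
    table = PhenotypeTable(df)
    if genotypes is not None:
        absent = sorted(set(table.patient_ids) - set(genotypes.patient_ids))
        if absent:
            raise ValidationError(f"phenotype patients absent from VCF: {absent}")
    prev = table.prevalences()
    logger.info(
        "phenotypes %s: %s",
        path,
        ", ".join(f"{k} {v[0]}/{v[1]}" for k, v in prev.items()),
    )
    return table


def load_catalog(path: Optional[str] = None) -> GeneSetCatalog:
    """Load a gene-set catalog from YAML (group name -> gene list), or the
    built-in 26-gene glutamate-receptor default when ``path`` is None."""
    if path is None:
        return GeneSetCatalog()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ValidationError(f"catalog {path} must map group names to gene lists")
    groups = {}
    for name, genes in raw.items():
        if not isinstance(genes, list) or not all(isinstance(g, str) for g in genes):
            raise ValidationError(f"catalog group {name!r} must be a list of gene symbols")
        groups[str(name)] = tuple(genes)
    return GeneSetCatalog(groups)


RESULT_COLUMNS = [
    "unit",
    "unit_kind",
    "outcome",
    "test",
    "statistic",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "p_value",
    "bonferroni_threshold",
    "significant_nominal",
    "significant_adjusted",
    "note",
]

_KIND_ORDER = {"group": 0, "gene": 1}
_OUTCOME_ORDER = {o: i for i, o in enumerate(OUTCOMES)}


def _fmt(x: float) -> str:
    if isinstance(x, bool):
        return str(int(x))
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        return format(x, ".6g")
    return str(x)


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Deterministically ordered results table (outcome, group-before-gene, unit)."""
    if not results:
        raise ValidationError("no association results to write")
    rows = sorted(
        results,
        key=lambda r: (_OUTCOME_ORDER.get(r.outcome, 99), _KIND_ORDER[r.unit_kind], r.unit),
    )
    return pd.DataFrame(
        [
            {
                "unit": r.unit,
                "unit_kind": r.unit_kind,
                "outcome": r.outcome,
                "test": r.test,
                "statistic": _fmt(r.statistic),
                "odds_ratio": _fmt(r.odds_ratio),
                "ci_low": _fmt(r.ci_low),
                "ci_high": _fmt(r.ci_high),
                "p_value": _fmt(r.p_value),
                "bonferroni_threshold": _fmt(r.bonferroni_threshold),
                "significant_nominal": int(r.significant_nominal),
                "significant_adjusted": int(r.significant_adjusted),
                "note": r.note,
            }
            for r in rows
        ],
        columns=RESULT_COLUMNS,
    )


def write_results(results: list[AssociationResult], path: str) -> None:
    """Write association results as TSV; reruns are byte-identical."""
    frame = results_frame(results)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
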