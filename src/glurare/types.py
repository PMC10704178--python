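"""Core domain types shared across the package.

The analysis operates on four kinds of objects: annotated variants, a
patients x variants genotype matrix, a binary phenotype table, and the
catalog of candidate genes partitioned into functional receptor-subunit
groups.  All are plain dataclasses; heavy tabular data lives in numpy
arrays / pandas frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CONSEQUENCES",
    "MISSING",
    "AnalysisConfig",
    "AssociationResult",
    "GeneSetCatalog",
    "GenotypeMatrix",
    "GlurareError",
    "PhenotypeTable",
    "ValidationError",
    "VariantRecord",
    "variant_key",
]


class GlurareError(Exception):
    """Base class for all package errors."""


class ValidationError(GlurareError):
    """Raised when an input file or object violates its contract."""


#: Closed controlled vocabulary for functional consequences.  The rare-variant
#: filter removes ``synonymous_snv`` only; every other class is retained.
CONSEQUENCES = frozenset(
    {
        "synonymous_snv",
        "missense_snv",
        "nonframeshift_substitution",
        "frameshift",
        "stop_gain",
        "splice",
        "other",
        "unannotated",
    }
)

#: Sentinel for a missing diploid genotype in :class:`GenotypeMatrix`.
MISSING: int = -1


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical variant identity ``chrom:pos:ref:alt`` (1-based, pre-normalized)."""
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass(frozen=True)
class VariantRecord:
    """One annotated alternate allele.

    Parameters
    ----------
    chrom, pos, ref, alt
        VCF-style coordinates; ``pos`` is 1-based and multi-allelic sites
        have been split so there is exactly one ``alt`` per record.
    gene
        HGNC symbol, or ``None`` when the variant maps to no gene.
    consequence
        One token from :data:`CONSEQUENCES`.
    pop_af
        Reference-population alternate allele frequency in ``[0, 1]``;
        ``None`` means the variant is absent from the frequency resource.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    consequence: str = "unannotated"
    pop_af: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(
                f"unknown consequence {self.consequence!r}; allowed: {sorted(CONSEQUENCES)}"
            )
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValidationError(
                f"pop_af {self.pop_af} out of [0, 1] for {self.key}"
            )

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    def with_annotation(self, gene: Optional[str], consequence: str, pop_af: Optional[float]) -> "VariantRecord":
        return replace(self, gene=gene, consequence=consequence, pop_af=pop_af)


@dataclass
class GenotypeMatrix:
    """Patients x variants diploid alternate-allele counts.

    ``allele_counts[i, j]`` is the number of copies of variant ``j``'s
    alternate allele carried by patient ``i`` (0, 1 or 2), or
    :data:`MISSING` for an uncalled genotype.
    """

    patient_ids: list[str]
    variant_keys: list[str]
    allele_counts: np.ndarray  # int8, shape (n_patients, n_variants)

    def __post_init__(self) -> None:
        self.allele_counts = np.asarray(self.allele_counts, dtype=np.int8)
        n_p, n_v = self.allele_counts.shape
        if n_p != len(self.patient_ids) or n_v != len(self.variant_keys):
            raise ValidationError("genotype matrix dimensions do not match id lists")
        if len(set(self.patient_ids)) != n_p:
            raise ValidationError("duplicate patient IDs in genotype matrix")
        if len(set(self.variant_keys)) != n_v:
            raise ValidationError("duplicate variant keys in genotype matrix")
        bad = ~np.isin(self.allele_counts, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("allele counts must be 0, 1, 2 or missing")

    @property
    def n_missing(self) -> int:
        return int((self.allele_counts == MISSING).sum())

    def reorder_patients(self, patient_ids: list[str]) -> "GenotypeMatrix":
        """Return a copy with rows in the given patient order."""
        index = {p: i for i, p in enumerate(self.patient_ids)}
        try:
            rows = [index[p] for p in patient_ids]
        except KeyError as exc:
            raise ValidationError(f"patient {exc.args[0]!r} absent from genotype matrix") from exc
        return GenotypeMatrix(list(patient_ids), list(self.variant_keys), self.allele_counts[rows])


#: Column order of the four binary treatment outcomes.
OUTCOMES = ("response", "adr", "behavior_adr", "retention_1yr")


@dataclass
class PhenotypeTable:
    """Binary treatment outcomes, one row per patient.

    The four outcomes are seizure response, any adverse drug reaction
    (ADR), behavioral ADR (a subset of ADR) and 1-year drug retention.
    """

    data: pd.DataFrame  # columns: patient_id + OUTCOMES, all binary

    def __post_init__(self) -> None:
        df = self.data
        required = ["patient_id", *OUTCOMES]
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"phenotype table missing columns: {missing_cols}")
        if len(df) == 0:
            raise ValidationError("phenotype table contains no patients")
        if df["patient_id"].duplicated().any():
            dups = sorted(df.loc[df["patient_id"].duplicated(), "patient_id"])
            raise ValidationError(f"duplicate patient IDs in phenotype table: {dups}")
        for col in OUTCOMES:
            vals = df[col]
            if vals.isna().any():
                raise ValidationError(f"missing values in outcome column {col!r}")
            bad = ~vals.isin([0, 1])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"outcome {col!r} must be coded 0/1; row {row} "
                    f"(patient {df['patient_id'].iloc[row]!r}) has {vals.iloc[row]!r}"
                )
        inconsistent = (df["behavior_adr"] == 1) & (df["adr"] == 0)
        if inconsistent.any():
            ids = sorted(df.loc[inconsistent, "patient_id"])
            raise ValidationError(
                f"behavior_adr = 1 requires adr = 1 (behavioral ADRs are a subset); violated for {ids}"
            )
        self.data = df[required].reset_index(drop=True).astype({c: int for c in OUTCOMES})

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data["patient_id"])

    def outcome(self, name: str) -> np.ndarray:
        if name not in OUTCOMES:
            raise ValidationError(f"unknown outcome {name!r}; expected one of {OUTCOMES}")
        return self.data[name].to_numpy(dtype=int)

    def prevalences(self) -> dict[str, tuple[int, int]]:
        """Map outcome -> (count positive, n patients)."""
        n = len(self.data)
        return {c: (int(self.data[c].sum()), n) for c in OUTCOMES}


#: The 26 HGNC glutamate-receptor genes partitioned into the five
#: functional receptor-subunit groups.
DEFAULT_GENE_GROUPS: dict[str, tuple[str, ...]] = {
    "AMPA": ("GRIA1", "GRIA2", "GRIA3", "GRIA4"),
    "delta": ("GRID1", "GRID2"),
    "kainate": ("GRIK1", "GRIK2", "GRIK3", "GRIK4", "GRIK5"),
    "NMDA": ("GRIN1", "GRIN2A", "GRIN2B", "GRIN2C", "GRIN2D", "GRIN3A", "GRIN3B"),
    "metabotropic": ("GRM1", "GRM2", "GRM3", "GRM4", "GRM5", "GRM6", "GRM7", "GRM8"),
}


@dataclass(frozen=True)
class GeneSetCatalog:
    """Candidate genes partitioned into named functional groups."""

    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_GENE_GROUPS.items()}
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, genes in self.groups.items():
            if not genes:
                raise ValidationError(f"gene group {name!r} is empty")
            overlap = seen & set(genes)
            if overlap:
                raise ValidationError(f"genes assigned to more than one group: {sorted(overlap)}")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate genes within group {name!r}")
            seen |= set(genes)

    @property
    def all_genes(self) -> tuple[str, ...]:
        return tuple(g for genes in self.groups.values() for g in genes)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(self.groups)

    def group_of(self, gene: str) -> Optional[str]:
        for name, genes in self.groups.items():
            if gene in genes:
                return name
        return None

    def __contains__(self, gene: str) -> bool:
        return self.group_of(gene) is not None


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis parameters.

    ``maf_threshold`` is the inclusive rare-variant frequency cutoff;
    ``burden_mode`` chooses whether a homozygous site contributes one
    (``distinct_sites``) or two (``allele_dosage``) to burden counts.
    """

    maf_threshold: float = 0.05
    alpha: float = 0.05
    ci_level: float = 0.95
    burden_mode: str = "distinct_sites"
    missing_genotype_policy: str = "as_reference"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_threshold <= 1.0):
            raise ValidationError(f"maf_threshold {self.maf_threshold} out of [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha {self.alpha} out of (0, 1)")
        if not (0.0 < self.ci_level < 1.0):
            raise ValidationError(f"ci_level {self.ci_level} out of (0, 1)")
        if self.burden_mode not in ("distinct_sites", "allele_dosage"):
            raise ValidationError(f"unknown burden_mode {self.burden_mode!r}")
        if self.missing_genotype_policy not in ("as_reference", "error"):
            raise ValidationError(
                f"unknown missing_genotype_policy {self.missing_genotype_policy!r}"
            )


@dataclass
class AssociationResult:
    """One association test: statistic, odds ratio, CI, p and verdicts.

    ``odds_ratio`` may be ``0`` or ``inf`` at the boundaries of the
    conditional support; ``significant_adjusted`` compares ``p_value``
    against ``bonferroni_threshold`` (alpha divided by family size).
    """

    unit: str
    unit_kind: str  # "gene" | "group"
    outcome: str
    test: str  # "mann_whitney" | "fisher_exact"
    statistic: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    bonferroni_threshold: float
    significant_nominal: bool
    significant_adjusted: bool
    note: str = ""

    def __post_init__(self) -> None:
        if self.unit_kind not in ("gene", "group"):
            raise ValidationError(f"unit_kind must be 'gene' or 'group', got {self.unit_kind!r}")
        if self.significant_adjusted and not self.significant_nominal:
            raise ValidationError("significant_adjusted implies significant_nominal")
        if not (math.isnan(self.p_value) or 0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} out of (0, 1]")
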