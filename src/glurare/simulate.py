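"""Synthetic cohort generation.

Two generators are provided.  :func:`simulate_cohort` draws cohorts with
the statistical structure the analysis assumes — independent binary
outcomes at configurable prevalences (behavioral ADR nested within ADR),
per-gene carrier probabilities, and configurable carrier-versus-outcome
odds ratios — and writes a valid VCF + annotation sidecar + phenotype
table.  :func:`study_fixture` emits a fixed 83-patient cohort whose
outcome counts and per-variant carrier counts match the published
marginal structure of the study (each variant assigned to distinct
patients, heterozygous), which the pipeline can analyse end to end.

:func:`recovery_experiment` repeatedly simulates and re-analyses cohorts
to measure type-I error, CI coverage and odds-ratio recovery.
"""

from __future__ import annotations

import io as _io
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import qualify, stats
from .types import (
    DEFAULT_GENE_GROUPS,
    OUTCOMES,
    AnalysisConfig,
    GeneSetCatalog,
    GenotypeMatrix,
    ValidationError,
    VariantRecord,
)

__all__ = [
    "SimulationConfig",
    "study_fixture",
    "recovery_experiment",
    "simulate_cohort",
]

#: Approximate transcription start per gene (GRCh38-like coordinates);
#: synthetic variant positions are offset from these anchors.  Genomic
#: realism beyond plausible coordinates is a non-goal.
GENE_LOCI: dict[str, tuple[str, int]] = {
    "GRIA1": ("5", 153500000),
    "GRIA2": ("4", 157200000),
    "GRIA3": ("X", 123200000),
    "GRIA4": ("11", 105600000),
    "GRID1": ("10", 85600000),
    "GRID2": ("4", 92300000),
    "GRIK1": ("21", 29500000),
    "GRIK2": ("6", 101400000),
    "GRIK3": ("1", 36800000),
    "GRIK4": ("11", 120500000),
    "GRIK5": ("19", 41900000),
    "GRIN1": ("9", 137100000),
    "GRIN2A": ("16", 9800000),
    "GRIN2B": ("12", 13500000),
    "GRIN2C": ("17", 74800000),
    "GRIN2D": ("19", 48400000),
    "GRIN3A": ("9", 101600000),
    "GRIN3B": ("19", 1000000),
    "GRM1": ("6", 146300000),
    "GRM2": ("3", 51700000),
    "GRM3": ("7", 86700000),
    "GRM4": ("6", 34000000),
    "GRM5": ("11", 88500000),
    "GRM6": ("5", 178900000),
    "GRM7": ("3", 6800000),
    "GRM8": ("7", 126400000),
}

_SNV_CYCLE = (("G", "A"), ("C", "T"), ("A", "G"), ("T", "C"))

#: Outcome prevalences of the 83-patient study cohort.
STUDY_PREVALENCES: dict[str, float] = {
    "response": 14 / 83,
    "adr": 22 / 83,
    "behavior_adr": 14 / 83,
    "retention_1yr": 61 / 83,
}


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic cohort.

    ``effect_map`` maps ``(unit, outcome)`` to a carrier-versus-outcome
    odds ratio; ``unit`` may be a gene symbol or a group name (the odds
    ratio is then applied to every gene in the group).  Carrier status
    per gene is Bernoulli with baseline probability
    ``per_gene_carrier_freq``; for outcome-positive patients the logit is
    shifted by ``log(OR)``, so the population carrier-versus-outcome
    odds ratio equals ``OR`` exactly.
    """

    n_patients: int = 83
    outcome_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(STUDY_PREVALENCES)
    )
    per_gene_carrier_freq: Union[float, dict[str, float]] = 0.15
    effect_map: dict[tuple[str, str], float] = field(default_factory=dict)
    variants_per_gene: int = 2
    maf_range: tuple[float, float] = (0.0005, 0.045)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("n_patients must be >= 2")
        for k, p in self.outcome_prevalences.items():
            if k not in OUTCOMES:
                raise ValidationError(f"unknown outcome {k!r} in prevalences")
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"prevalence {p} out of [0, 1] for {k!r}")
        pa = self.outcome_prevalences.get("adr", 0.0)
        pb = self.outcome_prevalences.get("behavior_adr", 0.0)
        if pb > pa:
            raise ValidationError(
                f"behavior ADR prevalence ({pb:.4g}) exceeds ADR prevalence ({pa:.4g})"
            )
        if self.variants_per_gene < 1:
            raise ValidationError("variants_per_gene must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.1):
            raise ValidationError("maf_range must satisfy 0 <= lo <= hi <= 0.1")
        for (unit, outcome), odds in self.effect_map.items():
            if outcome not in OUTCOMES:
                raise ValidationError(f"unknown outcome {outcome!r} in effect_map")
            if not odds > 0:
                raise ValidationError(f"effect odds ratio for ({unit}, {outcome}) must be > 0")

    def carrier_freq(self, gene: str) -> float:
        if isinstance(self.per_gene_carrier_freq, dict):
            return self.per_gene_carrier_freq.get(gene, 0.0)
        return float(self.per_gene_carrier_freq)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _gene_effects(config: SimulationConfig, catalog: GeneSetCatalog) -> dict[str, dict[str, float]]:
    """Resolve the effect map to gene -> outcome -> log odds ratio."""
    shifts: dict[str, dict[str, float]] = {}
    for (unit, outcome), odds in config.effect_map.items():
        genes = catalog.groups.get(unit, (unit,))
        for g in genes:
            shifts.setdefault(g, {})
            shifts[g][outcome] = shifts[g].get(outcome, 0.0) + math.log(odds)
    return shifts


def _draw_outcomes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    prev = config.outcome_prevalences
    out = {}
    out["response"] = (rng.random(n) < prev.get("response", 0.0)).astype(int)
    adr = (rng.random(n) < prev.get("adr", 0.0)).astype(int)
    pa, pb = prev.get("adr", 0.0), prev.get("behavior_adr", 0.0)
    p_cond = pb / pa if pa > 0 else 0.0
    behavior = ((rng.random(n) < p_cond) & (adr == 1)).astype(int)
    out["adr"] = adr
    out["behavior_adr"] = behavior
    out["retention_1yr"] = (rng.random(n) < prev.get("retention_1yr", 0.0)).astype(int)
    ids = [f"P{i + 1:03d}" for i in range(n)]
    return pd.DataFrame({"patient_id": ids, **{k: out[k] for k in OUTCOMES}})


@dataclass
class _CohortArrays:
    """In-memory cohort before file serialization."""

    phenotypes: pd.DataFrame
    variants: list[VariantRecord]
    genotypes: GenotypeMatrix


def _simulate_arrays(config: SimulationConfig, catalog: GeneSetCatalog, rng: np.random.Generator) -> _CohortArrays:
    pheno = _draw_outcomes(config, rng)
    n = config.n_patients
    shifts = _gene_effects(config, catalog)

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for gene in catalog.all_genes:
        chrom, anchor = GENE_LOCI.get(gene, ("1", 1000000))
        freq = config.carrier_freq(gene)
        k = config.variants_per_gene
        site_records = []
        for j in range(k):
            ref, alt = _SNV_CYCLE[j % len(_SNV_CYCLE)]
            pos = anchor + 101 + 211 * j
            pop_af = float(rng.uniform(*config.maf_range))
            site_records.append(
                VariantRecord(chrom, pos, ref, alt, gene=gene, consequence="missense_snv", pop_af=pop_af)
            )
        # carrier status: Bernoulli with outcome-shifted logit
        if freq <= 0.0:
            carrier = np.zeros(n, dtype=bool)
        else:
            eta = np.full(n, _logit(freq))
            for outcome, shift in shifts.get(gene, {}).items():
                eta = eta + shift * pheno[outcome].to_numpy()
            carrier = rng.random(n) < _expit(eta)
        site_choice = rng.integers(0, k, size=n)
        cols = np.zeros((n, k), dtype=np.int8)
        idx = np.flatnonzero(carrier)
        cols[idx, site_choice[idx]] = 1  # one heterozygous site per carrier
        variants.extend(site_records)
        columns.append(cols)
    counts = np.concatenate(columns, axis=1)
    matrix = GenotypeMatrix(list(pheno["patient_id"]), [v.key for v in variants], counts)
    return _CohortArrays(pheno, variants, matrix)


# ---------------------------------------------------------------------------
# File serialization
# ---------------------------------------------------------------------------

_CHROM_ORDER = {str(c): i for i, c in enumerate([*range(1, 23), "X", "Y"])}


def _write_vcf(arrays: _CohortArrays, path: str) -> None:
    order = sorted(
        range(len(arrays.variants)),
        key=lambda i: (
            _CHROM_ORDER.get(arrays.variants[i].chrom, 99),
            arrays.variants[i].pos,
            arrays.variants[i].alt,
        ),
    )
    contigs = []
    for i in order:
        c = arrays.variants[i].chrom
        if c not in contigs:
            contigs.append(c)
    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=glurare-simulate\n")
    for c in contigs:
        buf.write(f"##contig=<ID={c}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    samples = arrays.genotypes.patient_ids
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
    gt_text = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    for i in order:
        v = arrays.variants[i]
        col = arrays.genotypes.allele_counts[:, i]
        gts = "\t".join(gt_text[int(x)] for x in col)
        buf.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")
    with open(path, "w", newline="\n") as fh:
        fh.write(buf.getvalue())


def _write_sidecar(variants: list[VariantRecord], path: str) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("variant_key\tgene\tconsequence\tpop_af\n")
        for v in variants:
            af = "NA" if v.pop_af is None else format(v.pop_af, ".6g")
            gene = v.gene if v.gene is not None else "NA"
            fh.write(f"{v.key}\t{gene}\t{v.consequence}\t{af}\n")


def _write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False, lineterminator="\n")


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str,
    catalog: Optional[GeneSetCatalog] = None,
    prefix: str = "cohort",
) -> tuple[str, str, str]:
    """Simulate one cohort and write ``(VCF, sidecar, phenotype)`` files.

    The same seed yields byte-identical files.
    """
    catalog = catalog or GeneSetCatalog()
    rng = np.random.default_rng(config.seed)
    arrays = _simulate_arrays(config, catalog, rng)
    os.makedirs(out_dir, exist_ok=True)
    vcf = os.path.join(out_dir, f"{prefix}.vcf")
    sidecar = os.path.join(out_dir, f"{prefix}.annotation.tsv")
    pheno = os.path.join(out_dir, f"{prefix}.phenotypes.tsv")
    _write_vcf(arrays, vcf)
    _write_sidecar(arrays.variants, sidecar)
    _write_phenotypes(arrays.phenotypes, pheno)
    return vcf, sidecar, pheno


# ---------------------------------------------------------------------------
# Fixed study fixture
# ---------------------------------------------------------------------------

#: The seven observed variants: (gene, cDNA offset used as position offset,
#: ref, alt, consequence, sidecar pop_af or None, carriers split by the
#: variant's published stratifier).  GRID1 counts are stratified by ADR,
#: GRIN3A counts by behavioral ADR; every carrier is a distinct patient.
_FIXTURE_VARIANTS = [
    ("GRID1", 1585, "G", "A", "missense_snv", 0.012, "adr", 5, 3),
    ("GRID1", 1287, "CA", "GG", "nonframeshift_substitution", None, "adr", 2, 1),
    ("GRIN3A", 322, "C", "G", "missense_snv", 0.003, "behavior_adr", 1, 0),
    ("GRIN3A", 55, "C", "T", "missense_snv", 0.008, "behavior_adr", 0, 1),
    ("GRIN3A", 1462, "A", "G", "missense_snv", 0.021, "behavior_adr", 1, 3),
    ("GRIN3A", 1438, "C", "G", "missense_snv", 0.004, "behavior_adr", 3, 1),
    ("GRIN3A", 2501, "GT", "CA", "nonframeshift_substitution", None, "behavior_adr", 2, 7),
]


def _fixture_arrays() -> _CohortArrays:
    n = 83
    ids = [f"P{i + 1:03d}" for i in range(n)]
    # patients 1-14: behavioral ADR (hence ADR); 15-22: ADR only; 23-83: no ADR
    behavior = np.zeros(n, dtype=int)
    behavior[:14] = 1
    adr = np.zeros(n, dtype=int)
    adr[:22] = 1
    response = np.zeros(n, dtype=int)
    response[[0, 7, 14, 19, 22, 29, 39, 44, 49, 54, 59, 64, 69, 74]] = 1
    retention = np.ones(n, dtype=int)
    retention[11:22] = 0
    retention[72:83] = 0
    pheno = pd.DataFrame(
        {
            "patient_id": ids,
            "response": response,
            "adr": adr,
            "behavior_adr": behavior,
            "retention_1yr": retention,
        }
    )

    variants: list[VariantRecord] = []
    counts = np.zeros((n, len(_FIXTURE_VARIANTS)), dtype=np.int8)
    # carrier pools (0-based patient indices), consumed left to right so all
    # carriers are distinct patients
    pools = {
        ("adr", 1): list(range(14, 22)),  # ADR without behavioral ADR
        ("adr", 0): list(range(22, 27)),  # variant-free below index 27
        ("behavior_adr", 1): list(range(0, 14)),
        ("behavior_adr", 0): list(range(26, 83)),
    }
    cursors = {k: 0 for k in pools}
    for j, (gene, offset, ref, alt, csq, af, strat, n_pos, n_neg) in enumerate(_FIXTURE_VARIANTS):
        chrom, anchor = GENE_LOCI[gene]
        variants.append(VariantRecord(chrom, anchor + offset, ref, alt, gene=gene, consequence=csq, pop_af=af))
        for stratum, n_car in ((1, n_pos), (0, n_neg)):
            key = (strat, stratum)
            for _ in range(n_car):
                counts[pools[key][cursors[key]], j] = 1
                cursors[key] += 1
    matrix = GenotypeMatrix(ids, [v.key for v in variants], counts)
    return _CohortArrays(pheno, variants, matrix)


def study_fixture(out_dir: str, prefix: str = "fixture") -> tuple[str, str, str]:
    """Write the fixed 83-patient study cohort as ``(VCF, sidecar, phenotype)``.

    Outcome counts are (14, 22, 14, 61) of 83 for response, ADR,
    behavioral ADR and 1-year retention; the seven observed GRID1/GRIN3A
    variants carry their published per-stratum carrier counts, one
    heterozygous variant per distinct patient.  Deterministic: repeated
    calls produce byte-identical files.
    """
    arrays = _fixture_arrays()
    os.makedirs(out_dir, exist_ok=True)
    vcf = os.path.join(out_dir, f"{prefix}.vcf")
    sidecar = os.path.join(out_dir, f"{prefix}.annotation.tsv")
    pheno = os.path.join(out_dir, f"{prefix}.phenotypes.tsv")
    _write_vcf(arrays, vcf)
    _write_sidecar(arrays.variants, sidecar)
    _write_phenotypes(arrays.phenotypes, pheno)
    return vcf, sidecar, pheno


# ---------------------------------------------------------------------------
# Recovery / calibration experiment
# ---------------------------------------------------------------------------


def recovery_experiment(
    config: SimulationConfig,
    replicates: int,
    gene: str = "GRIN3A",
    outcome: str = "behavior_adr",
    true_or: Optional[float] = None,
    analysis: Optional[AnalysisConfig] = None,
    catalog: Optional[GeneSetCatalog] = None,
) -> pd.DataFrame:
    """Simulate ``replicates`` cohorts and re-analyse one gene-collapse test.

    Each replicate draws a cohort from ``config`` (seeds derived from
    ``config.seed``), runs it through qualification and collapsing, and
    computes the Fisher collapse test for ``gene`` versus ``outcome``:
    two-sided p, conditional-MLE odds ratio and exact CI.

    Returns a one-row summary with the median odds-ratio estimate,
    empirical CI coverage of ``true_or`` (taken from the effect map when
    not given), and rejection rates at the nominal level and at the
    26-gene Bonferroni threshold.  With a single replicate the coverage
    and rejection columns are reported as NaN.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    catalog = catalog or GeneSetCatalog()
    analysis = analysis or AnalysisConfig()
    if true_or is None:
        true_or = config.effect_map.get((gene, outcome), 1.0)
        group = catalog.group_of(gene)
        if group is not None and (group, outcome) in config.effect_map:
            true_or *= config.effect_map[(group, outcome)]
    seeds = np.random.SeedSequence(config.seed).generate_state(replicates) % (2**31)

    psi_hat = np.empty(replicates)
    p_vals = np.empty(replicates)
    covered = np.zeros(replicates, dtype=bool)
    for r in range(replicates):
        rng = np.random.default_rng(int(seeds[r]))
        arrays = _simulate_arrays(config, catalog, rng)
        qs = qualify.qualify_variants(arrays.variants, analysis, catalog)
        cab = qualify.build_carrier_and_burden(qs, arrays.genotypes, catalog, analysis)
        y = arrays.phenotypes[outcome].to_numpy()
        carrier = cab.carrier_vector(gene)
        t = stats.TwoByTwoTable(
            int(((y == 1) & (carrier == 1)).sum()),
            int(((y == 1) & (carrier == 0)).sum()),
            int(((y == 0) & (carrier == 1)).sum()),
            int(((y == 0) & (carrier == 0)).sum()),
        )
        p_vals[r] = stats.fisher_two_sided_p(t)
        psi_hat[r] = stats.conditional_mle_or(t)
        lo, hi = stats.exact_or_ci(t, analysis.ci_level)
        covered[r] = lo <= true_or <= hi

    bonf = stats.bonferroni(analysis.alpha, len(catalog.all_genes))
    finite = psi_hat[np.isfinite(psi_hat) & (psi_hat > 0)]
    single = replicates == 1
    return pd.DataFrame(
        [
            {
                "gene": gene,
                "outcome": outcome,
                "replicates": replicates,
                "true_or": true_or,
                "median_psi_hat": float(np.median(psi_hat)),
                "n_boundary_psi": int(replicates - len(finite)),
                "ci_coverage": math.nan if single else float(covered.mean()),
                "reject_nominal": math.nan if single else float((p_vals < analysis.alpha).mean()),
                "reject_bonferroni": math.nan if single else float((p_vals < bonf).mean()),
            }
        ]
    )
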