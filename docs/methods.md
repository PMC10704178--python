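# Methods

## Setting

`glurare` analyses a candidate-gene pharmacogenetic design: a cohort of
epilepsy patients treated with perampanel (PER), an AMPA-receptor
antagonist, with four dichotomized treatment outcomes — seizure response,
any adverse drug reaction (ADR), behavioral ADR (irritation, violent
behavior or psychosis; by definition a subset of ADR) and 1-year drug
retention — and genotypes restricted to the 26 HGNC glutamate-receptor
genes, partitioned into five functional subunit groups (AMPA *GRIA1-4*,
delta *GRID1-2*, kainate *GRIK1-5*, NMDA *GRIN1/GRIN2A-D/GRIN3A-B*,
metabotropic *GRM1-8*).

## Variant qualification

A variant qualifies when all of the following hold:

* reference-population allele frequency ≤ `maf_threshold`
  (default 0.05, inclusive), where a null frequency — absent from the
  resource — counts as rare: a variant never observed in a large
  reference panel is rarer than any cutoff, and discarding novel variants
  would defeat a rare-variant design;
* its consequence is not `synonymous_snv` (the vocabulary is closed:
  missense, non-frameshift substitution, frameshift, stop-gain, splice,
  other, unannotated all pass);
* it maps to a catalog gene.

Rules are applied in a fixed order (frequency, consequence, gene) so every
variant receives a single machine-readable reason code, emitted in the
audit TSV. Variant identity is the canonical `chrom:pos:ref:alt` key with
1-based coordinates; inputs are assumed pre-normalized and multi-allelic
sites are split on load, conserving per-sample alternate-allele dosage.

## Collapsing

Per patient, gene *g* is scored carrier (1) if at least one qualifying
variant in *g* has allele count ≥ 1. Per gene set *S* (the five groups
and the whole 26-gene catalog), burden is the number of distinct carried
qualifying sites in *S* (`distinct_sites`, default) or the summed allele
count (`allele_dosage`). Distinct-sites is the default because a count of
"rare variants" most naturally counts variant sites, and published
per-variant tallies in this design report carriers per site; the dosage
mode is a config flag. Because the five groups partition the catalog, the
whole-set burden equals the sum of the group burdens (asserted as a
property test). Missing genotypes default to homozygous reference with a
logged count (`missing_genotype_policy="as_reference"`); a strict mode
aborts instead. Missingness is otherwise not modeled.

## Tests

**Gene collapse (Fisher exact).** For each outcome and gene, the 2×2
table of carrier status by outcome is tested with the two-sided Fisher
exact test under the minimum-likelihood summation rule: the p-value sums
central hypergeometric probabilities of all tables with the observed
margins whose probability does not exceed the observed table's (the
convention of R's `fisher.test` and scipy). The reported effect is the
*conditional maximum-likelihood odds ratio*: the noncentrality ψ of the
noncentral hypergeometric law of the first cell that solves
E[A | margins, ψ] = a. The conditional mean is strictly increasing in ψ,
so the root is unique; it is found by bracket expansion and Brent's
method on log ψ (xtol 1e-12). Note the conditional MLE is shrunk relative
to the sample cross-product ratio (e.g. 4.64 vs 4.75 on the headline
table here). The CI is the central exact (conditional) interval by tail
inversion: the lower endpoint solves P(A ≥ a | ψ) = (1−level)/2 and the
upper solves P(A ≤ a | ψ) = (1−level)/2. At the support boundaries the
estimate and the corresponding endpoint are 0 or +∞, flagged, with no
continuity corrections anywhere. A zero-margin table is uninformative and
returns p = 1. Genes with zero carriers are emitted as untestable rows —
not p = 1 — but still count toward the Bonferroni family size (26 by
default), matching how a fixed candidate list is corrected.

**Group burden (Mann–Whitney U).** For each outcome, per-patient burden
counts are compared between outcome-positive and -negative patients. U is
computed with midranks. Exact mode evaluates the permutation distribution
of U given the pooled multiset by a dynamic program over doubled
midranks (integers), so ties are handled exactly; by symmetry of the
permutation distribution about n₁n₂/2 the two-sided p is the symmetric
tail mass. Auto mode uses exact for tie-free pooled samples of ≤ 25
observations (an implementation choice; burden counts are heavily tied,
so study-sized data take the approximation) and otherwise the normal
approximation with tie-corrected variance and a 0.5 continuity
correction. The whole-catalog test is its own single-test family; the
five subgroup tests form a Bonferroni family of five.

Because the Mann–Whitney test has no native odds ratio, a clearly-labeled
*companion* logistic OR per unit burden count (two-parameter logistic fit
by Newton–Raphson, Wald CI from observed information) is attached for
effect-direction reading only; significance always comes from the rank
test. Perfect or quasi-complete separation is detected up front and
flagged with an infinite/zero OR and no CI; constant counts pin the OR
to 1.

**Multiplicity.** Bonferroni is applied per analysis family within each
outcome — families of 5 (subgroups) and 26 (genes), i.e. thresholds 0.01
and 0.05/26 ≈ 1.92×10⁻³ at α = 0.05 — by thresholding, not p-value
inflation; `min(1, m·p)` is recoverable from the emitted columns.
Families are not pooled across the four outcomes, matching the per-family
thresholds this design reports.

## Synthetic cohorts

`simulate_cohort` emulates the statistical structure the analysis
assumes, not real exomes. Outcomes are Bernoulli at configurable
prevalences — defaults are the study cohort's margins (response 14/83,
ADR 22/83, behavioral ADR 14/83, retention 61/83) — mutually independent
except that behavioral ADR is drawn as a sub-event of ADR with
conditional probability chosen to hit its marginal. Carrier status per
gene is Bernoulli with baseline probability `per_gene_carrier_freq`
(default 0.15, a compromise between the two observed genes' carrier
fractions, 11/83 and 19/83); for outcome-positive patients the logit is
shifted by log OR from the effect map, so the population
carrier-versus-outcome odds ratio equals the configured value exactly —
which is what makes the CI-coverage experiment well-defined. A
group-level effect applies the same shift to each gene in the group.
Carriers receive one heterozygous variant at one of
`variants_per_gene` sites (default 2) chosen uniformly; sidecar
frequencies are uniform on `maf_range` (default 0.0005–0.045, inside the
rare cutoff). Not modeled: linkage disequilibrium, population structure,
realistic site-frequency spectra, compound heterozygotes, genomic
coordinates beyond plausible per-gene anchors, and any outcome
correlation beyond the ADR nesting. Passing simulation-based tests
therefore validates the inference machinery under the design's own
assumptions, not robustness to real-exome artifacts.

`study_fixture` is deterministic: 83 patients with the exact outcome
margins above and the seven observed GRID1/GRIN3A variants assigned at
their published per-stratum carrier counts, one heterozygous variant per
distinct patient. The distinct-carrier assumption is load-bearing: it is
what makes the collapsed GRIN3A table (7,7,12,57) reproduce the published
OR 4.64 and CI (1.16, 18.97); compound carriers were not published.
Cross-outcome joint structure beyond the ADR nesting is arbitrary (fixed
index patterns) and only the published margins should be read from it.

`recovery_experiment` re-analyses replicate cohorts through the same
qualification/collapse/test functions the pipeline uses, in memory, and
reports median conditional-MLE OR, empirical CI coverage and rejection
rates at the nominal and 26-gene Bonferroni thresholds. With the default
null configuration, 2000 replicates at n = 83 run in a few seconds;
coverage at OR = 4 is checked at n = 830 with carrier frequency 0.2 over
400 replicates (problem sizes chosen to keep Monte-Carlo error near one
percentage point while the suite stays quick).

## Numerical choices

* All hypergeometric weights are computed in log space via `gammaln` and
  normalized by max-subtraction; probability comparisons for the
  two-sided rule use a 1e-7 relative tolerance so exactly-equally-likely
  tables are included despite float round-off (verified against
  exact-fraction enumeration for every table with n ≤ 30).
* Root-finding for ψ̂ and CI endpoints brackets on log ψ by doubling and
  solves with Brent's method; deterministic, no randomness anywhere in
  the analysis path.
* Seeds: a single integer seeds each simulation; replicate seeds derive
  from `numpy.random.SeedSequence`. Identical seeds give byte-identical
  output files.
* Result TSVs are written with fixed 6-significant-digit formatting and
  a fixed row order (outcome, groups before genes, unit) so reruns are
  byte-identical.

## Known limitations

* No covariates, no weighting (MAF or functional), no variance-component
  (SKAT-type) tests — unweighted counts and presence/absence only, as the
  design prescribes.
* Sex-chromosome ploidy is not special-cased; all genotypes are treated
  as diploid.
* The companion logistic OR is descriptive; with study-sized cohorts and
  sparse counts its Wald CI can be unstable near separation, which is why
  it is flagged rather than trusted.
* The printed group-level burden odds ratios of the motivating study are
  not reproducible from published data and are not targeted; the same
  holds for one published gene-level OR whose reconstructed table yields
  a different conditional MLE.
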