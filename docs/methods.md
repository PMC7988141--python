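# Methods

This note documents the statistical procedures, the synthetic-data
model, the numerical choices, and the design decisions taken where the
design was genuinely open.

## Exact tests

**Fisher's exact test.** Two-sided p-values use the minimum-likelihood
rule: with margins fixed, p is the sum of hypergeometric probabilities
of all tables whose probability does not exceed that of the observed
table, with a 1×10⁻⁷ relative tolerance for floating-point ties. The
implementation sums log-gamma-based pmf vectors directly over the
support, which is two orders of magnitude faster than generic library
calls on large allelic tables and makes permutation re-scans of whole
panels affordable; agreement with exact-arithmetic enumeration is
tested to 10⁻¹² over exhaustive small-margin sweeps. The odds-ratio
point estimate is the conditional MLE with the exact tail-inversion
95% interval (scipy's `odds_ratio`); a Haldane-corrected Woolf
estimate is available (`or_method="woolf"`) and is used inside large
replicated scans where thousands of exact CIs would dominate runtime.
Zero cells yield open CI bounds; a table with no carriers on either
side is reported as p = 1, OR = 1, fully open interval.

**Hardy–Weinberg exact test.** The standard conditional formulation:
given the allele counts, heterozygote counts of matching parity are
assigned probability ∝ 2^h / (n_rr! h! n_aa!), and p sums those
configurations no more probable than the observed one. No mid-p
adjustment. Sites fail the scan profile when p < 10⁻⁵, computed on
controls only by default (`hwe_cohort="pooled"` switches to the pooled
cohort; which cohort a given study used is rarely stated).

**Allele-balance and missingness tests.** The heterozygous
alt-read-balance test is the exact two-sided binomial test at θ = ½
(fail when p ≤ 10⁻⁶, the strict direction of the stated rule).
"Differential missingness between cases and controls" is
under-specified as printed; it is implemented as the exact binomial
test of the case missing count against the pooled missingness
proportion — exact, direction-free, and vacuous (p = 1) when nothing
is missing.

## Site-QC battery and profiles

Each site is evaluated against every rule of its profile and all
failure reasons are returned, not just the first. Values exactly at a
printed `>=`/`<=` bound pass. The `exwas` profile: GQ ≥ 30, QUAL ≥ 30,
MQ ≥ 40, FS ≤ 60 (SNV) / 200 (indel), RPRS ≥ −2, MQRS ≥ −8, caller
PASS, het alt fraction in [0.3, 0.8], balance p > 10⁻⁶, differential
missingness p ≥ 10⁻⁶, < 1% missing per cohort, < 0.5% failed calls per
cohort, HWE p ≥ 10⁻⁵, external reference coverage ≥ 50%, and (when the
variant is externally observed) external z ≥ −0.2 and external MQ ≥ 30.
The `collapsing` profile differs exactly where the two analyses differ:
external coverage ≥ 25%, external z ≥ −2.0, an additional homozygous
alt-fraction ≥ 0.8 rule and a CCDS-transcript requirement, and no
HWE or failed-call rules.

Sample harmonisation removes contamination > 4%, European-ancestry
probability < 0.98, CCDS ≥10× coverage ≤ 95%, sex discordance (consumed
as a precomputed flag; X:Y coverage calling is upstream), a precomputed
relatedness flag when present, and PC1–4 outliers beyond 4 SD. PC
moments are computed on the post-ancestry-filter cohort in a single
pass (no iterative re-computation); the limit is configurable.
Gender matching keeps the under-represented control sex in full and
downsamples the other so the retained male fraction hits the target
within one sample, seeded.

## ExWAS

The scan codes exposure allelically (alt/ref chromosomes), matching
how allele frequencies are reported; dominant-carrier coding is a
config option. Variants enter if observed in ≥ 12 individuals —
"observed" counts carriers by default, with `count_rule="genotyped"`
as the alternative reading of that rule. Firth regression (sex, age,
PC1–4, standardised internally for conditioning) refits variants below
a configurable Fisher-p threshold (default 0.01). The Firth solver is
Newton iteration on the Jeffreys-penalised score with step-halving on
the penalised likelihood, declared converged when the adjusted score
max-norm falls below 10⁻⁸; non-convergence raises, never returns a
silent estimate. The Firth p is the penalised LRT (1 df), not Wald.
In the saturated 2×2 case the Firth estimate equals the Haldane
½-corrected log-OR, which the tests verify to 10⁻⁶.

## Collapsing

Qualifying-variant models are declarative (consequence set, internal
MAF bound, external popmax bound, optional intolerant-region flag,
zygosity). The shipped 11-model suite (10 non-synonymous + synonymous
negative control) is an approximation assembled from the field's usual
tiers; real studies' exact model tables are rarely recoverable from a
primary text, so the suite is fully user-overridable and labelled as a
default, not a reproduction. Recessive carriers need two qualifying
alleles counted phase-unaware — two heterozygous qualifying variants
count even if they could be in cis; phasing is out of scope and this
is a documented limitation. The CMH statistic uses the hypergeometric
(N−1) variance without continuity correction, so a single stratum
equals Pearson's chi-square times (N−1)/N; a continuity-corrected
variant is available by flag.

## Replication and calibration

Stouffer combination uses equal weights by default (√N weights by
config); a study's direction is the sign of its log OR, with OR = 1
contributing zero. Replication candidates are selected at strict
p < 0.01. The permutation null permutes case/control labels (case
count preserved; the cohort composition itself is held fixed rather
than re-gender-matched per permutation), re-runs the exact test on the
identical variant set, and takes the element-wise median of rank-sorted
p-vectors as the expected distribution — this is what makes a sparse,
heavily imbalanced scan calibratable at all, since the discreteness of
the exact test appears identically in observed and expected. λ is the
no-intercept least-squares slope of observed on expected 1-df χ²
quantiles (the classical median-ratio λ is reported alongside);
p-values are clipped to [10⁻³⁰⁰, 1] before the quantile transform.

## Architecture statistics

Carrier classification applies the dedicated QC sub-battery (alt
fraction ≥ 0.3, balance p > 0.001, GQ ≥ 30, QUAL ≥ 30, coding
transcript) and then per-gene rules: PTVs at popmax ≤ 0.05%, ultra-rare
(popmax = 0) missense where missense is interpretable, and
curated-pathogenic (ClinVar flag consumed as an annotation column, not
fetched) noncoding variants for the RNA gene. Flags are non-exclusive
and order-independent. The telomere model is
logit Pr(carrier) = β₀ + β₁·TL + β₂·age + β₃·sex, fitted by ML with a
Firth fallback under separation; TL enters untransformed (kilobases) by
default, and the per-SD OR is reported alongside because a per-unit OR
is meaningless without a unit convention. Clinical columns are
median-imputed over the whole cohort in one pass (not group-wise), then
compared by Mann–Whitney (exact for combined n ≤ 20, else tie-corrected
normal approximation with continuity correction); binary traits use
Fisher's exact test. Survival uses product-limit estimates and the
unweighted log-rank test; with zero events the statistic is reported as
undefined (NaN) rather than fabricated.

## Synthetic-cohort model

Controls draw genotypes per variant as Binomial(2, AF) under HWE;
case enrichment at effect loci acts on the allele level via
p_case = OR·q/(1−q+OR·q), then alleles pair into genotypes. Burden
genes use the same odds transform on the *carrier* frequency
(default control carrier frequency 3×10⁻⁴) and assign each carrier one
heterozygous qualifying variant drawn uniformly from the gene's QV set.
The modifier allele (control AF 11%) is drawn per case carrier class
with class-specific odds ratios (2.13 for burden-gene carriers, 2.95
for index carriers, 4.47 for the remaining cases). The replication
generator multiplies effect-locus control AFs by an inflation factor
(≈3.85 brings 0.78% to ≈3.0%), erroring if any effect AF would reach
0.5, and carries the discovery odds ratio over unchanged — its case
frequencies therefore follow from that OR, not from any separately
printed covariate-adjusted replication estimate. Telomere lengths are
log-normal (median 6.5 kb, log-SD 0.15) with the carrier median
multiplied by (1 − shortening), default 12% within the 10–15% band;
survival is exponential (cohort median 39.4 months, burden carriers'
scale divided by a hazard ratio of 1.6). Consequence classes are
categorical per variant (5% PTV / 65% missense / 30% synonymous — a
modelling default, explicitly not an empirical spectrum); the null AF
spectrum is log-uniform on [10⁻⁴, 0.1]; 20% of variants fall in
"intolerant regions". Effect variants are sampled independently: no
linkage disequilibrium, no haplotype structure, no sequence content,
no pedigrees. Identical (config, truth, seed) reproduces cohorts byte
for byte.

QC spikes inject one defect per filter class. Metric-level spikes
(GQ, QUAL, MQ, FS, rank sums, caller status, alt fractions, external
metrics, failed-call fraction) overwrite the annotation value; data-level
spikes rewrite genotypes (heterozygote excess for HWE, matched
missingness in both cohorts for the per-cohort missingness rule, a few
missing cases against none in controls for differential missingness —
the latter separable from the 1% missingness rule only when the control
cohort is large, which is why the QC battery experiment runs at full
control size). `SPIKE_EXPECTED_REASONS` records each class's intended
reason codes; the "missingness" spike intentionally triggers both
per-cohort codes.

**What passing tests do and do not show.** The generator matches the
study's marginal structure (imbalance, rarity, effect sizes, QC defect
classes) but real exomes add LD, population substructure correlated
with batch, coverage heterogeneity correlated with capture design,
and annotation error; recovery of embedded truths here validates the
statistical machinery, not robustness to those artefacts.

## Replicated experiments and problem sizes

`rarewas.experiments` fixes the study conditions used by the test
suite and the reproduction script: null calibration on 752 cases /
10,000 controls / 5,000 variants with 10 permutations (type-I error
measured over AF ≥ 1% variants, where the exact test's discreteness is
negligible — over all ≥12-carrier variants the exact test is
conservative by construction, rejecting at ≈0.039 rather than 0.05);
index-variant recovery over 100 replicates at full case and control
size (752 / 119,055) on 200-variant panels, because the variant's
top-rank stability depends on control-side precision; burden-gene
ranking over 50 replicates at full control size on 240-variant /
60-gene panels; the synonymous panel λ on a 300-gene null cohort
restricted to testable genes (≥ 1 qualifying carrier); telomere-model
power at n = 500 + 500. Sub-seeds all derive from one master seed and
stay below 2³¹.

## Known limitations

- No mixed models or saddlepoint correction for extreme imbalance; the
  permutation null is the calibration instrument instead.
- No variance-component (SKAT-type) or weighted burden tests.
- Recessive collapsing is phase-unaware (in-cis pairs overcount).
- The annotation is trusted as given; no re-annotation, liftover,
  kinship, ancestry or contamination estimation (all consumed as
  precomputed inputs).
- The VCF writer materialises per-call fields row by row and is meant
  for desk-scale cohorts; the TSV genotype matrix is the bulk format.
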