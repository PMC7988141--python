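"""Site- and sample-level quality control and cohort harmonisation.

Variant sites are screened with a battery of per-site filters (caller
metrics, read-balance tests, Hardy-Weinberg equilibrium, differential
missingness, external reference-population coverage) before any
association testing.  Two threshold profiles are shipped: ``exwas`` for
the variant-level scan and ``collapsing`` for the gene-burden analysis.
The profiles differ where the underlying study designs differ: the
collapsing profile relaxes the external coverage requirement (>=25%
instead of >=50%), relaxes the external z-score bound (>= -2.0 instead
of >= -0.2), adds a homozygous alt-read-fraction rule and a CCDS
transcript requirement, and drops the HWE and failed-call-fraction
rules.

Sample-level harmonisation removes contaminated, sex-discordant,
ancestry-outlying, under-covered and PC-outlying samples, and can
gender-match the control cohort to the case cohort by seeded
downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "SiteQCMetrics",
    "QCThresholds",
    "QCDecision",
    "EXWAS_PROFILE",
    "COLLAPSING_PROFILE",
    "hwe_exact_test",
    "binomial_balance_test",
    "differential_missingness_test",
    "evaluate_site",
    "run_site_qc",
    "filter_samples",
    "gender_match_controls",
]


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg genotype proportions.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts (same parity as the observed count, since
    allele counts are fixed) whose conditional probability does not
    exceed that of the observed configuration.  No mid-p adjustment.

    Returns a p-value in (0, 1].
    """
    for v in (n_hom_ref, n_het, n_hom_alt):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all-zero genotype counts")
    n_a = 2 * n_hom_alt + n_het      # alt allele count
    n_b = 2 * n_hom_ref + n_het
    # heterozygote counts share the parity of the minor allele count
    rare = min(n_a, n_b)
    het = np.arange(rare % 2, rare + 1, 2)
    # P(het | n, allele counts) ∝ 2^het / (hom_r! het! hom_a!)
    if n_a <= n_b:
        hom_a = (n_a - het) // 2
        hom_r = n - het - hom_a
    else:
        hom_r = (n_b - het) // 2
        hom_a = n - het - hom_r
    logp = (
        het * np.log(2.0)
        - gammaln(hom_r + 1)
        - gammaln(het + 1)
        - gammaln(hom_a + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.flatnonzero(het == n_het)[0]]
    return float(min(1.0, p[p <= obs * (1.0 + 1e-12)].sum()))


def binomial_balance_test(alt_reads: int, total_reads: int) -> float:
    """Exact two-sided binomial test of allele balance against 0.5.

    Used on heterozygous calls: an extreme departure of the alternate
    read fraction from 50% indicates a miscalled or artefactual site.
    """
    if not (0 <= alt_reads <= total_reads) or total_reads <= 0:
        raise ValueError("require 0 <= alt_reads <= total_reads, total > 0")
    return float(stats.binomtest(alt_reads, total_reads, 0.5).pvalue)


def differential_missingness_test(
    miss_cases: int, n_cases: int, miss_controls: int, n_controls: int
) -> float:
    """Exact binomial test of case/control missingness imbalance.

    The case missing count is tested against the pooled missingness
    proportion with an exact two-sided binomial test.  With zero pooled
    missingness the test is vacuous and returns 1.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("cohort sizes must be positive")
    if not (0 <= miss_cases <= n_cases and 0 <= miss_controls <= n_controls):
        raise ValueError("missing counts inconsistent with cohort sizes")
    pooled = (miss_cases + miss_controls) / (n_cases + n_controls)
    if pooled == 0.0:
        return 1.0
    return float(stats.binomtest(miss_cases, n_cases, pooled).pvalue)


# ---------------------------------------------------------------------------
# site QC battery
# ---------------------------------------------------------------------------

@dataclass
class SiteQCMetrics:
    """Per-site metrics consumed by the QC battery.

    Read-level and caller metrics are produced upstream (variant caller,
    reference-population summaries) and consumed here as numbers.
    """

    is_snv: bool = True
    coverage_fraction_cases: float = 1.0      # fraction of cases with >=10x
    coverage_fraction_controls: float = 1.0
    gq: float = 99.0
    qual: float = 999.0
    mq: float = 60.0
    fs: float = 0.0
    rprs: float = 0.0
    mqrs: float = 0.0
    caller_pass: bool = True
    alt_fraction_het: float = 0.5             # mean alt-read fraction, het calls
    alt_fraction_hom: float = 1.0             # mean alt-read fraction, hom-alt calls
    alt_reads_het: int = 15                   # representative het call
    total_reads_het: int = 30
    failed_fraction_cases: float = 0.0        # fraction of calls failing call-level QC
    failed_fraction_controls: float = 0.0
    external_observed: bool = True
    external_coverage_fraction: float = 1.0
    external_mq: float = 60.0
    external_zscore: float = 0.0
    ccds_transcript: bool = True
    genotype_counts_cases: tuple = (0, 0, 0)    # (hom-ref, het, hom-alt)
    genotype_counts_controls: tuple = (0, 0, 0)
    miss_cases: int = 0
    n_cases: int = 1
    miss_controls: int = 0
    n_controls: int = 1


@dataclass
class QCThresholds:
    """One numeric bound per site metric, plus the profile tag."""

    profile: str = "exwas"
    min_gq: float = 30.0
    min_qual: float = 30.0
    min_mq: float = 40.0
    max_fs_snv: float = 60.0
    max_fs_indel: float = 200.0
    min_rprs: float = -2.0
    min_mqrs: float = -8.0
    alt_fraction_het_range: tuple = (0.3, 0.8)
    min_alt_fraction_hom: float | None = None   # collapsing only
    min_balance_p: float = 1e-6                  # fail if p <= bound (strict '>')
    max_diff_missingness_p: float = 1e-6         # fail if p < bound
    min_hwe_p: float | None = 1e-5               # fail if p < bound; None disables
    max_missing_fraction: float = 0.01           # per cohort, fail if >= bound
    max_failed_fraction: float | None = 0.005    # per cohort; None disables
    min_external_coverage: float = 0.50
    min_external_zscore: float = -0.2
    min_external_mq: float = 30.0
    require_ccds: bool = False
    hwe_cohort: str = "controls"                 # "controls" or "pooled"


EXWAS_PROFILE = QCThresholds(profile="exwas")
COLLAPSING_PROFILE = QCThresholds(
    profile="collapsing",
    min_alt_fraction_hom=0.8,
    min_hwe_p=None,
    max_failed_fraction=None,
    min_external_coverage=0.25,
    min_external_zscore=-2.0,
    require_ccds=True,
)

PROFILES = {"exwas": EXWAS_PROFILE, "collapsing": COLLAPSING_PROFILE}


@dataclass
class QCDecision:
    passed: bool
    reasons: list = field(default_factory=list)


def evaluate_site(metrics: SiteQCMetrics, thresholds: QCThresholds) -> QCDecision:
    """Apply every threshold of the profile; collect all failure reasons.

    Values exactly at a printed ``>=`` / ``<=`` bound pass; strict
    inequalities in the source criteria (e.g. the balance test ``p >
    1e-6``) are honoured as strict.
    """
    if thresholds.profile not in PROFILES:
        raise ValueError(f"unknown QC profile {thresholds.profile!r}")
    t = thresholds
    m = metrics
    reasons: list[str] = []

    # missing (<10x) in >=1% of either cohort excludes the site
    miss_frac_cases = max(1.0 - m.coverage_fraction_cases, m.miss_cases / m.n_cases)
    miss_frac_controls = max(
        1.0 - m.coverage_fraction_controls, m.miss_controls / m.n_controls
    )
    if miss_frac_cases >= t.max_missing_fraction - 1e-12:
        reasons.append("missingness_cases")
    if miss_frac_controls >= t.max_missing_fraction - 1e-12:
        reasons.append("missingness_controls")
    if m.gq < t.min_gq:
        reasons.append("gq")
    if m.qual < t.min_qual:
        reasons.append("qual")
    if m.mq < t.min_mq:
        reasons.append("mq")
    fs_bound = t.max_fs_snv if m.is_snv else t.max_fs_indel
    if m.fs > fs_bound:
        reasons.append("fs")
    if m.rprs < t.min_rprs:
        reasons.append("rprs")
    if m.mqrs < t.min_mqrs:
        reasons.append("mqrs")
    if not m.caller_pass:
        reasons.append("caller")
    lo, hi = t.alt_fraction_het_range
    if not (lo <= m.alt_fraction_het <= hi):
        reasons.append("alt_fraction_het")
    if t.min_alt_fraction_hom is not None and m.alt_fraction_hom < t.min_alt_fraction_hom:
        reasons.append("alt_fraction_hom")
    if m.total_reads_het > 0:
        if binomial_balance_test(m.alt_reads_het, m.total_reads_het) <= t.min_balance_p:
            reasons.append("balance")
    p_dm = differential_missingness_test(
        m.miss_cases, m.n_cases, m.miss_controls, m.n_controls
    )
    if p_dm < t.max_diff_missingness_p:
        reasons.append("diff_missingness")
    if t.min_hwe_p is not None:
        if t.hwe_cohort == "pooled":
            gc = tuple(
                x + y
                for x, y in zip(m.genotype_counts_cases, m.genotype_counts_controls)
            )
        else:
            gc = m.genotype_counts_controls
        if sum(gc) > 0 and hwe_exact_test(*gc) < t.min_hwe_p:
            reasons.append("hwe")
    if t.max_failed_fraction is not None:
        if (
            m.failed_fraction_cases >= t.max_failed_fraction
            or m.failed_fraction_controls >= t.max_failed_fraction
        ):
            reasons.append("failed_calls")
    if m.external_coverage_fraction < t.min_external_coverage:
        reasons.append("external_coverage")
    if m.external_observed:
        if m.external_zscore < t.min_external_zscore:
            reasons.append("external_zscore")
        if m.external_mq < t.min_external_mq:
            reasons.append("external_mq")
    if t.require_ccds and not m.ccds_transcript:
        reasons.append("ccds")
    return QCDecision(passed=not reasons, reasons=reasons)


_METRIC_COLUMNS = [
    "is_snv", "coverage_fraction_cases", "coverage_fraction_controls", "gq",
    "qual", "mq", "fs", "rprs", "mqrs", "caller_pass", "alt_fraction_het",
    "alt_fraction_hom", "alt_reads_het", "total_reads_het",
    "failed_fraction_cases", "failed_fraction_controls", "external_observed",
    "external_coverage_fraction", "external_mq", "external_zscore",
    "ccds_transcript",
]


def run_site_qc(genotypes, annotation: pd.DataFrame, manifest: pd.DataFrame,
                profile: str | QCThresholds = "exwas") -> pd.DataFrame:
    """Evaluate the full site-QC battery over a cohort.

    Annotation columns supply the caller/external metrics; genotype
    counts and missingness are derived from the genotype matrix.
    Returns a report frame: variant_id, qc_pass, reasons (';'-joined).
    """
    thresholds = PROFILES[profile] if isinstance(profile, str) else profile
    case_mask = (manifest["phenotype"].to_numpy() == 1)
    geno = genotypes.geno
    missing = geno < 0
    rows = []
    ann = annotation.set_index("variant_id")
    for j, vid in enumerate(genotypes.variants):
        row = ann.loc[vid]
        kwargs = {c: row[c] for c in _METRIC_COLUMNS if c in row.index}
        g_case = geno[case_mask, j]
        g_ctrl = geno[~case_mask, j]
        metrics = SiteQCMetrics(
            genotype_counts_cases=(
                int((g_case == 0).sum()), int((g_case == 1).sum()),
                int((g_case == 2).sum())),
            genotype_counts_controls=(
                int((g_ctrl == 0).sum()), int((g_ctrl == 1).sum()),
                int((g_ctrl == 2).sum())),
            miss_cases=int(missing[case_mask, j].sum()),
            n_cases=int(case_mask.sum()),
            miss_controls=int(missing[~case_mask, j].sum()),
            n_controls=int((~case_mask).sum()),
            **kwargs,
        )
        d = evaluate_site(metrics, thresholds)
        rows.append((vid, d.passed, ";".join(d.reasons)))
    return pd.DataFrame(rows, columns=["variant_id", "qc_pass", "reasons"])


# ---------------------------------------------------------------------------
# sample harmonisation
# ---------------------------------------------------------------------------

def filter_samples(manifest: pd.DataFrame, pc_sd_limit: float = 4.0):
    """Partition samples into kept/removed with per-sample reason codes.

    Rules: contamination > 4%, European-ancestry probability < 0.98,
    CCDS >=10x coverage <= 95%, sex discordance, PC1-4 outliers beyond
    ``pc_sd_limit`` standard deviations (computed on the
    post-ancestry-filter cohort, single pass), and an optional
    precomputed ``unrelated`` flag.  Relatedness itself is not
    estimated here.
    """
    required = ["contamination", "european_prob", "ccds_coverage", "sex_concordant"]
    for col in required:
        if col not in manifest.columns:
            raise ValueError(f"manifest is missing required QC column {col!r}")
    reasons = {sid: [] for sid in manifest["sample_id"]}
    contaminated = manifest["contamination"] > 0.04
    non_euro = manifest["european_prob"] < 0.98
    low_cov = manifest["ccds_coverage"] <= 0.95
    discordant = ~manifest["sex_concordant"].astype(bool)
    for mask, code in [
        (contaminated, "contamination"),
        (non_euro, "ancestry"),
        (low_cov, "ccds_coverage"),
        (discordant, "sex_discordance"),
    ]:
        for sid in manifest.loc[mask.to_numpy(), "sample_id"]:
            reasons[sid].append(code)
    if "unrelated" in manifest.columns:
        related = ~manifest["unrelated"].astype(bool)
        for sid in manifest.loc[related.to_numpy(), "sample_id"]:
            reasons[sid].append("related")

    # PC outliers: moments computed over the ancestry-passing cohort
    pc_cols = [c for c in ("PC1", "PC2", "PC3", "PC4") if c in manifest.columns]
    if pc_cols:
        base = manifest.loc[(~non_euro).to_numpy(), pc_cols]
        mu = base.mean()
        sd = base.std(ddof=1)
        pcs = manifest[pc_cols]
        outlier = ((pcs - mu).abs() > pc_sd_limit * sd).any(axis=1)
        for sid in manifest.loc[outlier.to_numpy(), "sample_id"]:
            reasons[sid].append("pc_outlier")

    removed_ids = {sid for sid, r in reasons.items() if r}
    kept = manifest[~manifest["sample_id"].isin(removed_ids)].copy()
    removed = manifest[manifest["sample_id"].isin(removed_ids)].copy()
    removed["reasons"] = [";".join(reasons[s]) for s in removed["sample_id"]]
    return kept, removed


def gender_match_controls(manifest: pd.DataFrame, target_male_fraction: float,
                          seed: int) -> pd.DataFrame:
    """Downsample the over-represented control sex to hit a male fraction.

    Keeps the full complement of the under-represented sex and a seeded
    random subset of the other, so the retained male fraction equals the
    target to within one sample.
    """
    if not (0.0 <= target_male_fraction <= 1.0):
        raise ValueError("target male fraction must lie in [0, 1]")
    controls = manifest[manifest["phenotype"] == 0]
    males = controls[controls["sex"] == "M"]
    females = controls[controls["sex"] == "F"]
    m, f = len(males), len(females)
    t = target_male_fraction
    if (t > 0 and m == 0) or (t < 1 and f == 0):
        raise ValueError("target male fraction unattainable by downsampling")
    rng = np.random.default_rng(seed)
    current = m / (m + f)
    if current < t:
        keep_f = int(np.floor(m * (1 - t) / t)) if t > 0 else f
        idx = rng.choice(f, size=min(keep_f, f), replace=False)
        kept = pd.concat([males, females.iloc[np.sort(idx)]])
    elif current > t:
        keep_m = int(np.floor(f * t / (1 - t))) if t < 1 else m
        idx = rng.choice(m, size=min(keep_m, m), replace=False)
        kept = pd.concat([males.iloc[np.sort(idx)], females])
    else:
        kept = controls
    return kept.sort_index()
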