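"""Post-discovery genetic-architecture statistics.

Covers the downstream characterisation of an oligogenic case-control
study: rule-based classification of carriers of putatively pathogenic
variants in telomere-maintenance genes, stratified allele-frequency
contrasts of a common modifier allele against a shared reference
population, logistic-regression association of carrier status with
telomere length (adjusting for age and sex), clinical-characteristic
comparisons, Kaplan-Meier survival with log-rank tests, and
hypergeometric enrichment of top-ranked collapsing genes against a
predicted gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exwas import ContingencyTable, fisher_exact, firth_logistic
from .qc import binomial_balance_test

__all__ = [
    "PathogenicRule",
    "default_pathogenic_rules",
    "classify_carriers",
    "stratified_af_tests",
    "telomere_logistic",
    "TelomereModel",
    "clinical_compare",
    "km_logrank",
    "enrichment_hypergeometric",
    "effect_size_table",
]


# ---------------------------------------------------------------------------
# carrier classification
# ---------------------------------------------------------------------------

@dataclass
class PathogenicRule:
    """Per-gene qualifying rule for putatively pathogenic variants."""

    gene: str
    allowed_consequences: frozenset
    popmax_max: float | None = None       # None: no frequency bound
    require_clinvar_pathogenic: bool = False


def default_pathogenic_rules(genes=("RTEL1", "PARN", "TERT", "TERC")) -> list:
    """Telomere-gene rule set: PTVs at popmax <= 0.05%, ultra-rare
    missense (popmax = 0) for the two genes where missense is
    interpretable, and curated-pathogenic noncoding variants for the
    RNA gene."""
    ptv = frozenset({"ptv", "stop_gained", "frameshift", "splice"})
    rules = []
    for g in genes:
        if g == "TERC":
            rules.append(PathogenicRule(g, frozenset({"noncoding"}),
                                        require_clinvar_pathogenic=True))
            continue
        rules.append(PathogenicRule(g, ptv, popmax_max=5e-4))
        if g in ("TERT", "PARN"):
            rules.append(PathogenicRule(g, frozenset({"missense"}),
                                        popmax_max=0.0))
    return rules


def _site_qc_ok(ann: pd.DataFrame) -> np.ndarray:
    """Carrier-classification QC sub-battery.

    Alt-read fraction >= 0.3, exact binomial balance p > 0.001,
    GQ >= 30, QUAL >= 30, variant affects a coding (CCDS) transcript.
    """
    ok = (
        (ann["alt_fraction_het"].to_numpy(dtype=float) >= 0.3)
        & (ann["gq"].to_numpy(dtype=float) >= 30)
        & (ann["qual"].to_numpy(dtype=float) >= 30)
        & ann["ccds_transcript"].to_numpy(dtype=bool)
    )
    bal = np.array([
        binomial_balance_test(int(r), int(t)) if t > 0 else 1.0
        for r, t in zip(ann["alt_reads_het"], ann["total_reads_het"])
    ])
    return ok & (bal > 1e-3)


def classify_carriers(genotypes, annotation: pd.DataFrame, rules: list,
                      index_variant: str, modifier_variant: str):
    """Per-sample carrier-class flags and the dual-carrier cross-tab.

    Flags are non-exclusive: a sample receives every class that
    applies.  ``noncarrier`` marks samples carrying neither a
    pathogenic-gene qualifying variant nor the index variant.
    Classification is a pure function of genotypes, annotation and the
    rule set; flag assignment is idempotent and order-independent over
    variants.
    """
    ann = annotation.set_index("variant_id").loc[list(genotypes.variants)].reset_index()
    for vid in (index_variant, modifier_variant):
        if vid not in set(ann["variant_id"]):
            raise ValueError(f"variant {vid!r} absent from annotation")
    qc_ok = _site_qc_ok(ann)
    path_mask = np.zeros(len(ann), dtype=bool)
    for rule in rules:
        m = (
            (ann["gene"].to_numpy() == rule.gene)
            & ann["consequence"].isin(rule.allowed_consequences).to_numpy()
        )
        if rule.popmax_max is not None:
            m &= ann["popmax"].to_numpy(dtype=float) <= rule.popmax_max
        if rule.require_clinvar_pathogenic:
            m &= ann["clinvar_pathogenic"].to_numpy(dtype=bool)
        path_mask |= m
    path_mask &= qc_ok

    geno = np.where(genotypes.geno > 0, genotypes.geno, 0)
    telomere_qv = (geno[:, path_mask] >= 1).any(axis=1)
    idx_col = genotypes.variant_index(index_variant)
    mod_col = genotypes.variant_index(modifier_variant)
    index_c = geno[:, idx_col] >= 1
    modifier_c = geno[:, mod_col] >= 1
    table = pd.DataFrame({
        "sample_id": genotypes.samples,
        "telomere_qv_carrier": telomere_qv,
        "index_carrier": index_c,
        "modifier_carrier": modifier_c,
        "noncarrier": ~(telomere_qv | index_c),
    })
    crosstab = pd.crosstab(table["telomere_qv_carrier"], table["index_carrier"])
    return table, crosstab


# ---------------------------------------------------------------------------
# stratified allele-frequency contrasts
# ---------------------------------------------------------------------------

def stratified_af_tests(group_counts: dict, reference: tuple,
                        or_method: str = "conditional") -> pd.DataFrame:
    """One allelic Fisher test per group versus a shared reference.

    ``group_counts`` maps group name -> (alt alleles, total alleles);
    ``reference`` is the shared (alt, total).  Groups are reported in
    input order; an empty group is recorded with an error note while
    the others proceed.
    """
    ref_alt, ref_tot = reference
    if ref_tot <= 0:
        raise ValueError("reference allele counts must be positive")
    rows = []
    for name, (alt, tot) in group_counts.items():
        if tot <= 0:
            rows.append((name, alt, tot, np.nan, np.nan, np.nan, np.nan,
                         np.nan, "empty_group"))
            continue
        res = fisher_exact(
            ContingencyTable(int(alt), int(tot - alt),
                             int(ref_alt), int(ref_tot - ref_alt)),
            or_method=or_method)
        rows.append((name, alt, tot, alt / tot, res.p, res.or_point,
                     res.ci_low, res.ci_high, ""))
    return pd.DataFrame(rows, columns=[
        "group", "alt", "total", "af", "p", "or_point", "ci_low",
        "ci_high", "note"])


# ---------------------------------------------------------------------------
# telomere-length logistic model
# ---------------------------------------------------------------------------

@dataclass
class TelomereModel:
    """logit Pr(carrier) = b0 + b1*telomere + b2*age + b3*sex."""

    beta: np.ndarray                  # (intercept, telomere, age, sex)
    se: np.ndarray
    or_per_unit: float
    ci95: tuple
    p_lrt: float
    or_per_sd: float
    method: str = "ml"                # "ml" or "firth"


def telomere_logistic(carrier, telomere, age, sex,
                      firth_fallback: bool = True) -> TelomereModel:
    """Logistic regression of carrier status on telomere length.

    Maximum-likelihood Newton fit with age and sex covariates; reports
    the per-unit odds ratio with Wald CI and a likelihood-ratio
    p-value for the telomere term, plus the per-SD odds ratio for
    unit-free comparison.  Under (quasi-)separation the fit falls back
    to Firth penalisation when enabled, otherwise raises.
    """
    y = np.asarray(carrier, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one carrier and one non-carrier")
    sex_arr = np.asarray(sex)
    sex_num = ((sex_arr == "M").astype(float)
               if sex_arr.dtype.kind in "UOS" else sex_arr.astype(float))
    X = np.column_stack([
        np.ones_like(y), np.asarray(telomere, float),
        np.asarray(age, float), sex_num,
    ])
    method = "ml"
    try:
        with np.errstate(all="ignore"):
            full = sm.Logit(y, X).fit(disp=0, maxiter=200)
            red = sm.Logit(y, X[:, [0, 2, 3]]).fit(disp=0, maxiter=200)
        if not (full.mle_retvals.get("converged", True)
                and np.all(np.isfinite(full.bse))):
            raise np.linalg.LinAlgError("unstable ML fit")
        beta, se = np.asarray(full.params), np.asarray(full.bse)
        lrt = 2.0 * (full.llf - red.llf)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        if not firth_fallback:
            raise RuntimeError("separation: logistic fit failed and the "
                               "Firth fallback is disabled")
        beta, se, ll_full, _ = firth_logistic(X, y)
        _, _, ll_red, _ = firth_logistic(X[:, [0, 2, 3]], y)
        lrt = 2.0 * (ll_full - ll_red)
        method = "firth"
    p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    b1, s1 = float(beta[1]), float(se[1])
    z = stats.norm.isf(0.025)
    tl_sd = float(np.std(np.asarray(telomere, float), ddof=1))
    return TelomereModel(
        beta=beta, se=se,
        or_per_unit=float(np.exp(b1)),
        ci95=(float(np.exp(b1 - z * s1)), float(np.exp(b1 + z * s1))),
        p_lrt=p,
        or_per_sd=float(np.exp(b1 * tl_sd)),
        method=method)


# ---------------------------------------------------------------------------
# clinical comparisons, survival, enrichment
# ---------------------------------------------------------------------------

def clinical_compare(df: pd.DataFrame, group_col: str, columns: list,
                     binary_cols: tuple = (), exact_n_max: int = 20) -> pd.DataFrame:
    """Compare clinical columns between two groups.

    Numeric columns are median-imputed over the whole cohort (a single
    pass, not group-wise) and compared with the Mann-Whitney U test
    (exact for combined n <= ``exact_n_max``, else the tie-corrected
    normal approximation with continuity correction).  Binary columns
    are compared with Fisher's exact test.
    """
    g = df[group_col].astype(bool)
    rows = []
    for col in columns:
        x = df[col]
        if x.isna().all():
            raise ValueError(f"column {col!r} is entirely missing")
        if col in binary_cols:
            xa = x.astype(int)
            a = int((xa[g] == 1).sum()); b = int((xa[g] == 0).sum())
            c = int((xa[~g] == 1).sum()); d = int((xa[~g] == 0).sum())
            res = fisher_exact(ContingencyTable(a, b, c, d), or_method="woolf")
            rows.append((col, "fisher_exact", res.or_point, res.p))
        else:
            imputed = x.fillna(x.median())
            u, p = _mann_whitney(imputed[g].to_numpy(float),
                                 imputed[~g].to_numpy(float), exact_n_max)
            rows.append((col, "mann_whitney", u, p))
    return pd.DataFrame(rows, columns=["column", "test", "statistic", "p"])


def _mann_whitney(x, y, exact_n_max):
    method = "exact" if (len(x) + len(y)) <= exact_n_max else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def km_logrank(times, events, groups):
    """Kaplan-Meier curves per group and the k-sample log-rank test.

    Returns (curves DataFrame with columns group/time/survival,
    statistic, p, df).  With no events anywhere the log-rank statistic
    is undefined and reported as NaN.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if np.any(times < 0):
        raise ValueError("negative survival times")
    labels = pd.unique(pd.Series(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    curves = []
    for lab in labels:
        m = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        sf = kmf.survival_function_
        curves.append(pd.DataFrame({
            "group": lab,
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
        }))
    curves = pd.concat(curves, ignore_index=True)
    if events.sum() == 0:
        return curves, float("nan"), float("nan"), len(labels) - 1
    res = multivariate_logrank_test(times, groups, events)
    return curves, float(res.test_statistic), float(res.p_value), len(labels) - 1


def enrichment_hypergeometric(top_genes, predicted_set, universe) -> float:
    """Upper-tail hypergeometric enrichment p of two gene sets.

    Probability of an overlap at least as large as observed between
    ``top_genes`` (e.g. collapsing genes at p < 0.05) and
    ``predicted_set`` (e.g. the top 5% of classifier-ranked genes),
    both drawn from ``universe``.
    """
    top, pred, uni = set(top_genes), set(predicted_set), set(universe)
    if not top <= uni or not pred <= uni:
        raise ValueError("gene sets must be contained in the universe")
    k = len(top & pred)
    return float(stats.hypergeom.sf(k - 1, len(uni), len(pred), len(top)))


def effect_size_table(sources: list) -> pd.DataFrame:
    """Merge per-source (locus, control frequency, OR, CI, class) tables.

    No statistics are computed: rows are concatenated, locus ids must
    be unique, and the merged table is sorted by control frequency.
    """
    required = ["locus", "control_freq", "or_point", "ci_low", "ci_high",
                "variant_class"]
    frames = [pd.DataFrame(s) if not isinstance(s, pd.DataFrame) else s
              for s in sources]
    if not frames:
        return pd.DataFrame(columns=required)
    merged = pd.concat(frames, ignore_index=True)
    for col in required:
        if col not in merged.columns:
            raise ValueError(f"source tables missing column {col!r}")
    if merged["locus"].duplicated().any():
        dup = merged.loc[merged["locus"].duplicated(), "locus"].iloc[0]
        raise ValueError(f"duplicate locus id {dup!r}")
    return merged.sort_values("control_freq", kind="stable").reset_index(drop=True)
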