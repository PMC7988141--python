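"""Per-variant exome-wide association scan (ExWAS).

Each QC-passing variant is tested for case-control association with a
two-sided Fisher's exact test on the allelic (2n) 2x2 table, with a
conditional-MLE odds ratio and exact confidence interval.  Variants
passing a configurable p-value threshold are refit with Firth
penalised logistic regression adjusting for sex, age and the top four
principal components; the Firth p-value comes from the penalised
likelihood-ratio test, so it remains well defined under complete
separation.

The two-sided Fisher p is the "minimum likelihood" sum: the total
probability, over the hypergeometric support at fixed margins, of all
tables no more probable than the observed one (with a 1e-7 relative
tolerance for floating-point ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, expit

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "AssociationResult",
    "fisher_exact",
    "fisher_exact_p",
    "firth_logistic",
    "firth_logistic_fit",
    "run_exwas",
    "ConvergenceError",
]

GENOME_WIDE_P = 5e-8


@dataclass
class ContingencyTable:
    """2x2 case-control table: a/b exposed/unexposed cases, c/d controls."""

    a: int
    b: int
    c: int
    d: int
    exposure_coding: str = "allelic"

    def validate(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("each cohort margin must be positive")


@dataclass
class FisherResult:
    p: float
    or_point: float
    ci_low: float
    ci_high: float


@dataclass
class AssociationResult:
    variant_id: str
    table: ContingencyTable
    p_fet: float
    or_point: float
    ci95: tuple
    p_firth: float | None = None
    beta_firth: float | None = None
    genome_wide: bool = False


class ConvergenceError(RuntimeError):
    """Raised when the Firth Newton iteration fails to converge."""


def _lchoose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value (probability-ordering rule)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if c1 == 0 or c1 == n:       # exposure margin degenerate: only one table
        return 1.0
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logpmf = _lchoose(r1, k) + _lchoose(n - r1, c1 - k) - _lchoose(n, c1)
    logobs = logpmf[a - lo]
    p = float(np.exp(logpmf)[logpmf <= logobs + np.log1p(1e-7)].sum())
    return min(1.0, p)


def _woolf_ci(a, b, c, d, alpha=0.05):
    """Haldane-corrected log-OR with Woolf (normal) interval."""
    ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    logor = np.log(ah * dh / (bh * ch))
    se = np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    z = stats.norm.isf(alpha / 2)
    return np.exp(logor), np.exp(logor - z * se), np.exp(logor + z * se)


def fisher_exact(table: ContingencyTable, or_method: str = "conditional") -> FisherResult:
    """Fisher's exact test with odds-ratio point estimate and 95% CI.

    ``or_method='conditional'`` gives the conditional-MLE point estimate
    with the exact (tail-inversion) interval; ``'woolf'`` gives the fast
    Haldane-corrected log-OR with a normal interval.  Zero cells yield
    open CI bounds (0 or inf); a degenerate exposure margin (no carrier
    on either side) is reported as p=1, OR=1 with a fully open interval.
    """
    table.validate()
    a, b, c, d = table.a, table.b, table.c, table.d
    p = fisher_exact_p(a, b, c, d)
    if (a + c == 0) or (b + d == 0):
        return FisherResult(p=1.0, or_point=1.0, ci_low=0.0, ci_high=np.inf)
    if or_method == "woolf":
        or_pt, lo, hi = _woolf_ci(a, b, c, d)
        return FisherResult(p=p, or_point=float(or_pt), ci_low=float(lo),
                            ci_high=float(hi))
    if or_method != "conditional":
        raise ValueError(f"unknown or_method {or_method!r}")
    res = stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    return FisherResult(p=p, or_point=float(res.statistic),
                        ci_low=float(ci.low), ci_high=float(ci.high))


# ---------------------------------------------------------------------------
# Firth penalised logistic regression
# ---------------------------------------------------------------------------

def _penalised_loglik(X, y, beta):
    eta = X @ beta
    # stable log-likelihood
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                   tol: float = 1e-8):
    """Fit a logistic model by maximising the Jeffreys-penalised likelihood.

    Newton iteration on the Firth-adjusted score with step-halving on
    the penalised log-likelihood.  Converges (finite estimates) even
    under complete separation.  Returns (beta, se, penalised loglik,
    n_iter).  Raises :class:`ConvergenceError` if the adjusted score
    max-norm does not fall below ``tol`` within ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    ll = _penalised_loglik(X, y, beta)
    for it in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        XW = X * w[:, None]
        info = XW.T @ X
        info_inv = np.linalg.inv(info)
        # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        if np.max(np.abs(score)) < tol:
            se = np.sqrt(np.diag(info_inv))
            return beta, se, ll, it
        step = info_inv @ score
        # step-halving to guarantee ascent of the penalised likelihood
        lam = 1.0
        for _ in range(25):
            ll_new = _penalised_loglik(X, y, beta + lam * step)
            if ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        ll = ll_new
    raise ConvergenceError(
        f"Firth Newton iteration did not converge in {max_iter} steps"
    )


def firth_logistic_fit(covariates: pd.DataFrame, outcome: np.ndarray,
                       genotype_column: np.ndarray):
    """Firth regression of case status on genotype plus covariates.

    Covariates are standardised internally for numerical conditioning
    (the genotype effect is unaffected).  The genotype p-value comes
    from the penalised likelihood-ratio test (1 df).

    Returns a dict with the genotype log-odds (beta), its standard
    error, the per-coefficient estimates, and p_firth.
    """
    y = np.asarray(outcome, dtype=float)
    C = covariates.to_numpy(dtype=float)
    mu, sd = C.mean(axis=0), C.std(axis=0)
    if np.any(sd == 0):
        bad = covariates.columns[np.flatnonzero(sd == 0)].tolist()
        raise ValueError(f"constant covariate column(s): {bad}")
    Cs = (C - mu) / sd
    g = np.asarray(genotype_column, dtype=float)
    X_full = np.column_stack([np.ones_like(y), Cs, g])
    X_red = X_full[:, :-1]
    beta_f, se_f, ll_full, _ = firth_logistic(X_full, y)
    _, _, ll_red, _ = firth_logistic(X_red, y)
    lrt = max(0.0, 2.0 * (ll_full - ll_red))
    p = float(stats.chi2.sf(lrt, df=1))
    return {
        "beta": float(beta_f[-1]),
        "se": float(se_f[-1]),
        "p_firth": p,
        "coefficients": beta_f,
    }


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def _allelic_counts(geno: np.ndarray, case_mask: np.ndarray):
    """Alt-allele and called-chromosome counts per variant, by cohort."""
    called = geno >= 0
    g = np.where(called, geno, 0).astype(np.float64)
    cases = case_mask.astype(np.float64)
    alt_case = cases @ g
    alt_ctrl = (1.0 - cases) @ g
    n_case = 2.0 * (cases @ called)
    n_ctrl = 2.0 * ((1.0 - cases) @ called)
    return alt_case, n_case, alt_ctrl, n_ctrl


def run_exwas(genotypes, annotation: pd.DataFrame, manifest: pd.DataFrame,
              qc_report: pd.DataFrame | None = None, min_observed: int = 12,
              coding: str = "allelic", count_rule: str = "carriers",
              or_method: str = "conditional", firth_p_threshold: float = 0.01,
              genome_wide_p: float = GENOME_WIDE_P):
    """Run the per-variant association scan.

    Variants failing QC are dropped; variants observed in fewer than
    ``min_observed`` individuals (carriers by default; all genotyped
    individuals with ``count_rule='genotyped'``) are excluded and
    logged.  Variants with Fisher p below ``firth_p_threshold`` are
    refit with Firth regression on sex, age and PC1-4 where those
    columns are present.

    Returns (results DataFrame, exclusion-log DataFrame).
    """
    if coding not in ("allelic", "dominant"):
        raise ValueError(f"unknown exposure coding {coding!r}")
    sample_ids = list(genotypes.samples)
    man = manifest.set_index("sample_id").loc[sample_ids]
    case_mask = man["phenotype"].to_numpy() == 1
    geno = genotypes.geno
    variants = np.asarray(genotypes.variants)

    keep = np.ones(len(variants), dtype=bool)
    excluded = []
    if qc_report is not None:
        qc_pass = qc_report.set_index("variant_id")["qc_pass"]
        keep &= qc_pass.reindex(variants).fillna(False).to_numpy(dtype=bool)
        for vid in variants[~keep]:
            excluded.append((vid, "qc_fail"))

    carriers = (geno >= 1).sum(axis=0)
    genotyped = (geno >= 0).sum(axis=0)
    observed = carriers if count_rule == "carriers" else genotyped
    too_rare = keep & (observed < min_observed)
    for j in np.flatnonzero(too_rare):
        excluded.append((variants[j], f"observed_in_{int(observed[j])}"))
    keep &= ~too_rare

    alt_case, n_case, alt_ctrl, n_ctrl = _allelic_counts(geno, case_mask)
    rows = []
    want_firth = _has_covariates(man)
    for j in np.flatnonzero(keep):
        if coding == "allelic":
            a = int(alt_case[j]); b = int(n_case[j]) - a
            c = int(alt_ctrl[j]); d = int(n_ctrl[j]) - c
        else:
            gj = geno[:, j]
            called = gj >= 0
            a = int(((gj >= 1) & case_mask).sum())
            b = int((called & case_mask).sum()) - a
            c = int(((gj >= 1) & ~case_mask).sum())
            d = int((called & ~case_mask).sum()) - c
        res = fisher_exact(ContingencyTable(a, b, c, d, coding), or_method=or_method)
        p_firth = beta_firth = np.nan
        if res.p < firth_p_threshold and want_firth:
            try:
                fit = firth_logistic_fit(
                    man[_covariate_columns(man)],
                    case_mask.astype(float),
                    np.where(geno[:, j] >= 0, geno[:, j], 0).astype(float),
                )
                p_firth, beta_firth = fit["p_firth"], fit["beta"]
            except (ConvergenceError, np.linalg.LinAlgError):
                p_firth, beta_firth = np.nan, np.nan
        af_case = a / (a + b) if a + b else np.nan
        af_ctrl = c / (c + d) if c + d else np.nan
        rows.append((variants[j], a, b, c, d, af_case, af_ctrl, res.p,
                     res.or_point, res.ci_low, res.ci_high, p_firth,
                     beta_firth, res.p < genome_wide_p))
    results = pd.DataFrame(rows, columns=[
        "variant_id", "a", "b", "c", "d", "af_cases", "af_controls",
        "p_fet", "or_point", "ci_low", "ci_high", "p_firth", "beta_firth",
        "genome_wide"])
    exclusions = pd.DataFrame(excluded, columns=["variant_id", "reason"])
    return results, exclusions


def _covariate_columns(man: pd.DataFrame):
    cols = []
    if "sex" in man.columns:
        cols.append("sex_code")
    if "age" in man.columns:
        cols.append("age")
    cols += [c for c in ("PC1", "PC2", "PC3", "PC4") if c in man.columns]
    return cols


def _has_covariates(man: pd.DataFrame) -> bool:
    if "sex" in man.columns and "sex_code" not in man.columns:
        man["sex_code"] = (man["sex"] == "M").astype(float)
    return len(_covariate_columns(man)) > 0
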