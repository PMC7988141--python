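"""Replication meta-analysis and empirical-null calibration.

Cross-study combination uses Stouffer's Z: each study contributes a
signed normal score ``Z_i = Phi^-1(1 - p_i/2) * direction_i`` and the
combined two-sided p is ``2 Phi(-|sum w_i Z_i / sqrt(sum w_i^2)|)``.

Calibration of a sparse, heavily imbalanced scan uses a
permutation-based null: case/control labels are permuted (preserving
the case count), the exact test is re-run on the identical variant
set, each permutation's p-vector is rank-sorted, and the element-wise
median across permutations defines the expected distribution.  The
genomic inflation factor lambda is the slope of the no-intercept
regression of observed on expected 1-df chi-square quantiles; the
classical median-ratio lambda is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exwas import fisher_exact_p

__all__ = [
    "MetaInput",
    "CalibrationResult",
    "stouffer_combine",
    "select_replication_candidates",
    "permutation_null",
    "permutation_expected",
    "estimate_lambda",
]

P_FLOOR = 1e-300


@dataclass
class MetaInput:
    """Per-study (p, effect direction, optional weight) for one variant."""

    p: list
    direction: list
    weight: list | None = None

    def validate(self) -> None:
        if len(self.p) != len(self.direction):
            raise ValueError("p and direction must have equal length")
        for p in self.p:
            if p == 0:
                raise ValueError("p = 0 input; clip before combining")
            if not (0.0 < p <= 1.0):
                raise ValueError("p-values must lie in (0, 1]")


@dataclass
class CalibrationResult:
    lambda_regression: float
    lambda_median: float
    observed_p: np.ndarray        # rank-sorted ascending
    expected_p: np.ndarray        # rank-sorted ascending
    n_permutations: int
    variant_ids: np.ndarray = field(default_factory=lambda: np.array([]))


def stouffer_combine(inputs: MetaInput) -> float:
    """Stouffer's weighted Z combination; returns the combined two-sided p.

    Directions are +/-1 (the sign of the study's log odds ratio; an OR
    of exactly 1 contributes Z = 0 via direction 0).  Default weights
    are equal.  A single study returns its own p unchanged.
    """
    inputs.validate()
    p = np.asarray(inputs.p, dtype=float)
    d = np.asarray(inputs.direction, dtype=float)
    w = (np.ones_like(p) if inputs.weight is None
         else np.asarray(inputs.weight, dtype=float))
    z = stats.norm.isf(p / 2.0) * d
    Z = float(np.sum(w * z) / np.sqrt(np.sum(w ** 2)))
    return float(min(1.0, 2.0 * stats.norm.sf(abs(Z))))


def select_replication_candidates(results: pd.DataFrame,
                                  threshold: float = 0.01) -> pd.DataFrame:
    """Variants taken forward to replication: strict ``p < threshold``."""
    if "p_fet" not in results.columns:
        raise ValueError("results table must carry a 'p_fet' column")
    return results[results["p_fet"] < threshold].sort_values(
        "p_fet", kind="stable").reset_index(drop=True)


def _fet_scan(geno: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Allelic two-sided FET p per column for a given phenotype vector."""
    called = geno >= 0
    g = np.where(called, geno, 0).astype(np.float64)
    cases = case_mask.astype(np.float64)
    alt_case = cases @ g
    alt_ctrl = g.sum(axis=0) - alt_case
    n_case = 2.0 * (cases @ called)
    n_ctrl = 2.0 * called.sum(axis=0) - n_case
    return np.array([
        fisher_exact_p(int(alt_case[j]), int(n_case[j] - alt_case[j]),
                       int(alt_ctrl[j]), int(n_ctrl[j] - alt_ctrl[j]))
        for j in range(geno.shape[1])
    ])


def permutation_expected(p_fn, labels: np.ndarray, n_perm: int,
                         seed: int) -> np.ndarray:
    """Median of rank-sorted p-vectors over label permutations.

    ``p_fn`` maps a boolean case-label vector to a p-value vector; each
    permutation preserves the original case count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    sorted_ps = []
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        sorted_ps.append(np.sort(p_fn(perm)))
    return np.median(np.vstack(sorted_ps), axis=0)


def permutation_null(genotypes, manifest: pd.DataFrame, n_perm: int = 10,
                     seed: int = 0, min_observed: int = 12,
                     variant_mask: np.ndarray | None = None) -> CalibrationResult:
    """Permutation-based expected p distribution and inflation factor.

    The observed scan and every permutation run on the identical
    variant set (QC- and carrier-filtered before entry, or restricted
    by ``variant_mask``).
    """
    sample_ids = list(genotypes.samples)
    man = manifest.set_index("sample_id").loc[sample_ids]
    labels = man["phenotype"].to_numpy() == 1
    geno = genotypes.geno
    carriers = (geno >= 1).sum(axis=0)
    keep = carriers >= min_observed
    if variant_mask is not None:
        keep &= np.asarray(variant_mask, dtype=bool)
    geno = geno[:, keep]
    observed = np.sort(_fet_scan(geno, labels))
    expected = permutation_expected(
        lambda lab: _fet_scan(geno, lab), labels, n_perm, seed)
    lam_reg = estimate_lambda(observed, expected, method="regression")
    lam_med = estimate_lambda(observed, expected, method="median")
    return CalibrationResult(
        lambda_regression=lam_reg, lambda_median=lam_med,
        observed_p=observed, expected_p=expected, n_permutations=n_perm,
        variant_ids=np.asarray(genotypes.variants)[keep])


def estimate_lambda(observed_p, expected_p, method: str = "regression") -> float:
    """Genomic inflation factor from observed vs expected p-values.

    Both vectors are transformed to 1-df chi-square quantiles.
    ``regression`` returns the slope of the least-squares line through
    the origin (observed on expected); ``median`` returns the classical
    ratio of medians.  p-values are clipped to [1e-300, 1].
    """
    obs = np.clip(np.asarray(observed_p, dtype=float), P_FLOOR, 1.0)
    exp = np.clip(np.asarray(expected_p, dtype=float), P_FLOOR, 1.0)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected vectors must have equal length")
    chi_obs = stats.chi2.isf(obs, df=1)
    chi_exp = stats.chi2.isf(exp, df=1)
    if method == "regression":
        denom = float(np.sum(chi_exp ** 2))
        if denom == 0.0:
            raise ValueError("expected quantiles are all zero")
        return float(np.sum(chi_exp * chi_obs) / denom)
    if method == "median":
        med = float(np.median(chi_exp))
        if med == 0.0:
            raise ValueError("median expected quantile is zero")
        return float(np.median(chi_obs) / med)
    raise ValueError(f"unknown lambda method {method!r}")
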