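"""Site- and sample-QC unit tests with exact enumeration oracles."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarewas import qc
from rarewas.qc import (
    COLLAPSING_PROFILE,
    EXWAS_PROFILE,
    SiteQCMetrics,
    binomial_balance_test,
    differential_missingness_test,
    evaluate_site,
    filter_samples,
    gender_match_controls,
    hwe_exact_test,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def hwe_oracle(n_hom_ref, n_het, n_hom_alt):
    """Full enumeration over genotype configurations at fixed allele counts."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_alt + n_het
    rare = min(n_a, 2 * n - n_a)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_minor = (rare - h) // 2
        hom_major = n - h - hom_minor
        probs[h] = Fraction(2 ** h) * Fraction(
            math.factorial(n),
            math.factorial(hom_major) * math.factorial(h) * math.factorial(hom_minor),
        )
    total = sum(probs.values())
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs) / total)


def binom_two_sided_oracle(k, n):
    """Exact minimum-likelihood two-sided binomial p at theta = 1/2."""
    pmf = [Fraction(math.comb(n, i), 2 ** n) for i in range(n + 1)]
    obs = pmf[k]
    return float(sum(p for p in pmf if p <= obs))


# ---------------------------------------------------------------------------
# hwe
# ---------------------------------------------------------------------------

def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(100, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 50) == 1.0


def test_hwe_extreme_het_excess_fails_cutoff():
    assert hwe_exact_test(0, 100, 0) < 1e-5


@pytest.mark.parametrize("counts", [
    (5, 3, 2), (10, 0, 10), (20, 5, 0), (3, 3, 3), (50, 21, 4), (1, 1, 1),
    (40, 40, 20), (90, 9, 1),
])
def test_hwe_matches_enumeration(counts):
    assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 70), st.integers(0, 60), st.integers(0, 70))
def test_hwe_matches_enumeration_random(r, h, a):
    if r + h + a == 0:
        return
    assert hwe_exact_test(r, h, a) == pytest.approx(hwe_oracle(r, h, a), abs=1e-12)


def test_hwe_all_zero_errors():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# binomial tests
# ---------------------------------------------------------------------------

def test_balance_exact_values():
    assert binomial_balance_test(5, 10) == 1.0
    assert binomial_balance_test(1, 10) == pytest.approx(22 / 1024, abs=1e-12)
    assert binomial_balance_test(0, 40) < 1e-6


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(1, 80), st.data())
def test_balance_matches_enumeration(n, data):
    k = data.draw(st.integers(0, n))
    assert binomial_balance_test(k, n) == pytest.approx(
        binom_two_sided_oracle(k, n), abs=1e-12)


def test_balance_invalid_inputs():
    with pytest.raises(ValueError):
        binomial_balance_test(5, 0)
    with pytest.raises(ValueError):
        binomial_balance_test(11, 10)


def test_differential_missingness():
    # no missingness anywhere: vacuous test
    assert differential_missingness_test(0, 752, 0, 119055) == 1.0
    # grossly case-biased missingness is detected
    assert differential_missingness_test(50, 752, 0, 119055) < 1e-6
    # balanced missingness is unremarkable
    p = differential_missingness_test(5, 500, 10, 1000)
    assert p > 0.5


# ---------------------------------------------------------------------------
# site battery
# ---------------------------------------------------------------------------

def _clean_metrics(**overrides):
    base = dict(
        genotype_counts_cases=(100, 10, 1),
        genotype_counts_controls=(900, 90, 10),
        n_cases=111, n_controls=1000,
    )
    base.update(overrides)
    return SiteQCMetrics(**base)


def test_gq_below_threshold_single_reason():
    d = evaluate_site(_clean_metrics(gq=29), EXWAS_PROFILE)
    assert not d.passed
    assert d.reasons == ["gq"]


def test_fs_threshold_depends_on_variant_type():
    snv = evaluate_site(_clean_metrics(fs=100, is_snv=True), EXWAS_PROFILE)
    indel = evaluate_site(_clean_metrics(fs=100, is_snv=False), EXWAS_PROFILE)
    assert "fs" in snv.reasons
    assert "fs" not in indel.reasons


def test_boundary_values_pass():
    """Metrics exactly at their printed >=/<= bounds pass."""
    d = evaluate_site(_clean_metrics(
        gq=30, qual=30, mq=40, fs=60, rprs=-2, mqrs=-8,
        alt_fraction_het=0.3, external_coverage_fraction=0.5,
        external_zscore=-0.2, external_mq=30), EXWAS_PROFILE)
    assert d.passed and d.reasons == []


def test_all_failures_reported_not_just_first():
    d = evaluate_site(_clean_metrics(gq=10, mq=10, qual=10), EXWAS_PROFILE)
    assert set(d.reasons) == {"gq", "mq", "qual"}


def test_profiles_differ_where_designs_differ():
    # external coverage: 0.3 fails the scan profile, passes collapsing
    m = _clean_metrics(external_coverage_fraction=0.3)
    assert "external_coverage" in evaluate_site(m, EXWAS_PROFILE).reasons
    assert "external_coverage" not in evaluate_site(m, COLLAPSING_PROFILE).reasons
    # hom alt-fraction rule exists only in the collapsing profile
    m = _clean_metrics(alt_fraction_hom=0.6)
    assert evaluate_site(m, EXWAS_PROFILE).passed
    assert "alt_fraction_hom" in evaluate_site(m, COLLAPSING_PROFILE).reasons
    # external z-score bounds: -1.0 fails exwas (-0.2), passes collapsing (-2.0)
    m = _clean_metrics(external_zscore=-1.0)
    assert "external_zscore" in evaluate_site(m, EXWAS_PROFILE).reasons
    assert "external_zscore" not in evaluate_site(m, COLLAPSING_PROFILE).reasons


def test_hwe_rule_exwas_only():
    m = _clean_metrics(genotype_counts_controls=(0, 1000, 0))
    assert "hwe" in evaluate_site(m, EXWAS_PROFILE).reasons
    assert "hwe" not in evaluate_site(m, COLLAPSING_PROFILE).reasons


def test_unknown_profile_errors():
    bad = qc.QCThresholds(profile="bogus")
    with pytest.raises(ValueError):
        evaluate_site(_clean_metrics(), bad)


# ---------------------------------------------------------------------------
# sample filtering
# ---------------------------------------------------------------------------

def _manifest(n=50, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "phenotype": rng.integers(0, 2, n),
        "sex": rng.choice(["M", "F"], n),
        "contamination": np.full(n, 0.01),
        "european_prob": np.full(n, 0.999),
        "ccds_coverage": np.full(n, 0.98),
        "sex_concordant": True,
        "PC1": rng.normal(0, 1, n),
        "PC2": rng.normal(0, 1, n),
        "PC3": rng.normal(0, 1, n),
        "PC4": rng.normal(0, 1, n),
    })


def test_filter_samples_identity_on_clean_cohort():
    man = _manifest()
    kept, removed = filter_samples(man)
    assert len(kept) == len(man) and len(removed) == 0


def test_filter_samples_reason_codes():
    man = _manifest(100)
    man.loc[0, "contamination"] = 0.05
    man.loc[1, "european_prob"] = 0.9
    man.loc[2, "ccds_coverage"] = 0.90
    man.loc[3, "sex_concordant"] = False
    man.loc[4, "PC2"] = 30.0     # way beyond 4 SD
    kept, removed = filter_samples(man)
    reasons = removed.set_index("sample_id")["reasons"]
    assert reasons["S0"] == "contamination"
    assert reasons["S1"] == "ancestry"
    assert reasons["S2"] == "ccds_coverage"
    assert reasons["S3"] == "sex_discordance"
    assert "pc_outlier" in reasons["S4"]
    # partition conservation
    assert len(kept) + len(removed) == len(man)
    assert not set(kept["sample_id"]) & set(removed["sample_id"])


def test_filter_samples_missing_column_errors():
    man = _manifest().drop(columns=["contamination"])
    with pytest.raises(ValueError, match="contamination"):
        filter_samples(man)


# ---------------------------------------------------------------------------
# gender matching
# ---------------------------------------------------------------------------

def _controls(m, f):
    return pd.DataFrame({
        "sample_id": [f"C{i}" for i in range(m + f)],
        "phenotype": 0,
        "sex": ["M"] * m + ["F"] * f,
    })


def test_gender_match_closed_form_downsampling():
    kept = gender_match_controls(_controls(1000, 1000), 0.75, seed=1)
    assert (kept["sex"] == "M").sum() == 1000
    assert (kept["sex"] == "F").sum() == 333
    frac = (kept["sex"] == "M").mean()
    assert abs(frac - 0.75) < 1 / len(kept)


def test_gender_match_identity_when_already_at_target():
    ctrl = _controls(300, 100)
    kept = gender_match_controls(ctrl, 0.75, seed=3)
    assert len(kept) == 400


def test_gender_match_deterministic():
    a = gender_match_controls(_controls(500, 500), 0.6, seed=7)
    b = gender_match_controls(_controls(500, 500), 0.6, seed=7)
    assert list(a["sample_id"]) == list(b["sample_id"])


def test_gender_match_unattainable_errors():
    ctrl = _controls(0, 100)
    with pytest.raises(ValueError):
        gender_match_controls(ctrl, 0.75, seed=1)
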