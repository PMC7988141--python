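"""Genetic-architecture statistics tests."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from rarewas.architecture import (
    PathogenicRule,
    classify_carriers,
    clinical_compare,
    default_pathogenic_rules,
    effect_size_table,
    enrichment_hypergeometric,
    km_logrank,
    stratified_af_tests,
    telomere_logistic,
)
from rarewas.containers import GenotypeMatrix


# ---------------------------------------------------------------------------
# carrier classification
# ---------------------------------------------------------------------------

def _toy_cohort():
    """Five samples, five variants in telomere genes plus index/modifier."""
    ann = pd.DataFrame({
        "variant_id": ["ptv_ok", "mis_common", "mis_ultra", "idx", "mod"],
        "gene": ["RTEL1", "TERT", "TERT", "SPDL1", "MUC5B"],
        "consequence": ["ptv", "missense", "missense", "missense", "regulatory"],
        "popmax": [0.0004, 0.0004, 0.0, 0.008, 0.11],
        "clinvar_pathogenic": False,
        "alt_fraction_het": 0.5,
        "alt_reads_het": 15,
        "total_reads_het": 30,
        "gq": 60.0,
        "qual": 200.0,
        "ccds_transcript": True,
    })
    geno = np.array([
        [1, 0, 0, 0, 0],   # pathogenic PTV carrier
        [0, 1, 0, 0, 1],   # common missense: NOT a qualifying carrier
        [0, 0, 1, 0, 0],   # ultra-rare missense carrier
        [0, 0, 0, 1, 0],   # index-variant carrier
        [0, 0, 0, 0, 2],   # modifier only
    ], dtype=np.int8)
    gm = GenotypeMatrix(samples=np.array([f"S{i}" for i in range(5)]),
                        variants=ann["variant_id"].to_numpy(), geno=geno)
    return gm, ann


def test_classify_carriers_gene_rules():
    gm, ann = _toy_cohort()
    table, crosstab = classify_carriers(
        gm, ann, default_pathogenic_rules(), "idx", "mod")
    t = table.set_index("sample_id")
    # PTV at popmax 0.04% qualifies; missense requires popmax exactly 0
    assert t.loc["S0", "telomere_qv_carrier"]
    assert not t.loc["S1", "telomere_qv_carrier"]
    assert t.loc["S2", "telomere_qv_carrier"]
    assert t.loc["S3", "index_carrier"] and not t.loc["S3", "telomere_qv_carrier"]
    assert t.loc["S4", "modifier_carrier"] and t.loc["S4", "noncarrier"]
    # disjoint carrier sets here: no dual carriers
    assert crosstab.loc[True].get(True, 0) == 0


def test_classify_carriers_qc_subthresholds_gate():
    gm, ann = _toy_cohort()
    ann2 = ann.copy()
    ann2.loc[0, "gq"] = 20.0   # the PTV site now fails the GQ>=30 sub-rule
    table, _ = classify_carriers(gm, ann2, default_pathogenic_rules(),
                                 "idx", "mod")
    assert not table.set_index("sample_id").loc["S0", "telomere_qv_carrier"]


def test_classify_carriers_missing_variant_errors():
    gm, ann = _toy_cohort()
    with pytest.raises(ValueError):
        classify_carriers(gm, ann, default_pathogenic_rules(), "nope", "mod")


def test_classify_carriers_idempotent_under_variant_order():
    gm, ann = _toy_cohort()
    perm = [3, 1, 4, 0, 2]
    gm2 = GenotypeMatrix(samples=gm.samples, variants=gm.variants[perm],
                         geno=gm.geno[:, perm])
    t1, _ = classify_carriers(gm, ann, default_pathogenic_rules(), "idx", "mod")
    t2, _ = classify_carriers(gm2, ann, default_pathogenic_rules(), "idx", "mod")
    pd.testing.assert_frame_equal(t1, t2)


# ---------------------------------------------------------------------------
# stratified AF contrasts
# ---------------------------------------------------------------------------

def test_stratified_af_null_group():
    res = stratified_af_tests({"grp": (20, 200)}, (100, 1000),
                              or_method="woolf")
    row = res.iloc[0]
    assert row["p"] == 1.0
    assert row["or_point"] == pytest.approx(1.0, abs=0.05)


def test_stratified_af_empty_group_isolated():
    res = stratified_af_tests(
        {"empty": (0, 0), "ok": (30, 100)}, (100, 1000), or_method="woolf")
    assert res.iloc[0]["note"] == "empty_group"
    assert np.isnan(res.iloc[0]["p"])
    assert res.iloc[1]["p"] < 1e-6  # 30% vs 10%: strong enrichment
    assert list(res["group"]) == ["empty", "ok"]


def test_stratified_af_recovers_modifier_enrichment():
    """Monte-Carlo recovery of a modifier allele enriched OR~4.47 vs AF 11%."""
    rng = np.random.default_rng(11)
    ref_af, true_or = 0.11, 4.47
    grp_af = true_or * ref_af / (1 - ref_af + true_or * ref_af)
    n_grp, n_ref = 800, 30000
    ors = []
    for _ in range(150):
        alt = rng.binomial(n_grp, grp_af)
        ref_alt = rng.binomial(n_ref, ref_af)
        res = stratified_af_tests({"g": (alt, n_grp)}, (ref_alt, n_ref),
                                  or_method="woolf")
        ors.append(res.iloc[0]["or_point"])
    assert np.mean(ors) == pytest.approx(true_or, rel=0.05)


# ---------------------------------------------------------------------------
# telomere logistic model
# ---------------------------------------------------------------------------

def _irls_logistic(X, y, iters=60):
    """Independent IRLS oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        z = eta + (y - p) / W
        beta = np.linalg.solve((X * W[:, None]).T @ X, (X * W[:, None]).T @ z)
    return beta


def test_telomere_logistic_matches_irls_oracle():
    rng = np.random.default_rng(21)
    n = 300
    tl = rng.normal(6.5, 1.0, n)
    age = rng.normal(70, 8, n)
    sex = rng.choice(["M", "F"], n)
    logit = 2.0 - 0.5 * tl + 0.01 * age
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    model = telomere_logistic(y, tl, age, sex)
    X = np.column_stack([np.ones(n), tl, age, (sex == "M").astype(float)])
    oracle = _irls_logistic(X, y.astype(float))
    np.testing.assert_allclose(model.beta, oracle, atol=1e-6)
    assert model.p_lrt < 0.05 and model.or_per_unit < 1


def test_telomere_logistic_null_beta():
    rng = np.random.default_rng(22)
    n = 500
    y = rng.random(n) < 0.3
    model = telomere_logistic(y, rng.normal(6.5, 1, n), rng.normal(70, 8, n),
                              rng.choice(["M", "F"], n))
    assert abs(model.beta[1]) < 0.5
    assert model.p_lrt > 0.001


def test_telomere_logistic_separation_fallback():
    n = 40
    tl = np.r_[np.full(20, 4.0), np.full(20, 9.0)]
    y = tl < 5  # perfectly separated by telomere length
    age = np.linspace(50, 80, n)
    sex = np.array(["M", "F"] * 20)
    model = telomere_logistic(y, tl, age, sex, firth_fallback=True)
    assert model.method == "firth"
    assert np.all(np.isfinite(model.beta))
    with pytest.raises(RuntimeError):
        telomere_logistic(y, tl, age, sex, firth_fallback=False)


def test_telomere_logistic_degenerate_errors():
    with pytest.raises(ValueError):
        telomere_logistic(np.ones(10), np.arange(10), np.arange(10),
                          np.array(["M"] * 10))


# ---------------------------------------------------------------------------
# clinical comparisons
# ---------------------------------------------------------------------------

def test_mann_whitney_exact_small_example():
    df = pd.DataFrame({"grp": [1, 1, 0, 0], "x": [1.0, 2.0, 3.0, 4.0]})
    res = clinical_compare(df, "grp", ["x"])
    assert res.iloc[0]["statistic"] == 0.0
    assert res.iloc[0]["p"] == pytest.approx(2 / 6, abs=1e-12)


def test_mann_whitney_matches_permutation_enumeration():
    """Exact p equals full enumeration over label assignments (n <= 12)."""
    x = np.array([3.1, 5.2, 1.0, 7.4, 2.2, 6.6])
    labels = np.array([1, 1, 1, 0, 0, 0])
    df = pd.DataFrame({"grp": labels, "x": x})
    p_impl = clinical_compare(df, "grp", ["x"]).iloc[0]["p"]

    def ustat(mask):
        a = x[np.array(mask)]
        b = x[~np.array(mask)]
        return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)

    u_obs = ustat(labels.astype(bool))
    us = []
    for combo in itertools.combinations(range(6), 3):
        mask = np.zeros(6, bool)
        mask[list(combo)] = True
        us.append(ustat(mask))
    us = np.array(us)
    lo = (us <= u_obs).mean()
    hi = (us >= u_obs).mean()
    p_enum = min(1.0, 2 * min(lo, hi))
    assert p_impl == pytest.approx(p_enum, abs=1e-12)


def test_identical_groups_p_one():
    df = pd.DataFrame({"grp": [1, 1, 0, 0], "x": [5.0, 7.0, 5.0, 7.0]})
    assert clinical_compare(df, "grp", ["x"]).iloc[0]["p"] == 1.0


def test_median_imputation_uses_cohort_median():
    vals = [1.0, 2.0, 3.0, 4.0, np.nan, np.nan]
    df = pd.DataFrame({"grp": [1, 1, 1, 0, 0, 0], "x": vals})
    # imputing with the cohort median (2.5) must reproduce this comparison
    imputed = pd.DataFrame({"grp": df["grp"],
                            "x": [1.0, 2.0, 3.0, 4.0, 2.5, 2.5]})
    a = clinical_compare(df, "grp", ["x"]).iloc[0]["p"]
    b = clinical_compare(imputed, "grp", ["x"]).iloc[0]["p"]
    assert a == b


def test_binary_column_uses_fisher():
    df = pd.DataFrame({"grp": [1] * 10 + [0] * 10,
                       "male": [1] * 9 + [0] + [1] * 2 + [0] * 8})
    res = clinical_compare(df, "grp", ["male"], binary_cols=("male",))
    assert res.iloc[0]["test"] == "fisher_exact"
    assert res.iloc[0]["p"] < 0.01


def test_all_missing_column_errors():
    df = pd.DataFrame({"grp": [1, 0], "x": [np.nan, np.nan]})
    with pytest.raises(ValueError, match="x"):
        clinical_compare(df, "grp", ["x"])


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def test_km_identical_groups_null():
    times = np.array([5.0, 10, 15, 20, 5, 10, 15, 20])
    events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
    groups = np.array(["A"] * 4 + ["B"] * 4)
    curves, stat, p, df = km_logrank(times, events, groups)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=1e-9)
    # curves start at 1 and never increase
    for _, grp in curves.groupby("group"):
        s = grp.sort_values("time")["survival"].to_numpy()
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)


def test_km_logrank_matches_hand_calculation():
    """Observed-minus-expected over event times, two groups, no ties."""
    times = np.array([1.0, 2, 3, 4, 5, 6])
    events = np.array([1, 1, 1, 1, 1, 1])
    groups = np.array(["A", "A", "A", "B", "B", "B"])
    _, stat, p, _ = km_logrank(times, events, groups)
    # hand computation of the log-rank statistic
    o_minus_e, var = 0.0, 0.0
    at_risk_a, at_risk_b = 3, 3
    for t, g in zip(times, groups):
        n = at_risk_a + at_risk_b
        e_a = at_risk_a / n
        o_a = 1.0 if g == "A" else 0.0
        o_minus_e += o_a - e_a
        var += at_risk_a * at_risk_b / n ** 2 if n > 1 else 0
        if g == "A":
            at_risk_a -= 1
        else:
            at_risk_b -= 1
    # variance for single events: n1*n2*(n-d)/(n^2*(n-1)) with d=1
    var = 0.0
    at_risk_a, at_risk_b = 3, 3
    for t, g in zip(times, groups):
        n = at_risk_a + at_risk_b
        if n > 1:
            var += at_risk_a * at_risk_b * (n - 1) / (n ** 2 * (n - 1))
        if g == "A":
            at_risk_a -= 1
        else:
            at_risk_b -= 1
    assert stat == pytest.approx(o_minus_e ** 2 / var, rel=1e-6)


def test_km_all_censored_undefined():
    times = np.array([5.0, 6, 7, 8])
    events = np.zeros(4, int)
    groups = np.array(["A", "A", "B", "B"])
    _, stat, p, _ = km_logrank(times, events, groups)
    assert math.isnan(stat) and math.isnan(p)


def test_km_negative_times_error():
    with pytest.raises(ValueError):
        km_logrank([-1.0, 2.0], [1, 1], ["A", "B"])


# ---------------------------------------------------------------------------
# enrichment + effect-size table
# ---------------------------------------------------------------------------

def test_hypergeometric_worked_example():
    p = enrichment_hypergeometric({"a", "b"}, {"a", "b"}, {"a", "b", "c", "d"})
    assert p == pytest.approx(1 / 6, abs=1e-12)


def test_hypergeometric_zero_overlap_large_universe():
    uni = {f"g{i}" for i in range(1000)}
    p = enrichment_hypergeometric({"g1", "g2"}, {"g900", "g901"}, uni)
    assert p > 0.99


def test_hypergeometric_matches_enumeration():
    """Exact comparison against a combinatorial oracle over a grid."""
    M, n, N = 40, 12, 9
    uni = [f"g{i}" for i in range(M)]
    pred = set(uni[:n])
    for k in range(0, min(n, N) + 1):
        top = set(uni[:k]) | set(uni[n:n + (N - k)])
        p = enrichment_hypergeometric(top, pred, set(uni))
        oracle = sum(
            Fraction(math.comb(n, i) * math.comb(M - n, N - i),
                     math.comb(M, N))
            for i in range(k, min(n, N) + 1))
        assert p == pytest.approx(float(oracle), abs=1e-12)


def test_hypergeometric_monotone_in_overlap():
    M, n, N = 60, 15, 10
    uni = [f"g{i}" for i in range(M)]
    ps = []
    for k in range(0, N + 1):
        top = set(uni[:k]) | set(uni[n:n + (N - k)])
        ps.append(enrichment_hypergeometric(top, set(uni[:n]), set(uni)))
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_hypergeometric_subset_violation_errors():
    with pytest.raises(ValueError):
        enrichment_hypergeometric({"x"}, {"a"}, {"a", "b"})


def test_effect_size_table_merge_and_uniqueness():
    src = dict(locus=["L1", "L2", "L3"], control_freq=[0.3, 0.1, 0.2],
               or_point=[2.0, 3.0, 4.0], ci_low=[1, 1, 1], ci_high=[9, 9, 9],
               variant_class=["snv"] * 3)
    src2 = {**src, "locus": ["L4", "L5", "L6"]}
    merged = effect_size_table([pd.DataFrame(src), pd.DataFrame(src2)])
    assert len(merged) == 6
    assert list(merged["control_freq"]) == sorted(merged["control_freq"])
    assert len(effect_size_table([])) == 0
    with pytest.raises(ValueError, match="duplicate"):
        effect_size_table([pd.DataFrame(src), pd.DataFrame(src)])
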