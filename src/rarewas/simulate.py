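"""Seeded synthetic case-control cohort generator.

The generator emulates the structure of an imbalanced sequencing-based
case-control study of a late-onset fibrotic lung disease: a few hundred
cases against a much larger screened control cohort, a rare missense
index risk variant (control allele frequency ~0.78%, allelic odds ratio
~2.87), a handful of genes carrying rare protein-truncating-variant
burdens with large carrier odds ratios (~13-43), a common modifier
allele (control AF ~11%) enriched within case subgroups, shorter
telomeres in carriers of the burden-gene variants, and optional spiked
QC defects of every filter class handled by :mod:`rarewas.qc`.

Genotypes are drawn under Hardy-Weinberg equilibrium within each
stratum; case enrichment at effect variants is applied on the allele
(gamete) level via the odds transform ``p_case = OR*q / (1 - q + OR*q)``
for control allele frequency ``q``, then paired into genotypes.
Variants are sampled independently (no linkage disequilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "IndexVariant",
    "BurdenGene",
    "ModifierAllele",
    "QCSpike",
    "TrueArchitecture",
    "default_truth",
    "generate_cohort",
    "generate_replication_cohort",
    "attach_clinical",
    "write_cohort",
    "SPIKE_EXPECTED_REASONS",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Cohort dimensions and sampling distributions.

    ``baseline_af_spectrum`` is a small distribution spec for control
    allele frequencies of the null variants; the default log-uniform
    spectrum on [1e-4, 0.1] spans rare to common coding variation.
    Consequence classes are drawn per variant from a categorical
    distribution (default 5% protein-truncating, 65% missense, 30%
    synonymous; the proportions are a modelling choice, not an
    empirical spectrum).
    """

    n_cases: int = 752
    n_controls: int = 10_000
    n_variants: int = 1_000
    n_genes: int = 100
    baseline_af_spectrum: dict = field(
        default_factory=lambda: {"kind": "loguniform", "low": 1e-4, "high": 0.1}
    )
    male_fraction_cases: float = 0.75
    male_fraction_controls: float = 0.5
    age_mean: float = 71.0
    age_sd: float = 8.0
    consequence_proportions: dict = field(
        default_factory=lambda: {"ptv": 0.05, "missense": 0.65, "synonymous": 0.30}
    )
    missing_rate: float = 5e-4
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_variants", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("male_fraction_cases", "male_fraction_controls",
                     "missing_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.consequence_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("consequence proportions must sum to 1")


@dataclass
class IndexVariant:
    variant_id: str
    control_af: float
    odds_ratio: float
    gene: str = "INDEXGENE"
    consequence: str = "missense"


@dataclass
class BurdenGene:
    gene_id: str
    qv_class: str = "ptv"
    carrier_odds_ratio: float = 13.6
    control_carrier_freq: float = 3e-4
    n_qvs: int = 4


@dataclass
class ModifierAllele:
    variant_id: str = "mod1"
    control_af: float = 0.11
    gene: str = "MODGENE"
    consequence: str = "regulatory"
    # within-case enrichment odds ratio per carrier class, vs. reference AF
    class_odds: dict = field(
        default_factory=lambda: {"telomere_qv": 2.13, "index": 2.95, "other": 4.47}
    )


@dataclass
class QCSpike:
    variant_id: str
    metric: str
    value: object = None


@dataclass
class TrueArchitecture:
    """Known embedded effects used as simulation ground truth."""

    index_variants: list = field(default_factory=list)
    burden_genes: list = field(default_factory=list)
    modifier: ModifierAllele | None = None
    telomere_shortening: float = 0.12     # fractional shortening for burden carriers
    qc_spikes: list = field(default_factory=list)

    def validate(self) -> None:
        for iv in self.index_variants:
            if iv.odds_ratio <= 0:
                raise ValueError("odds ratios must be positive")
            if not (0.0 < iv.control_af <= 0.5):
                raise ValueError("control AFs must lie in (0, 0.5]")
        for bg in self.burden_genes:
            if bg.carrier_odds_ratio <= 0:
                raise ValueError("odds ratios must be positive")
            if not (0.0 < bg.control_carrier_freq <= 0.5):
                raise ValueError("carrier frequencies must lie in (0, 0.5]")
        if not (0.0 <= self.telomere_shortening < 1.0):
            raise ValueError("telomere shortening must lie in [0, 1)")
        for sp in self.qc_spikes:
            if sp.metric not in SPIKE_EXPECTED_REASONS:
                raise ValueError(f"unknown QC spike class {sp.metric!r}")


def default_truth(n_genes: int = 100) -> TrueArchitecture:
    """The study architecture used as the simulation default."""
    return TrueArchitecture(
        index_variants=[IndexVariant("idx1", control_af=0.0078, odds_ratio=2.87)],
        burden_genes=[
            BurdenGene("G0001", carrier_odds_ratio=13.6),
            BurdenGene("G0002", carrier_odds_ratio=28.9),
            BurdenGene("G0003", carrier_odds_ratio=43.3),
        ],
        modifier=ModifierAllele(),
        telomere_shortening=0.12,
    )


# QC spike classes and the site-QC reason codes they are built to trigger
# (in the exwas profile unless noted).  Used by tests and by validation.
SPIKE_EXPECTED_REASONS = {
    "gq": ["gq"],
    "qual": ["qual"],
    "mq": ["mq"],
    "fs": ["fs"],
    "rprs": ["rprs"],
    "mqrs": ["mqrs"],
    "caller": ["caller"],
    "alt_fraction_het": ["alt_fraction_het"],
    "alt_fraction_hom": ["alt_fraction_hom"],       # collapsing profile
    "balance": ["balance"],
    "external_coverage": ["external_coverage"],
    "external_zscore": ["external_zscore"],
    "external_mq": ["external_mq"],
    "failed_calls": ["failed_calls"],
    "ccds": ["ccds"],                                # collapsing profile
    "coverage_cases": ["missingness_cases"],
    "missingness": ["missingness_cases", "missingness_controls"],
    "diff_missingness": ["diff_missingness"],
    "hwe": ["hwe"],
}

_SPIKE_DEFAULTS = {
    "gq": 10.0, "qual": 10.0, "mq": 30.0, "fs": 100.0, "rprs": -5.0,
    "mqrs": -10.0, "caller": False, "alt_fraction_het": 0.15,
    "alt_fraction_hom": 0.6, "balance": (350, 1000),
    "external_coverage": 0.1, "external_zscore": -3.0, "external_mq": 20.0,
    "failed_calls": 0.01, "ccds": False, "coverage_cases": 0.95,
    "missingness": 0.02, "diff_missingness": 7, "hwe": None,
}


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def risk_af(control_af: float, odds_ratio: float) -> float:
    """Case allele frequency implied by a control AF and allelic OR."""
    q = control_af
    p = odds_ratio * q / (1.0 - q + odds_ratio * q)
    if not (0.0 < p < 1.0):
        raise ValueError(
            f"case AF implied by (AF={q}, OR={odds_ratio}) outside (0, 1)"
        )
    return p


def _draw_afs(rng, spec: dict, n: int) -> np.ndarray:
    kind = spec.get("kind", "loguniform")
    if kind == "loguniform":
        lo, hi = spec["low"], spec["high"]
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    if kind == "uniform":
        return rng.uniform(spec["low"], spec["high"], size=n)
    if kind == "fixed":
        return np.full(n, float(spec["value"]))
    raise ValueError(f"unknown AF spectrum kind {kind!r}")


def _draw_geno_block(rng, afs: np.ndarray, n: int, chunk: int = 512) -> np.ndarray:
    """HWE binomial genotype draws, chunked to keep memory flat."""
    out = np.empty((n, len(afs)), dtype=np.int8)
    for start in range(0, len(afs), chunk):
        sl = slice(start, min(start + chunk, len(afs)))
        out[:, sl] = rng.binomial(2, afs[sl], size=(n, sl.stop - sl.start))
    return out


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig, truth: TrueArchitecture):
    """Generate (GenotypeMatrix, annotation, manifest) for one cohort.

    Deterministic given (config, truth): the same seed reproduces the
    cohort byte for byte.
    """
    return _generate(config, truth, af_inflation=1.0)


def generate_replication_cohort(config: SimConfig, truth: TrueArchitecture,
                                af_inflation: float = 1.0):
    """Independent cohort with effect-locus control AFs scaled up.

    Emulates a bottleneck population in which the index allele drifted
    to a higher baseline frequency.  Effect-locus AFs that would reach
    0.5 after inflation raise an error; null-variant spectra are capped
    just below 0.5.
    """
    if af_inflation <= 0:
        raise ValueError("af_inflation must be positive")
    return _generate(config, truth, af_inflation=af_inflation)


def _generate(config: SimConfig, truth: TrueArchitecture, af_inflation: float):
    config.validate()
    truth.validate()
    rng = np.random.default_rng(config.seed)
    n_cases, n_controls = config.n_cases, config.n_controls
    n_samples = n_cases + n_controls

    # --- variant frame: null variants in contiguous gene blocks ------------
    genes = np.array([f"G{i + 1:04d}" for i in range(config.n_genes)])
    gene_of = genes[
        np.minimum(
            np.arange(config.n_variants) * config.n_genes // config.n_variants,
            config.n_genes - 1,
        )
    ]
    variant_ids = [f"v{i + 1:06d}" for i in range(config.n_variants)]
    classes = list(config.consequence_proportions)
    probs = np.array([config.consequence_proportions[c] for c in classes])
    consequence = rng.choice(classes, size=config.n_variants, p=probs)
    afs = _draw_afs(rng, config.baseline_af_spectrum, config.n_variants)
    if af_inflation != 1.0:
        afs = np.minimum(afs * af_inflation, 0.499)

    # --- wire the truth into the variant frame -----------------------------
    burden_cols: dict[str, list[int]] = {}
    for bg in truth.burden_genes:
        if bg.gene_id not in genes:
            raise ValueError(f"burden gene {bg.gene_id!r} not among generated genes")
        members = np.flatnonzero(gene_of == bg.gene_id)
        if len(members) < bg.n_qvs:
            raise ValueError(
                f"gene {bg.gene_id!r} has fewer than {bg.n_qvs} variants")
        cols = members[: bg.n_qvs].tolist()
        burden_cols[bg.gene_id] = cols
        for j in cols:
            consequence[j] = bg.qv_class
            afs[j] = 0.0  # genotypes come from the carrier mechanism below

    extra_ids, extra_genes, extra_csq, extra_af_ctrl, extra_af_case = [], [], [], [], []
    for iv in truth.index_variants:
        q = iv.control_af * af_inflation
        if q >= 0.5:
            raise ValueError(
                f"inflated control AF {q:.3g} at effect locus {iv.variant_id!r} "
                "reaches 0.5")
        extra_ids.append(iv.variant_id)
        extra_genes.append(iv.gene)
        extra_csq.append(iv.consequence)
        extra_af_ctrl.append(q)
        extra_af_case.append(risk_af(q, iv.odds_ratio))
    modifier_col = None
    if truth.modifier is not None:
        q = truth.modifier.control_af * af_inflation
        if q >= 0.5:
            raise ValueError("inflated modifier AF reaches 0.5")
        modifier_col = config.n_variants + len(extra_ids)
        extra_ids.append(truth.modifier.variant_id)
        extra_genes.append(truth.modifier.gene)
        extra_csq.append(truth.modifier.consequence)
        extra_af_ctrl.append(q)
        extra_af_case.append(q)  # case genotypes assigned per carrier class below

    all_ids = np.array(variant_ids + extra_ids)
    all_genes = np.concatenate([gene_of, np.array(extra_genes, dtype=object)]) \
        if extra_genes else gene_of
    all_csq = np.concatenate([consequence, np.array(extra_csq, dtype=object)]) \
        if extra_csq else consequence
    af_ctrl_vec = np.concatenate([afs, np.array(extra_af_ctrl)]) \
        if extra_af_ctrl else afs
    af_case_vec = np.concatenate([afs, np.array(extra_af_case)]) \
        if extra_af_case else afs.copy()

    # --- genotypes ----------------------------------------------------------
    geno_cases = _draw_geno_block(rng, af_case_vec, n_cases)
    geno_controls = _draw_geno_block(rng, af_ctrl_vec, n_controls)
    geno = np.vstack([geno_cases, geno_controls])

    # burden genes: carrier-level sampling, one heterozygous QV per carrier
    telomere_carrier = np.zeros(n_samples, dtype=bool)
    for bg in truth.burden_genes:
        f0 = min(bg.control_carrier_freq * af_inflation, 0.5)
        if bg.control_carrier_freq * af_inflation >= 0.5:
            raise ValueError(
                f"inflated carrier frequency at burden gene {bg.gene_id!r} "
                "reaches 0.5")
        f1 = risk_af(f0, bg.carrier_odds_ratio)
        carrier = np.concatenate([
            rng.random(n_cases) < f1,
            rng.random(n_controls) < f0,
        ])
        cols = burden_cols[bg.gene_id]
        geno[:, cols] = 0
        which = rng.integers(0, len(cols), size=int(carrier.sum()))
        rows = np.flatnonzero(carrier)
        geno[rows, np.array(cols)[which]] = 1
        telomere_carrier |= carrier

    index_carrier = np.zeros(n_samples, dtype=bool)
    for k, iv in enumerate(truth.index_variants):
        col = config.n_variants + k
        index_carrier |= geno[:, col] >= 1

    # modifier allele: case genotypes depend on carrier class
    modifier_carrier = np.zeros(n_samples, dtype=bool)
    if truth.modifier is not None:
        q = truth.modifier.control_af * af_inflation
        case_class = np.where(
            telomere_carrier[:n_cases], "telomere_qv",
            np.where(index_carrier[:n_cases], "index", "other"))
        af_case_mod = np.array([
            risk_af(q, truth.modifier.class_odds.get(c, 1.0)) for c in case_class
        ])
        geno[:n_cases, modifier_col] = rng.binomial(2, af_case_mod)
        modifier_carrier = geno[:, modifier_col] >= 1

    # random missingness
    if config.missing_rate > 0:
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = MISSING

    # --- annotation ---------------------------------------------------------
    n_var_total = len(all_ids)
    ann = pd.DataFrame({
        "variant_id": all_ids,
        "gene": all_genes,
        "consequence": all_csq,
        "generating_af": af_ctrl_vec,
    })
    called = geno >= 0
    alt = np.where(called, geno, 0)
    with np.errstate(invalid="ignore"):
        ann["af_cases"] = alt[:n_cases].sum(0) / np.maximum(
            2 * called[:n_cases].sum(0), 1)
        ann["af_controls"] = alt[n_cases:].sum(0) / np.maximum(
            2 * called[n_cases:].sum(0), 1)
        ann["af_internal"] = alt.sum(0) / np.maximum(2 * called.sum(0), 1)
    popmax = af_ctrl_vec * rng.uniform(0.5, 1.5, n_var_total)
    for bg in truth.burden_genes:          # burden QVs are absent externally
        popmax[burden_cols[bg.gene_id]] = 0.0
    for k, iv in enumerate(truth.index_variants):
        popmax[config.n_variants + k] = extra_af_ctrl[k]
    ann["popmax"] = np.minimum(popmax, 0.5)
    ann["clinvar_pathogenic"] = False
    # fraction of coding sites falling in missense-intolerant regions
    ann["intolerant_region"] = rng.random(n_var_total) < 0.2
    # site QC metrics, drawn inside passing ranges
    ann["is_snv"] = True
    ann["coverage_fraction_cases"] = rng.uniform(0.995, 1.0, n_var_total)
    ann["coverage_fraction_controls"] = rng.uniform(0.995, 1.0, n_var_total)
    ann["gq"] = rng.uniform(45.0, 99.0, n_var_total)
    ann["qual"] = rng.uniform(100.0, 1000.0, n_var_total)
    ann["mq"] = rng.uniform(50.0, 60.0, n_var_total)
    ann["fs"] = rng.uniform(0.0, 20.0, n_var_total)
    ann["rprs"] = rng.uniform(-1.0, 1.0, n_var_total)
    ann["mqrs"] = rng.uniform(-2.0, 2.0, n_var_total)
    ann["caller_pass"] = True
    ann["alt_fraction_het"] = rng.uniform(0.45, 0.55, n_var_total)
    ann["alt_fraction_hom"] = rng.uniform(0.9, 1.0, n_var_total)
    ann["alt_reads_het"] = 15
    ann["total_reads_het"] = 30
    ann["failed_fraction_cases"] = 0.0
    ann["failed_fraction_controls"] = 0.0
    ann["external_observed"] = ann["popmax"] > 0
    ann["external_coverage_fraction"] = rng.uniform(0.8, 1.0, n_var_total)
    ann["external_mq"] = rng.uniform(40.0, 60.0, n_var_total)
    ann["external_zscore"] = rng.uniform(-0.1, 1.0, n_var_total)
    ann["ccds_transcript"] = True

    # --- manifest -----------------------------------------------------------
    sex = np.concatenate([
        np.where(rng.random(n_cases) < config.male_fraction_cases, "M", "F"),
        np.where(rng.random(n_controls) < config.male_fraction_controls, "M", "F"),
    ])
    manifest = pd.DataFrame({
        "sample_id": [f"S{i + 1:06d}" for i in range(n_samples)],
        "phenotype": np.r_[np.ones(n_cases, int), np.zeros(n_controls, int)],
        "sex": sex,
        "age": np.clip(rng.normal(config.age_mean, config.age_sd, n_samples),
                       40, 95),
        "PC1": rng.normal(0, 1.0, n_samples),
        "PC2": rng.normal(0, 0.8, n_samples),
        "PC3": rng.normal(0, 0.6, n_samples),
        "PC4": rng.normal(0, 0.5, n_samples),
        "contamination": rng.uniform(0.0, 0.02, n_samples),
        "european_prob": rng.uniform(0.99, 1.0, n_samples),
        "ccds_coverage": rng.uniform(0.96, 0.995, n_samples),
        "sex_concordant": True,
        "unrelated": True,
        "telomere_qv_carrier": telomere_carrier,
        "index_carrier": index_carrier,
        "modifier_carrier": modifier_carrier,
    })

    gm = GenotypeMatrix(
        samples=manifest["sample_id"].to_numpy(),
        variants=all_ids,
        geno=geno,
    )
    _apply_spikes(gm, ann, manifest, truth.qc_spikes, rng)
    return gm, ann, manifest


def _apply_spikes(gm: GenotypeMatrix, ann: pd.DataFrame, manifest: pd.DataFrame,
                  spikes, rng) -> None:
    """Inject QC defects so each spiked site fails its intended filter."""
    n_cases = int((manifest["phenotype"] == 1).sum())
    ann_ix = {v: i for i, v in enumerate(ann["variant_id"])}
    metric_cols = {
        "gq": "gq", "qual": "qual", "mq": "mq", "fs": "fs", "rprs": "rprs",
        "mqrs": "mqrs", "caller": "caller_pass",
        "alt_fraction_het": "alt_fraction_het",
        "alt_fraction_hom": "alt_fraction_hom",
        "external_coverage": "external_coverage_fraction",
        "external_zscore": "external_zscore", "external_mq": "external_mq",
        "ccds": "ccds_transcript", "coverage_cases": "coverage_fraction_cases",
    }
    for sp in spikes:
        if sp.variant_id not in ann_ix:
            raise ValueError(f"spiked variant {sp.variant_id!r} not in cohort")
        i = ann_ix[sp.variant_id]
        j = gm.variant_index(sp.variant_id)
        value = sp.value if sp.value is not None else _SPIKE_DEFAULTS[sp.metric]
        if sp.metric in metric_cols:
            ann.loc[i, metric_cols[sp.metric]] = value
        elif sp.metric == "balance":
            alt_reads, total_reads = value
            ann.loc[i, "alt_reads_het"] = alt_reads
            ann.loc[i, "total_reads_het"] = total_reads
            ann.loc[i, "alt_fraction_het"] = alt_reads / total_reads
        elif sp.metric == "failed_calls":
            ann.loc[i, "failed_fraction_cases"] = value
        elif sp.metric == "missingness":
            # same missing fraction in both cohorts: trips the per-cohort
            # missingness rule without differential signal
            n = gm.n_samples
            k_cases = max(1, int(np.ceil(value * n_cases)))
            k_ctrl = max(1, int(np.ceil(value * (n - n_cases))))
            gm.geno[rng.choice(n_cases, k_cases, replace=False), j] = MISSING
            gm.geno[n_cases + rng.choice(n - n_cases, k_ctrl, replace=False), j] = MISSING
            ann.loc[i, "coverage_fraction_cases"] = 1.0 - value
            ann.loc[i, "coverage_fraction_controls"] = 1.0 - value
        elif sp.metric == "diff_missingness":
            # a few missing cases, none in controls: significant imbalance
            # while staying under the 1% per-cohort missingness bound
            # (requires a large control cohort, as in the study design)
            k = int(value)
            gm.geno[rng.choice(n_cases, k, replace=False), j] = MISSING
        elif sp.metric == "hwe":
            # heterozygote excess in both cohorts
            called = gm.geno[:, j] >= 0
            gm.geno[called, j] = 1
        else:  # pragma: no cover - guarded by TrueArchitecture.validate
            raise ValueError(f"unknown spike class {sp.metric!r}")


# ---------------------------------------------------------------------------
# clinical layer
# ---------------------------------------------------------------------------

def attach_clinical(manifest: pd.DataFrame, truth: TrueArchitecture, seed: int,
                    telomere_median_kb: float = 6.5, telomere_log_sd: float = 0.15,
                    survival_median_months: float = 39.4,
                    carrier_hazard_ratio: float = 1.6,
                    event_fraction: float = 0.7,
                    missing_rate: float = 0.1) -> pd.DataFrame:
    """Attach telomere lengths, survival and clinical columns to cases.

    Telomere lengths are log-normal; carriers of burden-gene qualifying
    variants have their median multiplied by ``1 - shortening``.
    Survival times are exponential with the configured cohort median,
    scaled down for burden carriers.  Clinical measurements (height,
    weight, FVC, DLCO) get missing values injected at ``missing_rate``.
    """
    s = truth.telomere_shortening
    if not (0.0 <= s < 1.0):
        raise ValueError("telomere shortening must lie in [0, 1)")
    if "telomere_qv_carrier" not in manifest.columns:
        raise ValueError("carrier classes must be assigned before attach_clinical")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    n = len(out)
    carrier = out["telomere_qv_carrier"].to_numpy(dtype=bool)
    median = np.where(carrier, telomere_median_kb * (1.0 - s), telomere_median_kb)
    out["telomere_kb"] = np.exp(
        rng.normal(np.log(median), telomere_log_sd, size=n))
    scale = survival_median_months / np.log(2.0)
    scale_vec = np.where(carrier, scale / carrier_hazard_ratio, scale)
    out["survival_months"] = rng.exponential(scale_vec)
    out["event"] = (rng.random(n) < event_fraction).astype(int)
    out["height_cm"] = rng.normal(170, 9, n)
    out["weight_kg"] = rng.normal(78, 14, n)
    out["fvc_pct"] = rng.normal(75, 18, n)
    out["dlco_pct"] = rng.normal(48, 15, n)
    for col in ("height_cm", "weight_kg", "fvc_pct", "dlco_pct"):
        out.loc[rng.random(n) < missing_rate, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_cohort(triple, out_dir, seed: int = 0) -> dict:
    """Write (genotypes, annotation, manifest) as VCF v4.2 + TSVs.

    Per-call FORMAT fields (GQ, DP, AD) are materialised from pass-range
    distributions consistent with each genotype.  Round-trips losslessly
    through :func:`rarewas.io.read_vcf` / the TSV readers.
    """
    import os

    from . import io as rio

    gm, ann, manifest = triple
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "annotation": os.path.join(out_dir, "annotation.tsv"),
        "manifest": os.path.join(out_dir, "manifest.tsv"),
    }
    rio.write_vcf(gm, paths["vcf"], annotation=ann, seed=seed)
    ann.to_csv(paths["annotation"], sep="\t", index=False)
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    return paths
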