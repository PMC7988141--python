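"""Qualifying-variant gene-burden (collapsing) analysis.

For each gene and each collapsing model, variants satisfying the
model's predicate (consequence class, internal minor allele frequency,
external population-maximum frequency, optional intolerant-region
restriction, collapsing-profile QC) are aggregated, and the proportion
of cases carrying at least one qualifying allele is compared to the
proportion of controls by Fisher's exact test.  The recessive model
requires two qualifying alleles (one homozygote or two heterozygous
qualifying variants, phase-unaware).  A synonymous-variant model is
carried as an empirical negative control.

The shipped 11-model suite (10 non-synonymous + synonymous control) is
an approximation assembled from the field's common design — tiers of
internal MAF and external popmax bounds over protein-truncating and
missense classes, an intolerant-region-restricted missense model and a
recessive model — and is fully user-overridable; exact model
definitions in any given study are rarely reproducible from a primary
text.

Cross-study combination uses the Cochran-Mantel-Haenszel test (without
continuity correction) with the Mantel-Haenszel common odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import StratifiedTable

from .exwas import ContingencyTable, fisher_exact

__all__ = [
    "QVModel",
    "GeneBurdenResult",
    "default_model_suite",
    "is_qualifying",
    "qualifying_mask",
    "collapse_carriers",
    "gene_burden_test",
    "cmh_combine",
    "run_collapsing",
]

STUDY_WIDE_P = 2.4e-7

PTV_CLASSES = frozenset({"ptv", "stop_gained", "frameshift", "splice"})
MISSENSE_CLASSES = frozenset({"missense"})


@dataclass(frozen=True)
class QVModel:
    """Declarative predicate describing qualifying variants."""

    name: str
    allowed_consequences: frozenset
    internal_maf_max: float = 1e-3
    external_popmax_max: float = 1e-3
    require_intolerant_region: bool = False
    zygosity: str = "dominant"
    qc_profile: str = "collapsing"
    negative_control: bool = False

    def __post_init__(self):
        if not (0.0 <= self.internal_maf_max <= 1.0
                and 0.0 <= self.external_popmax_max <= 1.0):
            raise ValueError("model frequency bounds must lie in [0, 1]")
        if self.zygosity not in ("dominant", "recessive"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")


def default_model_suite() -> list[QVModel]:
    """Eleven models: ten non-synonymous plus a synonymous negative control."""
    ns = PTV_CLASSES | MISSENSE_CLASSES
    return [
        QVModel("ptv", PTV_CLASSES, 1e-3, 1e-3),
        QVModel("ptv_ultrarare", PTV_CLASSES, 5e-5, 0.0),
        QVModel("flexible_nonsyn", ns, 1e-3, 1e-3),
        QVModel("flexible_nonsyn_strict", ns, 5e-5, 5e-5),
        QVModel("ultrarare_nonsyn", ns, 5e-5, 0.0),
        QVModel("rare_nonsyn_mtr", ns, 1e-3, 1e-3,
                require_intolerant_region=True),
        QVModel("missense_intolerant", MISSENSE_CLASSES, 1e-3, 1e-3,
                require_intolerant_region=True),
        QVModel("rare_missense", MISSENSE_CLASSES, 1e-3, 1e-3),
        QVModel("ultrarare_missense", MISSENSE_CLASSES, 5e-5, 0.0),
        QVModel("recessive", ns, 1e-2, 1e-2, zygosity="recessive"),
        QVModel("synonymous", frozenset({"synonymous"}), 5e-3, 5e-3,
                negative_control=True),
    ]


_MODEL_FIELDS = ["consequence", "af_internal", "popmax"]


def qualifying_mask(annotation: pd.DataFrame, model: QVModel,
                    qc_pass=None) -> np.ndarray:
    """Boolean qualifying-variant flags over an annotation frame."""
    for col in _MODEL_FIELDS:
        if col not in annotation.columns:
            raise ValueError(f"annotation is missing required field {col!r}")
    if model.require_intolerant_region and "intolerant_region" not in annotation.columns:
        raise ValueError("annotation is missing required field 'intolerant_region'")
    maf = np.minimum(annotation["af_internal"].to_numpy(dtype=float),
                     1.0 - annotation["af_internal"].to_numpy(dtype=float))
    mask = (
        annotation["consequence"].isin(model.allowed_consequences).to_numpy()
        & (maf < model.internal_maf_max)
        & (annotation["popmax"].to_numpy(dtype=float) <= model.external_popmax_max)
    )
    if model.require_intolerant_region:
        mask &= annotation["intolerant_region"].to_numpy(dtype=bool)
    if qc_pass is not None:
        mask &= np.asarray(qc_pass, dtype=bool)
    return mask


def is_qualifying(variant: pd.Series, model: QVModel, qc_pass: bool = True) -> bool:
    """Single-variant predicate; see :func:`qualifying_mask`."""
    return bool(qualifying_mask(variant.to_frame().T, model,
                                [qc_pass])[0])


def collapse_carriers(geno: np.ndarray, qv_flags: np.ndarray,
                      gene_ids: np.ndarray, zygosity: str = "dominant"):
    """Per-sample carrier indicator per gene.

    ``geno`` is samples x variants additive-coded; missing genotypes
    contribute zero alleles.  Dominant carriers hold >=1 qualifying
    allele in the gene; recessive carriers hold >=2 (a homozygote or
    two heterozygous qualifying variants, counted phase-unaware).

    Returns (genes, carrier matrix samples x genes, bool).
    """
    if len(qv_flags) != geno.shape[1] or len(gene_ids) != geno.shape[1]:
        raise ValueError("qv_flags and gene_ids must align to genotype columns")
    threshold = 1 if zygosity == "dominant" else 2
    genes = pd.unique(pd.Series(gene_ids))
    counts = np.zeros((geno.shape[0], len(genes)), dtype=np.int32)
    qv_cols = np.flatnonzero(np.asarray(qv_flags, dtype=bool))
    if len(qv_cols):
        alleles = np.where(geno[:, qv_cols] > 0, geno[:, qv_cols], 0).astype(np.int32)
        gene_pos = {g: k for k, g in enumerate(genes)}
        dest = np.array([gene_pos[g] for g in np.asarray(gene_ids)[qv_cols]])
        np.add.at(counts.T, dest, alleles.T)
    return genes, counts >= threshold


@dataclass
class GeneBurdenResult:
    gene: str
    model: str
    case_carriers: int
    n_cases: int
    control_carriers: int
    n_controls: int
    p: float
    or_point: float
    ci95: tuple
    study_wide: bool


def gene_burden_test(gene: str, model: str, case_carriers: int, n_cases: int,
                     control_carriers: int, n_controls: int,
                     or_method: str = "conditional",
                     study_wide_p: float = STUDY_WIDE_P) -> GeneBurdenResult:
    """Fisher's exact test on the carrier 2x2 for one gene and model."""
    table = ContingencyTable(
        case_carriers, n_cases - case_carriers,
        control_carriers, n_controls - control_carriers,
        exposure_coding="dominant-carrier")
    res = fisher_exact(table, or_method=or_method)
    return GeneBurdenResult(
        gene=gene, model=model,
        case_carriers=case_carriers, n_cases=n_cases,
        control_carriers=control_carriers, n_controls=n_controls,
        p=res.p, or_point=res.or_point, ci95=(res.ci_low, res.ci_high),
        study_wide=res.p < study_wide_p)


def cmh_combine(strata, correction: bool = False):
    """Cochran-Mantel-Haenszel combination of per-stratum 2x2 tables.

    ``strata`` is a sequence of (a, b, c, d) carrier tables in
    consistent orientation.  Returns (chi-square statistic, 1-df
    p-value, Mantel-Haenszel common odds ratio).  No continuity
    correction by default, so a single stratum reduces to the classical
    uncorrected chi-square for that table.
    """
    strata = [tuple(int(x) for x in s) for s in strata]
    if not strata:
        raise ValueError("at least one stratum required")
    ok = [s for s in strata
          if (s[0] + s[1]) > 0 and (s[2] + s[3]) > 0
          and (s[0] + s[2]) > 0 and (s[1] + s[3]) > 0]
    if not ok:
        raise ValueError("all strata degenerate")
    tables = np.array([[[a, b], [c, d]] for a, b, c, d in ok], dtype=float)
    st = StratifiedTable(tables.transpose(1, 2, 0))
    res = st.test_null_odds(correction=correction)
    return float(res.statistic), float(res.pvalue), float(st.oddsratio_pooled)


def run_collapsing(genotypes, annotation: pd.DataFrame, manifest: pd.DataFrame,
                   models: list[QVModel] | None = None,
                   qc_report: pd.DataFrame | None = None,
                   or_method: str = "woolf",
                   study_wide_p: float = STUDY_WIDE_P) -> pd.DataFrame:
    """Run every collapsing model over every gene.

    Returns one row per gene x model with carrier counts, Fisher p, OR
    and CI; synonymous-model rows are flagged ``negative_control`` so
    they can be segregated as the empirical null panel.
    """
    if models is None:
        models = default_model_suite()
    if not models:
        raise ValueError("empty model suite")
    sample_ids = list(genotypes.samples)
    man = manifest.set_index("sample_id").loc[sample_ids]
    case_mask = man["phenotype"].to_numpy() == 1
    n_cases = int(case_mask.sum())
    n_controls = int((~case_mask).sum())
    ann = annotation.set_index("variant_id").loc[list(genotypes.variants)].reset_index()
    qc_pass = None
    if qc_report is not None:
        qc_pass = (qc_report.set_index("variant_id")["qc_pass"]
                   .reindex(genotypes.variants).fillna(False).to_numpy(dtype=bool))
    gene_ids = ann["gene"].to_numpy()
    rows = []
    for model in models:
        flags = qualifying_mask(ann, model, qc_pass)
        genes, carriers = collapse_carriers(
            genotypes.geno, flags, gene_ids, model.zygosity)
        case_c = carriers[case_mask].sum(axis=0)
        ctrl_c = carriers[~case_mask].sum(axis=0)
        for k, gene in enumerate(genes):
            r = gene_burden_test(
                gene, model.name, int(case_c[k]), n_cases,
                int(ctrl_c[k]), n_controls, or_method=or_method,
                study_wide_p=study_wide_p)
            rows.append((r.gene, r.model, model.negative_control,
                         r.case_carriers, r.n_cases, r.control_carriers,
                         r.n_controls, r.p, r.or_point, r.ci95[0], r.ci95[1],
                         r.study_wide))
    return pd.DataFrame(rows, columns=[
        "gene", "model", "negative_control", "case_carriers", "n_cases",
        "control_carriers", "n_controls", "p", "or_point", "ci_low",
        "ci_high", "study_wide"])
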