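"""End-to-end workflow: sample QC -> site QC -> ExWAS -> replication ->
collapsing -> cross-study combination -> calibration -> architecture
statistics, with a machine-readable run report.

Every stage writes its counts in and out to the report so that the
partition telescopes: each stage's input equals the previous stage's
output, and no sample or variant appears in two mutually exclusive
partitions.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import collapsing as clp
from . import exwas as ex
from . import io as rio
from . import meta
from . import qc

log = logging.getLogger("rarewas")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for one pipeline run.

    Threshold defaults are the conventional study values: variants
    observed in >=12 individuals enter the scan, genome-wide
    significance at p < 5e-8, collapsing study-wide significance at
    p < 2.4e-7, and replication review of variants at p < 0.01.
    """

    genotypes: str = ""
    annotation: str = ""
    manifest: str = ""
    replication_genotypes: str | None = None
    replication_annotation: str | None = None
    replication_manifest: str | None = None
    out_dir: str = "run"
    qc_profile: str = "exwas"
    min_observed: int = 12
    genome_wide_p: float = 5e-8
    study_wide_p: float = 2.4e-7
    replication_p: float = 0.01
    gender_match_target: float | None = None
    n_permutations: int = 10
    or_method: str = "conditional"
    count_rule: str = "carriers"
    seed: int = 0
    schema_version: int = 1

    def to_yaml(self, path) -> None:
        rio.dump_config(asdict(self), path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**rio.load_config(path))


def _stage(report, name, n_in, n_out, **extra):
    entry = {"stage": name, "n_in": int(n_in), "n_out": int(n_out), **extra}
    report["stages"].append(entry)
    log.info("stage %-22s in=%d out=%d", name, n_in, n_out)


def run_pipeline(config: RunConfig) -> str:
    """Execute the full workflow; returns the run directory path."""
    os.makedirs(config.out_dir, exist_ok=True)
    report = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_observed": config.min_observed,
            "genome_wide_p": config.genome_wide_p,
            "study_wide_p": config.study_wide_p,
            "replication_p": config.replication_p,
        },
        "seeds": {"pipeline": config.seed,
                  "gender_match": config.seed + 1,
                  "permutation_null": config.seed + 2},
        "stages": [],
    }
    try:
        _run_stages(config, report)
        report["status"] = "complete"
    except Exception as err:
        report["status"] = "failed"
        report["failed_stage"] = report["stages"][-1]["stage"] if report["stages"] else "input"
        report["error"] = f"{type(err).__name__}: {err}"
        _write_report(report, config.out_dir)
        raise
    _write_report(report, config.out_dir)
    return config.out_dir


def _write_report(report, out_dir):
    with open(os.path.join(out_dir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)


def _load_triple(geno_path, ann_path, man_path):
    return (rio.read_genotypes(geno_path), rio.read_annotation(ann_path),
            rio.read_manifest(man_path))


def _run_stages(config: RunConfig, report: dict) -> None:
    out = config.out_dir
    gm, ann, manifest = _load_triple(
        config.genotypes, config.annotation, config.manifest)

    # ---- sample harmonisation -------------------------------------------
    kept, removed = qc.filter_samples(manifest)
    _stage(report, "sample_qc", len(manifest), len(kept),
           n_removed=len(removed))
    removed.to_csv(os.path.join(out, "samples_removed.tsv"), sep="\t",
                   index=False)
    if config.gender_match_target is not None:
        matched_controls = qc.gender_match_controls(
            kept, config.gender_match_target, seed=config.seed + 1)
        cases = kept[kept["phenotype"] == 1]
        harmonised = pd.concat([cases, matched_controls]).sort_index()
    else:
        harmonised = kept
    _stage(report, "gender_match", len(kept), len(harmonised))
    gm = gm.subset_samples(harmonised["sample_id"].to_numpy())

    # ---- site QC ---------------------------------------------------------
    site_report = qc.run_site_qc(gm, ann, harmonised, profile=config.qc_profile)
    site_report.to_csv(os.path.join(out, "site_qc.tsv"), sep="\t", index=False)
    n_pass = int(site_report["qc_pass"].sum())
    _stage(report, "site_qc", gm.n_variants, n_pass)

    # ---- ExWAS -----------------------------------------------------------
    results, exclusions = ex.run_exwas(
        gm, ann, harmonised, qc_report=site_report,
        min_observed=config.min_observed, or_method=config.or_method,
        count_rule=config.count_rule, genome_wide_p=config.genome_wide_p)
    results.to_csv(os.path.join(out, "exwas_results.tsv"), sep="\t", index=False)
    exclusions.to_csv(os.path.join(out, "exwas_exclusions.tsv"), sep="\t",
                      index=False)
    _stage(report, "exwas", n_pass, len(results),
           n_genome_wide=int(results["genome_wide"].sum()))

    # ---- replication + combination --------------------------------------
    candidates = meta.select_replication_candidates(
        results, threshold=config.replication_p)
    _stage(report, "replication_selection", len(results), len(candidates))
    if config.replication_genotypes:
        rgm, rann, rman = _load_triple(
            config.replication_genotypes, config.replication_annotation,
            config.replication_manifest)
        rres, _ = ex.run_exwas(rgm, rann, rman,
                               min_observed=config.min_observed,
                               or_method="woolf")
        rres = rres.set_index("variant_id")
        combined = []
        for _, row in candidates.iterrows():
            vid = row["variant_id"]
            if vid not in rres.index:
                combined.append(np.nan)
                continue
            rrow = rres.loc[vid]
            mi = meta.MetaInput(
                p=[max(row["p_fet"], meta.P_FLOOR),
                   max(rrow["p_fet"], meta.P_FLOOR)],
                direction=[np.sign(np.log(row["or_point"])) or 0.0,
                           np.sign(np.log(rrow["or_point"])) or 0.0])
            combined.append(meta.stouffer_combine(mi))
        candidates = candidates.assign(p_combined=combined)
        _stage(report, "meta_combination", len(candidates), len(candidates))
    candidates.to_csv(os.path.join(out, "replication_candidates.tsv"),
                      sep="\t", index=False)

    # ---- collapsing ------------------------------------------------------
    collapse_qc = qc.run_site_qc(gm, ann, harmonised, profile="collapsing")
    burden = clp.run_collapsing(gm, ann, harmonised,
                                qc_report=collapse_qc, or_method="woolf",
                                study_wide_p=config.study_wide_p)
    burden[~burden["negative_control"]].to_csv(
        os.path.join(out, "collapsing_results.tsv"), sep="\t", index=False)
    burden[burden["negative_control"]].to_csv(
        os.path.join(out, "collapsing_negative_control.tsv"), sep="\t",
        index=False)
    _stage(report, "collapsing", gm.n_variants, len(burden),
           n_models=int(burden["model"].nunique()))

    # ---- calibration -----------------------------------------------------
    calib = meta.permutation_null(
        gm, harmonised, n_perm=config.n_permutations,
        seed=config.seed + 2, min_observed=config.min_observed)
    pd.DataFrame({
        "rank": np.arange(1, len(calib.observed_p) + 1),
        "expected_p": calib.expected_p,
        "observed_p": calib.observed_p,
    }).to_csv(os.path.join(out, "qq_table.tsv"), sep="\t", index=False)
    report["calibration"] = {
        "lambda_regression": calib.lambda_regression,
        "lambda_median": calib.lambda_median,
        "n_permutations": calib.n_permutations,
    }
    _stage(report, "calibration", len(results), len(calib.observed_p))
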