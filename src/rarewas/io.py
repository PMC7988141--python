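"""File I/O: VCF v4.2, genotype-matrix/annotation/manifest TSVs, YAML config.

The primary desk-scale interchange format is a TSV genotype matrix
(variants x samples, additive 0/1/2 coding, ``NA`` for missing).  VCF
v4.2 with GT/GQ/DP/AD FORMAT fields is supported for realism; reading
goes through cyvcf2 and splits multi-allelic records into bi-allelic
rows (one row per alternate allele, each counting only its own allele).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "read_genotypes",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_vcf",
    "write_vcf",
    "read_annotation",
    "read_manifest",
    "load_config",
    "dump_config",
]


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def read_genotypes(path) -> GenotypeMatrix:
    """Dispatch on extension: ``.vcf``/``.vcf.gz`` or genotype TSV."""
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return read_vcf(p)
    return read_genotype_tsv(p)


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read a variants x samples additive-coded TSV (NA = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "variant_id":
        raise ValueError(
            f"genotype TSV must have a 'variant_id' first column, "
            f"got {df.index.name!r}")
    geno = df.to_numpy(dtype=float).T  # -> samples x variants
    bad = ~(np.isnan(geno) | np.isin(geno, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype code {geno[i, j]!r} for sample "
            f"{df.columns[i]!r}, variant {df.index[j]!r}")
    geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    return GenotypeMatrix(
        samples=df.columns.to_numpy(), variants=df.index.to_numpy(), geno=geno)


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        gm.geno.T.astype(object), index=gm.variants, columns=gm.samples)
    df[df == MISSING] = "NA"
    df.index.name = "variant_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=rarewas
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=1>
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, annotation: pd.DataFrame | None = None,
              seed: int = 0) -> None:
    """Emit a VCF v4.2 with GT:GQ:DP:AD per call.

    Per-call GQ/DP/AD come from the matrix's per-call arrays when
    present, otherwise from seeded pass-range distributions consistent
    with each genotype (depth ~30x, balanced het alt fractions).
    """
    rng = np.random.default_rng(seed)
    ann = None
    if annotation is not None:
        ann = annotation.set_index("variant_id")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, gm.samples)) + "\n")
        for j, vid in enumerate(gm.variants):
            info = "."
            qual = "100"
            if ann is not None and vid in ann.index:
                row = ann.loc[vid]
                info = f"GENE={row['gene']};CSQ={row['consequence']}"
                if "qual" in row.index:
                    qual = f"{float(row['qual']):.0f}"
            g = gm.geno[:, j]
            if gm.depth is not None:
                dp = gm.depth[:, j].astype(int)
            else:
                dp = rng.integers(20, 45, size=len(g))
            if gm.gq is not None:
                gq = gm.gq[:, j].astype(int)
            else:
                gq = rng.integers(35, 99, size=len(g))
            alt_reads = np.select(
                [g == 0, g == 1, g == 2],
                [0, np.round(dp * 0.5).astype(int), np.round(dp * 0.95).astype(int)],
                default=0)
            calls = []
            for i in range(len(g)):
                if g[i] == MISSING:
                    calls.append("./.:.:.:.")
                else:
                    calls.append(
                        f"{_GT_STRINGS[int(g[i])]}:{gq[i]}:{dp[i]}:"
                        f"{dp[i] - alt_reads[i]},{alt_reads[i]}")
            fh.write(f"1\t{j + 1}\t{vid}\tA\tG\t{qual}\tPASS\t{info}\tGT:GQ:DP:AD\t"
                     + "\t".join(calls) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into an additive genotype matrix.

    Multi-allelic records are split into one bi-allelic row per
    alternate allele; each split row counts only its own allele, and
    genotypes carrying a different alternate allele count as 0 for that
    row.  Missing calls map to the missing sentinel.  Per-call GQ and DP
    are loaded when the FORMAT declares them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    variant_ids, geno_rows, gq_rows, dp_rows = [], [], [], []
    has_gq = has_dp = True
    for rec in vcf:
        gts = np.array(rec.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=int)
        for alt_index, alt in enumerate(rec.ALT, start=1):
            vid = rec.ID if rec.ID and len(rec.ALT) == 1 else (
                f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}")
            counts = (alleles == alt_index).sum(axis=1).astype(np.int8)
            counts[(alleles < 0).any(axis=1)] = MISSING
            variant_ids.append(vid)
            geno_rows.append(counts)
            if has_gq:
                try:
                    gq_rows.append(rec.format("GQ").reshape(-1).astype(float))
                except (TypeError, AttributeError, KeyError):
                    has_gq = False
            if has_dp:
                try:
                    dp_rows.append(rec.format("DP").reshape(-1).astype(float))
                except (TypeError, AttributeError, KeyError):
                    has_dp = False
    geno = (np.vstack(geno_rows).T if geno_rows
            else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(
        samples=samples,
        variants=np.array(variant_ids),
        geno=geno,
        gq=np.vstack(gq_rows).T if has_gq and gq_rows else None,
        depth=np.vstack(dp_rows).T if has_dp and dp_rows else None,
    )


# ---------------------------------------------------------------------------
# tables and config
# ---------------------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "variant_id" not in df.columns:
        raise ValueError("annotation TSV must have a 'variant_id' column")
    return df


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"manifest TSV must have a {col!r} column")
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
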