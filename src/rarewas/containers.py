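"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1  # reserved missing-genotype sentinel, distinct from 0/1/2


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes, samples x variants.

    ``geno`` holds 0/1/2 alt-allele counts with :data:`MISSING` (-1) for
    uncalled genotypes.  Optional per-call metric arrays (same shape)
    carry genotype quality, depth and alt-read fraction when the data
    came from a VCF or when the simulator was asked to materialise
    them; they are ``None`` for large desk-scale matrices.
    """

    samples: np.ndarray
    variants: np.ndarray
    geno: np.ndarray
    gq: np.ndarray | None = None
    depth: np.ndarray | None = None
    alt_fraction: np.ndarray | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        self.variants = np.asarray(self.variants)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.samples), len(self.variants)):
            raise ValueError("geno shape must be (n_samples, n_variants)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        idx = np.flatnonzero(self.variants == variant_id)
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in matrix")
        return int(idx[0])

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        order = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([order[s] for s in sample_ids], dtype=int)
        return GenotypeMatrix(
            samples=self.samples[idx],
            variants=self.variants,
            geno=self.geno[idx],
            gq=None if self.gq is None else self.gq[idx],
            depth=None if self.depth is None else self.depth[idx],
            alt_fraction=None if self.alt_fraction is None else self.alt_fraction[idx],
        )
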