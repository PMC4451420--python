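"""In-memory containers for SNP-array genotype and haplotype data.

Genotypes are diploid alternate-allele counts (0/1/2) with a distinct
missing sentinel; haplotypes are phased 0/1 alleles, two rows per sample.
Variant maps are pandas DataFrames sorted by (chrom, pos_bp), 1-based
physical coordinates throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid genotype call.  Kept far from {0,1,2} so
#: that accidental arithmetic on missing cells is loud, never silent.
MISSING: int = -9

VARIANT_COLUMNS = ["id", "chrom", "pos_bp", "allele_ref", "allele_alt"]

#: Recognised gene biotypes; anything else maps to "other" on read.
BIOTYPES = frozenset(
    {"protein_coding", "miRNA", "snoRNA", "snRNA", "rRNA", "pseudogene", "other"}
)


class VariantRecord(NamedTuple):
    """One SNP: identifier, chromosome, 1-based position and its two alleles."""

    id: str
    chrom: str
    pos_bp: int
    allele_ref: str
    allele_alt: str


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Numeric chromosomes sort numerically, others lexically after them."""
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, str(chrom))


def sort_variant_table(variants: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Return variants sorted by (chrom, pos_bp) plus the applied permutation."""
    keys = [_chrom_sort_key(c) for c in variants["chrom"]]
    order = np.array(
        sorted(range(len(variants)), key=lambda i: (keys[i], int(variants["pos_bp"].iloc[i]))),
        dtype=int,
    )
    out = variants.iloc[order].reset_index(drop=True)
    return out, order


def validate_variant_table(variants: pd.DataFrame) -> None:
    missing_cols = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing_cols:
        raise ValueError(f"variant table missing columns: {missing_cols}")
    if (variants["pos_bp"] < 1).any():
        raise ValueError("variant positions must be >= 1 (1-based)")
    dup = variants.duplicated(subset=["chrom", "pos_bp"])
    if dup.any():
        where = variants.loc[dup, ["chrom", "pos_bp"]].iloc[0]
        raise ValueError(f"duplicate variant position {where.chrom}:{where.pos_bp}")
    same = variants["allele_ref"] == variants["allele_alt"]
    # An unseen alternate allele is written '.' by the PED reader.
    if (same & (variants["allele_alt"] != ".")).any():
        raise ValueError("allele_ref must differ from allele_alt")


@dataclass
class GenotypeDataset:
    """Diploid genotype matrix plus variant map and population metadata.

    ``calls`` has shape (n_samples, n_variants) with entries in
    {0, 1, 2, MISSING} counting copies of ``allele_alt``.
    """

    variants: pd.DataFrame
    samples: list[str]
    populations: dict[str, str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        validate_variant_table(self.variants)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")
        unlabeled = [s for s in self.samples if s not in self.populations]
        if unlabeled:
            raise ValueError(f"samples without a population label: {unlabeled[:5]}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def population_names(self) -> list[str]:
        """Populations in order of first appearance among samples."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples) if self.populations[s] == population],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"population {population!r} not present in dataset")
        return idx

    def variant_records(self) -> Iterator[VariantRecord]:
        for row in self.variants.itertuples(index=False):
            yield VariantRecord(row.id, row.chrom, int(row.pos_bp), row.allele_ref, row.allele_alt)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    # -- subsetting (always copies; datasets are treated as immutable) ---
    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        variant_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeDataset":
        sidx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx, int)
        vidx = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx, int)
        samples = [self.samples[i] for i in sidx]
        return GenotypeDataset(
            variants=self.variants.iloc[vidx].reset_index(drop=True),
            samples=samples,
            populations={s: self.populations[s] for s in samples},
            calls=self.calls[np.ix_(sidx, vidx)].copy(),
        )


@dataclass
class HaplotypeSet:
    """Phased haplotypes for one chromosome.

    Rows 2i and 2i+1 of ``haplotypes`` are the two chromosome copies of
    ``samples[i]``; entries are 0 (reference) or 1 (alternate), no missing.
    """

    variants: pd.DataFrame
    samples: list[str]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        validate_variant_table(self.variants)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2 != 0:
            raise ValueError("haplotype matrix must be 2-D with an even row count")
        if self.haplotypes.shape != (2 * len(self.samples), len(self.variants)):
            raise ValueError(
                f"haplotypes shape {self.haplotypes.shape} != "
                f"({2 * len(self.samples)}, {len(self.variants)})"
            )
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0 or 1")
        if self.variants["chrom"].nunique() > 1:
            raise ValueError("a HaplotypeSet holds a single chromosome")
        pos = self.variants["pos_bp"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError("variants must be sorted by position")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chrom(self) -> str:
        return str(self.variants["chrom"].iloc[0])

    def positions(self) -> np.ndarray:
        return self.variants["pos_bp"].to_numpy(dtype=np.int64)

    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def to_genotypes(self) -> np.ndarray:
        """Collapse phase: per-sample alternate-allele counts (n, m) int8."""
        return (self.haplotypes[0::2].astype(np.int16) + self.haplotypes[1::2]).astype(np.int8)


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval with its molecule-class biotype (1-based inclusive)."""

    id: str
    chrom: str
    start_bp: int
    end_bp: int
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.start_bp < 1:
            raise ValueError(f"gene {self.id}: start_bp must be >= 1")
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.id}: start_bp > end_bp")
        if self.biotype not in BIOTYPES:
            object.__setattr__(self, "biotype", "other")
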