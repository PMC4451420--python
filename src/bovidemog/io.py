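"""Readers and writers for the text formats the pipeline speaks.

PLINK-style PED/MAP for genotypes (whitespace-delimited, allele code 0 =
missing), a HAPS-style table for phased haplotypes, BED4+/GFF3 for gene
features, and a two-column TSV for sample→population assignment.  All
writers round-trip bit-exactly through their paired reader.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    BIOTYPES,
    GeneFeature,
    GenotypeDataset,
    HaplotypeSet,
    sort_variant_table,
)


class ParseError(ValueError):
    """A malformed record in an input file; the message names the line."""


class MetadataError(ValueError):
    """Sample metadata inconsistent with the genotype files."""


# ---------------------------------------------------------------------------
# population table
# ---------------------------------------------------------------------------

def read_population_table(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV (sample_id, population); '#' lines are comments."""
    pops: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}: line {ln}: expected 'sample population'")
            pops[parts[0]] = parts[1]
    return pops


def write_population_table(populations: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s, p in populations.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# PED/MAP genotypes
# ---------------------------------------------------------------------------

def _read_map(map_path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            # 4-column PLINK MAP (chrom, id, cM, bp); a 3-column dialect
            # without the genetic-distance field is also accepted.
            if len(parts) == 4:
                chrom, vid, _cm, pos = parts
            elif len(parts) == 3:
                chrom, vid, pos = parts
            else:
                raise ParseError(f"{map_path}: line {ln}: expected 3 or 4 fields")
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ParseError(f"{map_path}: line {ln}: bad position {pos!r}") from exc
            rows.append((vid, chrom, pos_i))
    return pd.DataFrame(rows, columns=["id", "chrom", "pos_bp"])


def read_genotypes(
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
    pop_table: str | os.PathLike,
) -> GenotypeDataset:
    """Read a PED/MAP pair plus population table into a GenotypeDataset.

    Alternate allele = second distinct allele observed per variant in PED
    order; genotype code counts copies of it.  Allele code "0" is missing.
    Variants are returned sorted by (chrom, pos_bp) with call columns
    permuted consistently.
    """
    variants = _read_map(map_path)
    m = len(variants)
    populations = read_population_table(pop_table)

    samples: list[str] = []
    geno_rows: list[np.ndarray] = []
    # first/second distinct allele seen per variant, '.' while unseen
    a1 = np.full(m, ".", dtype=object)
    a2 = np.full(m, ".", dtype=object)

    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * m} fields "
                    f"(6 + 2 alleles x {m} SNPs), got {len(parts)}"
                )
            sid = parts[1]
            if sid not in populations:
                raise MetadataError(
                    f"{ped_path}: line {ln}: sample {sid!r} missing from population table"
                )
            alleles = parts[6:]
            row = np.empty(m, dtype=np.int8)
            for v in range(m):
                x, y = alleles[2 * v], alleles[2 * v + 1]
                if x == "0" or y == "0":
                    row[v] = MISSING
                    continue
                count = 0
                for al in (x, y):
                    if a1[v] == ".":
                        a1[v] = al
                    elif al != a1[v] and a2[v] == ".":
                        a2[v] = al
                    if al == a2[v]:
                        count += 1
                    elif al != a1[v]:
                        raise ParseError(
                            f"{ped_path}: line {ln}: variant {variants['id'].iloc[v]} "
                            f"has >2 alleles ({a1[v]}, {a2[v]}, {al})"
                        )
                row[v] = count
            samples.append(sid)
            geno_rows.append(row)

    calls = np.vstack(geno_rows) if geno_rows else np.empty((0, m), dtype=np.int8)
    variants["allele_ref"] = a1.astype(str)
    variants["allele_alt"] = a2.astype(str)
    variants = variants[["id", "chrom", "pos_bp", "allele_ref", "allele_alt"]]
    variants, order = sort_variant_table(variants)
    return GenotypeDataset(
        variants=variants,
        samples=samples,
        populations={s: populations[s] for s in samples},
        calls=calls[:, order],
    )


def write_genotypes(
    ds: GenotypeDataset,
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
) -> None:
    """Write PED/MAP; missing calls become '0 0'."""
    with open(map_path, "w") as fh:
        for v in ds.variants.itertuples(index=False):
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos_bp}\n")
    refs = ds.variants["allele_ref"].to_numpy(dtype=object)
    alts = ds.variants["allele_alt"].to_numpy(dtype=object)
    # a '.' alternate (monomorphic variant) can never be emitted: code is 0
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(ds.samples):
            fields = [ds.populations[sid], sid, "0", "0", "0", "-9"]
            row = ds.calls[i]
            for v in range(ds.n_variants):
                g = row[v]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [refs[v], refs[v]]
                elif g == 1:
                    fields += [refs[v], alts[v]]
                else:
                    fields += [alts[v], alts[v]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# HAPS-style phased haplotypes
# ---------------------------------------------------------------------------

def read_haplotypes(path: str | os.PathLike, samples: list[str] | None = None) -> HaplotypeSet:
    """Read a HAPS-style table: chrom id pos ref alt then one 0/1 per haplotype.

    An optional header line ``#samples s1 s2 ...`` carries sample ids; when
    absent (and ``samples`` not given) samples are named hap pairs h0, h1...
    """
    rows = []
    hap_cols: list[list[int]] = []
    file_samples: list[str] | None = None
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#samples"):
                file_samples = line.split()[1:]
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}: line {ln}: expected at least 6 fields")
            chrom, vid, pos, ref, alt = parts[:5]
            alleles = parts[5:]
            if hap_cols and len(alleles) != len(hap_cols[0]):
                raise ParseError(f"{path}: line {ln}: inconsistent haplotype count")
            try:
                vals = [int(a) for a in alleles]
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: non-integer allele") from exc
            if any(a not in (0, 1) for a in vals):
                raise ParseError(f"{path}: line {ln}: haplotype alleles must be 0 or 1")
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: bad position {pos!r}") from exc
            rows.append((vid, chrom, pos_i, ref, alt))
            hap_cols.append(vals)

    if not rows:
        raise ParseError(f"{path}: empty haplotype file")
    n_hap = len(hap_cols[0])
    if n_hap % 2 != 0:
        raise ParseError(f"{path}: odd haplotype count {n_hap} (two per sample expected)")
    if samples is None:
        samples = file_samples if file_samples is not None else [f"h{i}" for i in range(n_hap // 2)]
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos_bp", "allele_ref", "allele_alt"])
    haps = np.array(hap_cols, dtype=np.uint8).T  # (n_hap, n_variants)
    return HaplotypeSet(variants=variants, samples=list(samples), haplotypes=haps)


def write_haplotypes(hs: HaplotypeSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#samples " + " ".join(hs.samples) + "\n")
        H = hs.haplotypes
        for j, v in enumerate(hs.variants.itertuples(index=False)):
            alleles = " ".join(str(int(a)) for a in H[:, j])
            fh.write(f"{v.chrom} {v.id} {v.pos_bp} {v.allele_ref} {v.allele_alt} {alleles}\n")


# ---------------------------------------------------------------------------
# gene features
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.split(";"):
        item = item.strip()
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_features(path: str | os.PathLike, fmt: str) -> list[GeneFeature]:
    """Read gene features from BED4+ (0-based half-open, optional 5th-column
    biotype) or GFF3 (1-based inclusive, biotype/gene_biotype attribute).

    Unknown biotypes map to "other".  BED coordinates are converted to the
    package's 1-based inclusive convention on read.
    """
    if fmt not in ("bed", "gff3"):
        raise ValueError(f"fmt must be 'bed' or 'gff3', got {fmt!r}")
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if fmt == "bed":
                if len(parts) < 4:
                    raise ParseError(f"{path}: line {ln}: BED4+ needs >= 4 columns")
                chrom, start, end, name = parts[:4]
                biotype = parts[4] if len(parts) > 4 and parts[4] in BIOTYPES else (
                    "other" if len(parts) > 4 else "other"
                )
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as exc:
                    raise ParseError(f"{path}: line {ln}: bad BED coordinates") from exc
                if end_i <= start_i:
                    raise ParseError(f"{path}: line {ln}: empty/negative BED interval")
                feats.append(GeneFeature(name, chrom, start_i + 1, end_i, biotype))
            else:
                if len(parts) < 9:
                    raise ParseError(f"{path}: line {ln}: GFF3 needs 9 columns")
                chrom, _src, ftype, start, end, _score, _strand, _phase, attr = parts[:9]
                if ftype != "gene":
                    continue
                attrs = _parse_gff3_attributes(attr)
                name = attrs.get("ID", attrs.get("Name", f"gene_line{ln}"))
                biotype = attrs.get("biotype", attrs.get("gene_biotype", "other"))
                if biotype not in BIOTYPES:
                    biotype = "other"
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as exc:
                    raise ParseError(f"{path}: line {ln}: bad GFF3 coordinates") from exc
                feats.append(GeneFeature(name, chrom, start_i, end_i, biotype))
    return feats


def write_features_bed(features: Iterable[GeneFeature], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start_bp - 1}\t{f.end_bp}\t{f.id}\t{f.biotype}\n")
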