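"""Shared fixtures: hand-written text fixtures and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bovidemog.datatypes import MISSING, GenotypeDataset, HaplotypeSet
from bovidemog.simulate import PopulationSpec, SimConfig, simulate


def make_hapset(H, positions, chrom="1"):
    """HaplotypeSet from a raw 0/1 matrix and positions."""
    H = np.asarray(H, dtype=np.uint8)
    positions = np.asarray(positions, dtype=np.int64)
    m = H.shape[1]
    variants = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(m)],
            "chrom": chrom,
            "pos_bp": positions,
            "allele_ref": "A",
            "allele_alt": "B",
        }
    )
    return HaplotypeSet(
        variants=variants,
        samples=[f"x{i}" for i in range(H.shape[0] // 2)],
        haplotypes=H,
    )


def make_dataset(calls, populations=None, positions=None, chrom="1"):
    """GenotypeDataset from a raw calls matrix (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    samples = [f"x{i}" for i in range(n)]
    if populations is None:
        populations = {s: "pop" for s in samples}
    else:
        populations = dict(zip(samples, populations))
    variants = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(m)],
            "chrom": chrom,
            "pos_bp": np.asarray(positions, dtype=np.int64),
            "allele_ref": "A",
            "allele_alt": "B",
        }
    )
    return GenotypeDataset(
        variants=variants, samples=samples, populations=populations, calls=calls
    )


@pytest.fixture(scope="session")
def two_pop_sim():
    """A small neutral two-population split, shared across tests."""
    cfg = SimConfig(
        chrom_length_bp=20_000_000,
        n_variants=800,
        populations=[
            PopulationSpec("anc", [(120, 150)]),
            PopulationSpec("A", [(60, 120)], parents=["anc"], split_generation=60),
            PopulationSpec("B", [(60, 120)], parents=["anc"], split_generation=60),
        ],
        sample_sizes={"A": 30, "B": 30},
        seed=1234,
    )
    return simulate(cfg)


@pytest.fixture
def toy_ped_map(tmp_path):
    """2 samples x 3 SNPs with one missing genotype and an unsorted MAP."""
    map_path = tmp_path / "toy.map"
    map_path.write_text(
        "1 s1 0 100\n"
        "1 s2 0 200\n"
        "1 s3 0 300\n"
    )
    ped_path = tmp_path / "toy.ped"
    ped_path.write_text(
        "FAM A 0 0 0 -9 A A A G G G\n"
        "FAM B 0 0 0 -9 A C G G 0 0\n"
    )
    pop_path = tmp_path / "toy.pops"
    pop_path.write_text("A\talpha\nB\tbeta\n")
    return ped_path, map_path, pop_path
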