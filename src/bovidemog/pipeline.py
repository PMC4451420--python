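"""Config-driven end-to-end run: QC -> diversity -> Reynolds/NJ tree ->
Ne trajectories -> pairwise XP-EHH scans -> consensus -> gene annotation.

Inputs come either from PED/MAP + phased HAPS files or from the built-in
simulator (synthetic mode).  Every stage writes TSV/Newick outputs into
the output directory and records its row counts in a JSON manifest whose
checksums make deterministic reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import ComparisonSet, consensus, link_genes, tally_biotypes
from .datatypes import GenotypeDataset, HaplotypeSet
from .diversity import diversity_table
from .distance import bootstrap_support, reynolds_matrix
from .io import (
    read_features,
    read_genotypes,
    read_haplotypes,
    read_population_table,
    write_genotypes,
    write_haplotypes,
)
from .ne import ne_trajectory
from .qc import filter_call_rate
from .simulate import SimConfig, config_from_dict, simulate
from .xpehh import flag_outliers, standardize_by_chrom, xpehh

log = logging.getLogger("bovidemog")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # synthetic mode
    sim: SimConfig | None = None
    # real-input mode
    ped: str | None = None
    map: str | None = None
    pop_table: str | None = None
    haplotype_files: list[dict[str, str]] = field(default_factory=list)
    features: str | None = None
    features_fmt: str = "bed"
    # comparison design: list of {name, m, pairs: [[pop_a, pop_b], ...]}
    comparisons: list[dict[str, Any]] = field(default_factory=list)
    # thresholds
    sample_call_rate: float = 0.95
    snp_call_rate: float = 0.95
    maf_min: float = 0.05
    max_gap_bp: int = 400_000
    q_low: float = 0.05
    q_high: float = 0.95
    n_bins: int = 30
    ld_min_bp: int = 5_000
    ld_max_bp: int = 1_000_000
    bootstrap_replicates: int = 100
    min_support: int = 3

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = config_from_dict(d["simulate"]) if "simulate" in d else None
        keys = {
            k: d[k]
            for k in (
                "out_dir", "seed", "ped", "map", "pop_table", "haplotype_files",
                "features", "features_fmt", "comparisons", "sample_call_rate",
                "snp_call_rate", "maf_min", "max_gap_bp", "q_low", "q_high",
                "n_bins", "ld_min_bp", "ld_max_bp", "bootstrap_replicates",
                "min_support",
            )
            if k in d
        }
        return cls(sim=sim, **keys)


def build_figure1_design(
    taurine: list[str],
    indicine: list[str],
    taurine_european: list[str],
    taurine_african: list[str],
    indicine_asian: list[str],
    indicine_african: list[str],
    min_support: int = 3,
) -> list[dict[str, Any]]:
    """The three replicated comparison families of the study design.

    Between-species: the i-th of four taurine breeds against the i-th of
    four indicine breeds (K=4, call at >= 3 agreeing); within-taurine:
    three European vs three African breeds (K=3, all 3 must agree);
    within-indicine: three Asian vs three African breeds (K=3).
    """
    if len(taurine) != 4 or len(indicine) != 4:
        raise ValueError("between-species design needs 4 taurine and 4 indicine breeds")
    for name, grp in (
        ("taurine_european", taurine_european),
        ("taurine_african", taurine_african),
        ("indicine_asian", indicine_asian),
        ("indicine_african", indicine_african),
    ):
        if len(grp) != 3:
            raise ValueError(f"{name}: within-species design needs 3 breeds")
    designs = []
    for name, a_grp, b_grp, m in (
        ("taurine_vs_indicine", taurine, indicine, min_support),
        ("taurine_european_vs_african", taurine_european, taurine_african, 3),
        ("indicine_asian_vs_african", indicine_asian, indicine_african, 3),
    ):
        if set(a_grp) & set(b_grp):
            raise ValueError(f"{name}: population on both sides: {set(a_grp) & set(b_grp)}")
        designs.append(
            {"name": name, "m": m, "pairs": [[a, b] for a, b in zip(a_grp, b_grp)]}
        )
    return designs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    stage = "validate"
    try:
        # design validation first: a bad config must abort before any
        # stage output is written
        if config.sim is not None:
            known = set(config.sim.sample_sizes)
        elif config.pop_table:
            known = set(read_population_table(config.pop_table).values())
        else:
            raise PipelineError("need ped/map/pop_table or a simulate block")
        for d in config.comparisons:
            for a, b in d["pairs"]:
                for p in (a, b):
                    if p not in known:
                        raise PipelineError(
                            f"comparison design references unknown population {p!r}"
                        )

        # ---------------- input / simulate ----------------
        stage = "input"
        if config.sim is not None:
            ds, hapsets, truth = simulate(config.sim)
            truth.to_tsv(str(out / "truth.tsv"))
            write_genotypes(ds, out / "simulated.ped", out / "simulated.map")
            for pop, hs_list in hapsets.items():
                for hs in hs_list:
                    write_haplotypes(hs, out / f"haps_{pop}_chr{hs.chrom}.txt")
        else:
            if not (config.ped and config.map and config.pop_table):
                raise PipelineError("need ped/map/pop_table or a simulate block")
            ds = read_genotypes(config.ped, config.map, config.pop_table)
            hapsets = {}
            for item in config.haplotype_files:
                hs = read_haplotypes(item["path"])
                hapsets.setdefault(item["population"], []).append(hs)
        pops = ds.population_names()
        manifest["stages"]["input"] = {
            "n_samples": ds.n_samples, "n_variants": ds.n_variants,
            "populations": pops,
        }

        # ---------------- QC ----------------
        stage = "qc"
        ds_qc = filter_call_rate(ds, config.sample_call_rate, config.snp_call_rate)
        manifest["stages"]["qc"] = {
            "samples_kept": ds_qc.n_samples,
            "samples_dropped": ds.n_samples - ds_qc.n_samples,
            "snps_kept": ds_qc.n_variants,
            "snps_dropped": ds.n_variants - ds_qc.n_variants,
        }
        log.info("qc: kept %d/%d samples, %d/%d SNPs", ds_qc.n_samples,
                 ds.n_samples, ds_qc.n_variants, ds.n_variants)

        # ---------------- diversity ----------------
        stage = "diversity"
        div = diversity_table(ds_qc)
        div.to_csv(out / "diversity.tsv", sep="\t", index=False, float_format="%.6f")
        manifest["stages"]["diversity"] = {"rows": len(div)}

        # ---------------- distance tree ----------------
        stage = "tree"
        if len(pops) >= 3:
            dm = reynolds_matrix(ds_qc)
            dm.to_phylip(out / "reynolds.dist")
            tree = bootstrap_support(
                ds_qc, replicates=config.bootstrap_replicates, seed=config.seed
            )
            (out / "tree.nwk").write_text(tree.to_newick() + "\n")
            manifest["stages"]["tree"] = {
                "populations": len(pops),
                "bootstrap_replicates": config.bootstrap_replicates,
            }

        # ---------------- Ne trajectories ----------------
        stage = "ne"
        ne_rows = 0
        for pop, hs_list in hapsets.items():
            try:
                traj = ne_trajectory(
                    hs_list, population=pop, n_bins=config.n_bins,
                    min_bp=config.ld_min_bp, max_bp=config.ld_max_bp,
                    maf_min=config.maf_min,
                )
            except ValueError as exc:
                log.warning("ne: skipping %s (%s)", pop, exc)
                continue
            traj.to_tsv(str(out / f"ne_{pop}.tsv"))
            ne_rows += len(traj.bins)
        manifest["stages"]["ne"] = {"bins_written": ne_rows}

        # ---------------- XP-EHH comparisons ----------------
        stage = "xpehh"
        comparison_sets: list[ComparisonSet] = []
        for d in config.comparisons:
            recs = []
            for a, b in d["pairs"]:
                per_chrom = []
                for hs_a, hs_b in zip(hapsets[a], hapsets[b]):
                    per_chrom.append(
                        xpehh(hs_a, hs_b, maf_min=config.maf_min,
                              max_gap_bp=config.max_gap_bp)
                    )
                rec = pd.concat(per_chrom, ignore_index=True)
                rec = flag_outliers(standardize_by_chrom(rec),
                                    q_low=config.q_low, q_high=config.q_high)
                rec.to_csv(out / f"xpehh_{d['name']}_{a}_vs_{b}.tsv", sep="\t",
                           index=False, float_format="%.6g")
                recs.append((a, b, rec))
            comparison_sets.append(
                ComparisonSet(name=d["name"], comparisons=recs,
                              m=int(d.get("m", config.min_support)))
            )
        manifest["stages"]["xpehh"] = {"comparison_sets": len(comparison_sets)}

        # ---------------- consensus + annotation ----------------
        stage = "consensus"
        features = (
            read_features(config.features, config.features_fmt)
            if config.features else []
        )
        total_calls = 0
        for cs in comparison_sets:
            calls = consensus(cs)
            calls.to_csv(out / f"consensus_{cs.name}.tsv", sep="\t", index=False)
            total_calls += len(calls)
            if features:
                links = link_genes(calls, features)
                links.to_csv(out / f"links_{cs.name}.tsv", sep="\t", index=False)
                tally_biotypes(links).to_csv(
                    out / f"biotypes_{cs.name}.tsv", sep="\t", index=False
                )
        manifest["stages"]["consensus"] = {"calls": total_calls}

    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
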