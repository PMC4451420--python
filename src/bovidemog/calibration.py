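"""Synthetic calibration experiments for the pipeline's statistics.

Each experiment simulates data under known truth with the forward
Wright–Fisher generator and measures how well an estimator recovers it:
sweep detection power of the XP-EHH scan, the false-call rate of the
replicated consensus rule on sweep-free data, Sved-estimator recovery of a
constant effective size, the rank trend under a declining size, and
NJ/bootstrap recovery of a known population tree.  The experiment designs
(sizes, depths, selection strength) are frozen here so that tests and
reproduction scripts measure the same conditions.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from .consensus import ComparisonSet, analytic_null_consensus_rate, consensus
from .distance import bipartitions, bootstrap_support
from .ne import ne_trajectory
from .simulate import PopulationSpec, SimConfig, SweepSpec, simulate
from .xpehh import flag_outliers, standardize_by_chrom, xpehh

P = PopulationSpec


def sweep_power_experiment(
    n_replicates: int = 50, seed: int = 0
) -> dict[str, Any]:
    """Power of the XP-EHH scan against a hard sweep caught mid-flight.

    Two populations of Ne = 500 split 100 generations ago; a hard additive
    sweep (s = 0.1, 2Ns = 100) starts 55 generations ago in population A
    from a rare standing variant (frequency 0.01, ~10 copies, so the
    favored class descends from few haplotype backgrounds) and the run is
    conditioned on the allele reaching frequency 0.5 — the partial-sweep
    regime where cross-population haplotype tests have power while the
    focal region is still polymorphic.  2000 SNPs on 60 Mb (~30 kb
    spacing, medium-density array scale), 50 diploids sampled per side.
    A replicate detects the sweep when a tested SNP within 100 kb of the
    focal site is flagged as a high-tail outlier.
    """
    hits = 0
    peak_dists = []
    for r in range(n_replicates):
        L = 60_000_000
        cfg = SimConfig(
            chrom_length_bp=L,
            n_variants=2000,
            populations=[
                P("anc", [(110, 500)]),
                P("A", [(100, 500)], parents=["anc"], split_generation=100),
                P("B", [(100, 500)], parents=["anc"], split_generation=100),
            ],
            sweeps=[SweepSpec("1", L // 2, 0.1, 55, ["A"], initial_freq=0.01)],
            sample_sizes={"A": 50, "B": 50},
            seed=(seed * 7919 + r) % (2**31 - 1),
            resample_until_established=True,
            established_freq=0.5,
        )
        _, haps, truth = simulate(cfg)
        rec = flag_outliers(standardize_by_chrom(xpehh(haps["A"][0], haps["B"][0])))
        fpos = int(truth.sweep_trajectories["pos_bp"].iloc[0])
        tested = rec[rec["tested"]]
        near = tested[(tested["pos_bp"] - fpos).abs() <= 100_000]
        if len(near) and (near["outlier"] == "high").any():
            hits += 1
        if len(tested):
            peak = tested.loc[tested["z"].idxmax()]
            peak_dists.append(abs(int(peak["pos_bp"]) - fpos))
    return {
        "detection_rate": hits / n_replicates,
        "n_replicates": n_replicates,
        "median_peak_distance_bp": float(np.median(peak_dists)),
    }


def neutral_consensus_experiment(
    n_replicates: int = 5, seed: int = 0
) -> dict[str, Any]:
    """Sweep-free calibration of the K=3, m=3 consensus rule.

    Six populations (Ne = 150) split from one ancestor (Ne = 200) 60
    generations ago; three disjoint pairwise XP-EHH comparisons per
    replicate.  Reports the flagged fraction (10 % by quantile
    construction), the consensus-call rate over SNPs tested in all three
    comparisons, and the analytic independent-flag null 2q^3*...
    """
    total_calls = 0
    total_eligible = 0
    flagged_fracs = []
    for r in range(n_replicates):
        pops = [P("anc", [(100, 200)])] + [
            P(f"P{i}", [(60, 150)], parents=["anc"], split_generation=60)
            for i in range(6)
        ]
        cfg = SimConfig(
            chrom_length_bp=60_000_000,
            n_variants=3000,
            populations=pops,
            sample_sizes={f"P{i}": 40 for i in range(6)},
            seed=(seed * 104729 + r) % (2**31 - 1),
        )
        _, haps, _ = simulate(cfg)
        recs = []
        for a, b in ((0, 3), (1, 4), (2, 5)):
            rec = flag_outliers(
                standardize_by_chrom(xpehh(haps[f"P{a}"][0], haps[f"P{b}"][0]))
            )
            recs.append((f"P{a}", f"P{b}", rec))
            n_tested = int(rec["tested"].sum())
            flagged_fracs.append(
                float((rec["outlier"] != "none").sum()) / n_tested
            )
        tested = np.stack([r_["tested"].to_numpy() for _, _, r_ in recs])
        total_eligible += int((tested.sum(axis=0) >= 3).sum())
        total_calls += len(consensus(ComparisonSet("neutral", recs, m=3)))
    analytic = analytic_null_consensus_rate(3, 3, 0.05)
    rate = total_calls / total_eligible
    se_null = float(np.sqrt(analytic * (1 - analytic) / total_eligible))
    return {
        "flagged_fraction": float(np.mean(flagged_fracs)),
        "consensus_calls": total_calls,
        "eligible_snps": total_eligible,
        "consensus_rate": rate,
        "analytic_null_rate": analytic,
        "null_se": se_null,
    }


def constant_ne_experiment(seed: int = 0) -> dict[str, Any]:
    """Sved-estimator recovery of a constant Ne = 200.

    One population run for 500 generations (~2.5 Ne, enough for LD at the
    5 kb-1 Mb distances to approach drift-recombination balance) over two
    independently simulated 25 Mb chromosomes of 1000 SNPs each; 50
    diploids sampled.
    """
    cfg = SimConfig(
        chrom_length_bp=25_000_000,
        n_variants=1000,
        n_chromosomes=2,
        populations=[P("pop", [(500, 200)])],
        sample_sizes={"pop": 50},
        seed=seed % (2**31 - 1),
    )
    _, haps, _ = simulate(cfg)
    traj = ne_trajectory(haps["pop"], population="pop")
    return {
        "true_ne": 200,
        "median_bin_ne": float(traj.bins["ne"].median()),
        "harmonic_mean_ne": traj.harmonic_mean_ne,
        "n_pairs": int(traj.bins["n_pairs"].sum()),
        "most_recent_t": float(traj.bins["t_generations"].iloc[0]),
    }


def declining_ne_experiment(seed: int = 0) -> dict[str, Any]:
    """Rank trend under a decline from Ne 1000 to 100 over 500 generations:
    recent bins must estimate a smaller Ne than ancient bins."""
    schedule = [
        (600, 1000), (500, 800), (400, 600), (300, 400),
        (200, 250), (100, 150), (50, 100),
    ]
    cfg = SimConfig(
        chrom_length_bp=50_000_000,
        n_variants=2000,
        populations=[P("pop", schedule)],
        sample_sizes={"pop": 50},
        seed=seed % (2**31 - 1),
    )
    _, haps, _ = simulate(cfg)
    bins = ne_trajectory(haps["pop"], population="pop").bins
    return {
        "recent_mean_ne": float(bins.head(8)["ne"].mean()),
        "ancient_mean_ne": float(bins.tail(8)["ne"].mean()),
    }


def tree_recovery_experiment(
    seed: int = 0, replicates: int = 100
) -> dict[str, Any]:
    """NJ on Reynolds distances against a known ((A,B),(C,D),O) history.

    All splits are at least 50 generations deep at Ne = 100: outgroup O at
    180, the two inner clades at 150, and the terminal splits at 80
    generations before present.
    """
    cfg = SimConfig(
        chrom_length_bp=25_000_000,
        n_variants=1500,
        populations=[
            P("anc", [(200, 100)]),
            P("O", [(180, 100)], parents=["anc"], split_generation=180),
            P("L", [(150, 100)], parents=["anc"], split_generation=150),
            P("R", [(150, 100)], parents=["anc"], split_generation=150),
            P("A", [(80, 100)], parents=["L"], split_generation=80),
            P("B", [(80, 100)], parents=["L"], split_generation=80),
            P("C", [(80, 100)], parents=["R"], split_generation=80),
            P("D", [(80, 100)], parents=["R"], split_generation=80),
        ],
        sample_sizes={p: 30 for p in ("A", "B", "C", "D", "O")},
        seed=seed % (2**31 - 1),
    )
    ds, _, _ = simulate(cfg)
    tree = bootstrap_support(ds, replicates=replicates, seed=(seed + 1) % (2**31 - 1))
    true_bips = {frozenset({"A", "B"}), frozenset({"C", "D"})}
    got = bipartitions(tree)
    supports = []

    def walk(node):
        if node.support is not None:
            supports.append(node.support)
        for child, _ in node.children:
            walk(child)

    walk(tree)
    return {
        "topology_recovered": got == true_bips,
        "min_support": float(min(supports)) if supports else 0.0,
        "newick": tree.to_newick(),
    }
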