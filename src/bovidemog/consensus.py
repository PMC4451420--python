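"""Replicated-comparison consensus calls and gene annotation.

Several pairwise XP-EHH scans between members of two groups act as
biological replicates: a SNP is called under selection when it is an
outlier with the same sign in at least ``m`` of the K comparisons (and,
under the default conservative rule, an opposite-sign outlier in none).
Called SNPs are linked to genes within a +/-50 kb window and tallied by
molecule-class biotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .datatypes import BIOTYPES, GeneFeature


@dataclass
class ComparisonSet:
    """A named family of pairwise comparisons sharing one variant map.

    ``comparisons`` holds (pop_a, pop_b, records) triples where records is
    a flagged XP-EHH table; pop_a is always the same side of the design
    (e.g. taurine), so a "high" flag means selection on the A side.
    """

    name: str
    comparisons: list[tuple[str, str, pd.DataFrame]]
    m: int = 3
    require_all_tested: bool = False

    def __post_init__(self) -> None:
        if self.m > len(self.comparisons):
            raise ValueError(
                f"{self.name}: min support m={self.m} exceeds "
                f"{len(self.comparisons)} comparisons"
            )
        first = self.comparisons[0][2]["variant_id"].to_numpy()
        for _, _, rec in self.comparisons[1:]:
            if not (rec["variant_id"].to_numpy() == first).all():
                raise ValueError(f"{self.name}: comparisons must share the variant map")


def consensus(cs: ComparisonSet, allow_conflict: bool = False) -> pd.DataFrame:
    """Cross-comparison consensus calls.

    A SNP is called when it is tested in >= m comparisons and flagged with
    the same sign in >= m of them; with the default conservative rule any
    opposite-sign flag vetoes the call (``allow_conflict`` disables the
    veto).  Returns variant_id, chrom, pos_bp, direction (pop_a_side /
    pop_b_side), support, n_tested, conflicting.
    """
    base = cs.comparisons[0][2]
    k = len(cs.comparisons)
    tested = np.stack([rec["tested"].to_numpy() for _, _, rec in cs.comparisons])
    high = np.stack(
        [(rec["outlier"].to_numpy() == "high") for _, _, rec in cs.comparisons]
    )
    low = np.stack(
        [(rec["outlier"].to_numpy() == "low") for _, _, rec in cs.comparisons]
    )
    n_tested = tested.sum(axis=0)
    n_high = high.sum(axis=0)
    n_low = low.sum(axis=0)

    enough_tested = n_tested == k if cs.require_all_tested else n_tested >= cs.m
    call_a = enough_tested & (n_high >= cs.m)
    call_b = enough_tested & (n_low >= cs.m)
    conflicting = (n_high > 0) & (n_low > 0)
    if not allow_conflict:
        call_a &= ~conflicting
        call_b &= ~conflicting

    rows = []
    for v in np.flatnonzero(call_a | call_b):
        a_side = bool(call_a[v])
        rows.append(
            {
                "variant_id": base["variant_id"].iloc[v],
                "chrom": base["chrom"].iloc[v],
                "pos_bp": int(base["pos_bp"].iloc[v]),
                "direction": "pop_a_side" if a_side else "pop_b_side",
                "support": int(n_high[v] if a_side else n_low[v]),
                "n_tested": int(n_tested[v]),
                "conflicting": bool(conflicting[v]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos_bp", "direction",
            "support", "n_tested", "conflicting",
        ],
    )


def null_consensus_rate(
    K: int,
    m: int,
    q: float = 0.05,
    replicates: int = 200_000,
    seed: int = 0,
    no_conflict: bool = True,
) -> float:
    """Monte-Carlo per-SNP probability of a consensus call when outlier
    flags are independent across comparisons with per-tail probability q.

    The closed form without conflicts for K = m is 2 q^m; with the
    no-conflict rule at K > m it is
    2 * sum_{j=m..K} C(K,j) q^j (1 - 2q)^(K-j).
    """
    if not 0 <= q < 0.5:
        raise ValueError("q must be in [0, 0.5)")
    if m > K:
        raise ValueError("m must be <= K")
    rng = np.random.default_rng(seed)
    u = rng.random((replicates, K))
    high = u < q
    low = u >= 1.0 - q
    n_high = high.sum(axis=1)
    n_low = low.sum(axis=1)
    call = (n_high >= m) | (n_low >= m)
    if no_conflict:
        call &= ~((n_high > 0) & (n_low > 0))
    return float(call.mean())


def analytic_null_consensus_rate(K: int, m: int, q: float, no_conflict: bool = True) -> float:
    """Closed-form counterpart of ``null_consensus_rate`` (binomial sum)."""
    if no_conflict:
        return 2.0 * sum(
            comb(K, j) * q**j * (1.0 - 2.0 * q) ** (K - j) for j in range(m, K + 1)
        )
    total = 0.0
    # sum over (n_high, n_low) configurations with either count >= m
    for h in range(K + 1):
        for l in range(K + 1 - h):
            if h < m and l < m:
                continue
            total += (
                comb(K, h) * comb(K - h, l)
                * q**h * q**l * (1.0 - 2.0 * q) ** (K - h - l)
            )
    return total


def link_genes(
    calls: pd.DataFrame,
    features: list[GeneFeature],
    window_bp: int = 50_000,
) -> pd.DataFrame:
    """Link each consensus SNP to every gene whose interval intersects
    [pos − window, pos + window]; distance 0 inside the gene, else the bp
    gap to the nearer gene edge.  Columns: variant_id, direction, gene_id,
    biotype, distance_bp.
    """
    by_chrom: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_chrom.setdefault(str(f.chrom), []).append(f)
    rows = []
    for call in calls.itertuples(index=False):
        pos = int(call.pos_bp)
        for f in by_chrom.get(str(call.chrom), []):
            if f.start_bp > pos + window_bp or f.end_bp < pos - window_bp:
                continue
            if f.start_bp <= pos <= f.end_bp:
                dist = 0
            else:
                dist = min(abs(pos - f.start_bp), abs(pos - f.end_bp))
            rows.append(
                {
                    "variant_id": call.variant_id,
                    "direction": call.direction,
                    "gene_id": f.id,
                    "biotype": f.biotype,
                    "distance_bp": dist,
                }
            )
    return pd.DataFrame(
        rows, columns=["variant_id", "direction", "gene_id", "biotype", "distance_bp"]
    )


def tally_biotypes(links: pd.DataFrame) -> pd.DataFrame:
    """Distinct genes per biotype, split by call direction.

    A gene linked by several SNPs counts once per direction (the tallies
    count molecules, not links).
    """
    order = ["protein_coding", "miRNA", "snoRNA", "snRNA", "rRNA", "pseudogene", "other"]
    directions = ["pop_a_side", "pop_b_side"]
    counts = {d: dict.fromkeys(order, 0) for d in directions}
    if len(links):
        uniq = links.drop_duplicates(subset=["direction", "gene_id"])
        for row in uniq.itertuples(index=False):
            if row.direction in counts and row.biotype in counts[row.direction]:
                counts[row.direction][row.biotype] += 1
    return pd.DataFrame(
        {"biotype": order, **{d: [counts[d][b] for b in order] for d in directions}}
    )
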