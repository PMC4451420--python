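"""Reynolds' genetic distance, neighbor-joining, and bootstrap support.

Reynolds, Weir & Cockerham's least-squares coancestry distance is suited to
short, drift-dominated divergence (breed formation); the dendrogram is
built with Saitou–Nei neighbor joining and assessed by resampling variants
with replacement.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset


# ---------------------------------------------------------------------------
# allele frequencies and Reynolds distance
# ---------------------------------------------------------------------------

def population_allele_freqs(ds: GenotypeDataset) -> pd.DataFrame:
    """Alternate-allele frequency per population (rows) per variant (cols),
    over non-missing calls; NaN where a population has no call."""
    rows = {}
    for pop in ds.population_names():
        calls = ds.calls[ds.sample_indices(pop)]
        called = calls != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[pop] = np.where(n > 0, alt / (2.0 * n), np.nan)
    return pd.DataFrame(rows).T


def reynolds_distance(freqs_a: np.ndarray, freqs_b: np.ndarray) -> float:
    """Reynolds' coancestry distance over biallelic variants.

    theta = sum_v sum_alleles (p - q)^2 / (2 sum_v (1 - sum_alleles p*q));
    for alternate frequencies p, q this is sum 2(p-q)^2 over
    sum 2(1 - pq - (1-p)(1-q)).  Loci fixed identically in both
    populations contribute zero to both sums; if every locus is such,
    the distance is undefined (NaN).  NaN frequencies are dropped pairwise.
    """
    p = np.asarray(freqs_a, dtype=float)
    q = np.asarray(freqs_b, dtype=float)
    if p.shape != q.shape:
        raise ValueError("frequency vectors must share the variant list")
    ok = ~(np.isnan(p) | np.isnan(q))
    p, q = p[ok], q[ok]
    num = (2.0 * (p - q) ** 2).sum()
    den = (2.0 * (1.0 - p * q - (1.0 - p) * (1.0 - q))).sum()
    if den == 0:
        return float("nan")
    return float(num / den)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    def to_phylip(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab.ljust(12) + " ".join(f"{x:.6f}" for x in row) + "\n")


def reynolds_matrix(ds: GenotypeDataset) -> DistanceMatrix:
    freqs = population_allele_freqs(ds)
    return _matrix_from_freqs(freqs)


def _matrix_from_freqs(freqs: pd.DataFrame) -> DistanceMatrix:
    labels = list(freqs.index)
    n = len(labels)
    vals = np.zeros((n, n))
    arr = freqs.to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            d = reynolds_distance(arr[i], arr[j])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels=labels, values=vals)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A rooted view of the (unrooted) NJ tree: children carry branch lengths."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.label] if self.label else []
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self, with_support: bool = True) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf():
            return self.label or ""
        inner = ",".join(
            f"{c._newick(with_support)}:{bl:.6f}" for c, bl in self.children
        )
        sup = ""
        if with_support and self.support is not None:
            sup = f"{self.support:.2f}"
        return f"({inner}){sup}"


def nj_tree(d: DistanceMatrix, allow_negative: bool = False) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    The Q-criterion pair with the smallest (row, column) index is joined on
    ties; the unrooted result is returned rooted at the final join, the
    last edge split evenly between the two remaining nodes.  Negative
    branch lengths are clamped to 0 unless ``allow_negative``.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    D = d.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in d.labels]

    def clamp(x: float) -> float:
        return x if allow_negative else max(x, 0.0)

    while len(nodes) > 2:
        k = len(nodes)
        r = D.sum(axis=1)
        best: tuple[float, int, int] | None = None
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best  # type: ignore[misc]
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = D[i, j] - li
        new = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        dnew = np.array(
            [(D[i, m] + D[j, m] - D[i, j]) / 2.0 for m in range(k) if m not in (i, j)]
        )
        keep = [m for m in range(k) if m not in (i, j)]
        D = D[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = dnew
        D[:-1, -1] = dnew
        nodes = [nodes[m] for m in keep] + [new]

    a, b = nodes
    half = D[0, 1] / 2.0
    return TreeNode(children=[(a, clamp(half)), (b, clamp(half))])


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical frozensets of the smaller side
    (ties broken lexically), ignoring branch lengths and rooting."""
    all_leaves = frozenset(tree.leaves())
    out: set[frozenset[str]] = set()

    def canon(side: frozenset[str]) -> frozenset[str]:
        other = all_leaves - side
        if len(side) < len(other):
            return side
        if len(other) < len(side):
            return other
        return min(side, other, key=lambda s: tuple(sorted(s)))

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.label])
        below = frozenset()
        for child, _ in node.children:
            sub = walk(child)
            if 1 < len(sub) < len(all_leaves) - 1:
                out.add(canon(sub))
            below |= sub
        return below

    walk(tree)
    return out


def bootstrap_support(
    ds: GenotypeDataset,
    replicates: int = 100,
    seed: int = 0,
    allow_negative: bool = False,
) -> TreeNode:
    """NJ tree on Reynolds distances with bootstrap (resample variants with
    replacement) support on internal nodes; deterministic given the seed."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    freqs = population_allele_freqs(ds)
    tree = nj_tree(_matrix_from_freqs(freqs), allow_negative=allow_negative)
    all_leaves = frozenset(tree.leaves())

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(tree)}
    m = freqs.shape[1]
    for _ in range(replicates):
        idx = rng.integers(0, m, m)
        rep_freqs = freqs.iloc[:, idx]
        rep_tree = nj_tree(_matrix_from_freqs(rep_freqs), allow_negative=allow_negative)
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1

    def canon(side: frozenset[str]) -> frozenset[str]:
        other = all_leaves - side
        if len(side) < len(other):
            return side
        if len(other) < len(side):
            return other
        return min(side, other, key=lambda s: tuple(sorted(s)))

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.label])
        below = frozenset()
        for child, _ in node.children:
            below |= annotate(child)
        key = canon(below)
        if 1 < len(below) < len(all_leaves) - 1 and key in counts:
            node.support = counts[key] / replicates
        return below

    annotate(tree)
    return tree
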