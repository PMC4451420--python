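"""Reynolds distance, neighbor joining (vs closed forms and dendropy),
and bootstrap support."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bovidemog.distance import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    nj_tree,
    reynolds_distance,
    reynolds_matrix,
)

from conftest import make_dataset


class TestReynoldsDistance:
    def test_identical_is_zero(self):
        f = np.array([0.1, 0.5, 0.9])
        assert reynolds_distance(f, f) == 0.0

    def test_reciprocal_fixation(self):
        assert reynolds_distance([1.0], [0.0]) == 1.0

    def test_hand_evaluation(self):
        assert reynolds_distance([0.75], [0.25]) == pytest.approx(0.4)

    def test_identically_fixed_loci_undefined(self):
        assert np.isnan(reynolds_distance([1.0, 0.0], [1.0, 0.0]))

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20),
        st.data(),
    )
    def test_symmetry_and_nonnegativity(self, p, data):
        q = data.draw(
            st.lists(st.floats(0.0, 1.0), min_size=len(p), max_size=len(p))
        )
        p, q = np.array(p), np.array(q)
        d_pq = reynolds_distance(p, q)
        d_qp = reynolds_distance(q, p)
        if not np.isnan(d_pq):
            assert d_pq == pytest.approx(d_qp)
            assert d_pq >= 0.0


def _path_lengths(tree):
    """Leaf-to-leaf path length matrix of a TreeNode, via accumulation at
    the lowest common ancestor."""
    labels = sorted(tree.leaves())
    n = len(labels)
    mat = {l: {} for l in labels}

    def pairs(node):
        if node.is_leaf():
            return {node.label: 0.0}
        sub = []
        for child, bl in node.children:
            d = pairs(child)
            sub.append({k: v + bl for k, v in d.items()})
        merged = {}
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                for a, da in sub[i].items():
                    for b, db in sub[j].items():
                        mat[a][b] = mat[b][a] = da + db
            merged.update(sub[i])
        return merged

    pairs(tree)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                out[i, j] = mat[a][b]
    return labels, out


class TestNjTree:
    def test_three_taxa_three_point_formulas(self):
        # leaf edges a=1, b=2, c=4
        d = DistanceMatrix(["A", "B", "C"], np.array(
            [[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float
        ))
        tree = nj_tree(d)
        labels, paths = _path_lengths(tree)
        np.testing.assert_allclose(paths, d.values, atol=1e-9)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
        labels = ["A", "B", "C", "D"]
        d = DistanceMatrix(labels, np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            dtype=float,
        ))
        tree = nj_tree(d)
        assert bipartitions(tree) == {frozenset({"A", "B"})}
        got_labels, paths = _path_lengths(tree)
        assert got_labels == labels
        np.testing.assert_allclose(paths, d.values, atol=1e-9)
        # brute-force least-squares over the three unrooted topologies
        assert _best_topology_oracle(d.values) == frozenset({"A", "B"})

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.random((6, 3))
        vals = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"L{i}" for i in range(6)]
        t1 = nj_tree(DistanceMatrix(labels, vals))
        perm = [3, 0, 5, 1, 4, 2]
        t2 = nj_tree(
            DistanceMatrix([labels[i] for i in perm], vals[np.ix_(perm, perm)])
        )
        assert bipartitions(t1) == bipartitions(t2)

    def test_matches_dendropy_on_random_metric(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(3)
        pts = rng.random((7, 4))
        vals = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"T{i}" for i in range(7)]
        ours = bipartitions(nj_tree(DistanceMatrix(labels, vals)))

        csv = "," + ",".join(labels) + "\n"
        for i, lab in enumerate(labels):
            csv += lab + "," + ",".join(f"{x:.10f}" for x in vals[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        theirs = set()
        all_taxa = frozenset(labels)
        for edge in dtree.preorder_edge_iter():
            if edge.head_node.is_leaf() or edge.head_node.parent_node is None:
                continue
            side = frozenset(
                lf.taxon.label for lf in edge.head_node.leaf_iter()
            )
            if 1 < len(side) < len(labels) - 1:
                other = all_taxa - side
                canon = side if len(side) < len(other) else (
                    other if len(other) < len(side)
                    else min(side, other, key=lambda s: tuple(sorted(s)))
                )
                theirs.add(canon)
        assert ours == theirs

    def test_too_few_labels(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_negative_branch_clamping(self):
        d = DistanceMatrix(["A", "B", "C", "D"], np.array(
            [
                [0.0, 1.0, 1.0, 1.0],
                [1.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.1],
                [1.0, 1.0, 0.1, 0.0],
            ]
        ))
        def min_bl(node):
            out = []
            for c, bl in node.children:
                out.append(bl)
                out.extend(min_bl(c))
            return out
        assert min(min_bl(nj_tree(d))) >= 0.0
        assert min(min_bl(nj_tree(d, allow_negative=True))) <= min(
            min_bl(nj_tree(d))
        )


def _best_topology_oracle(D):
    """Least-squares fit of the three 4-taxon topologies; returns the cherry
    containing taxon A of the best fit."""
    import itertools

    best = None
    for pair in (("A", "B"), ("A", "C"), ("A", "D")):
        order = ["A", "B", "C", "D"]
        idx = {l: i for i, l in enumerate(order)}
        a, b = pair
        c, d = [x for x in order if x not in pair]
        # unknowns: 4 leaf edges + internal edge; rows = 6 pairs
        rows, y = [], []
        for u, v in itertools.combinations(order, 2):
            coef = np.zeros(5)
            coef[idx[u]] = coef[idx[v]] = 1.0
            same_cherry = {u, v} in ({a, b}, {c, d})
            if not same_cherry:
                coef[4] = 1.0
            rows.append(coef)
            y.append(D[idx[u], idx[v]])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        rss = ((np.array(rows) @ sol - y) ** 2).sum()
        if best is None or rss < best[0]:
            best = (rss, frozenset(pair))
    return best[1]


class TestBootstrap:
    def test_single_replicate_supports_binary(self, two_pop_sim):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, (40, 120)).astype(np.int8)
        pops = ["p1"] * 10 + ["p2"] * 10 + ["p3"] * 10 + ["p4"] * 10
        ds = make_dataset(calls, populations=pops)
        tree = bootstrap_support(ds, replicates=1, seed=0)
        sups = []
        def walk(n):
            if n.support is not None:
                sups.append(n.support)
            for c, _ in n.children:
                walk(c)
        walk(tree)
        assert sups and all(s in (0.0, 1.0) for s in sups)

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, (40, 120)).astype(np.int8)
        pops = ["p1"] * 10 + ["p2"] * 10 + ["p3"] * 10 + ["p4"] * 10
        ds = make_dataset(calls, populations=pops)
        t1 = bootstrap_support(ds, replicates=25, seed=42)
        t2 = bootstrap_support(ds, replicates=25, seed=42)
        assert t1.to_newick() == t2.to_newick()

    def test_reynolds_matrix_structure(self, two_pop_sim):
        ds, _, _ = two_pop_sim
        dm = reynolds_matrix(ds)
        assert dm.labels == ["A", "B"]
        assert dm.values[0, 0] == 0.0
        assert dm.values[0, 1] == dm.values[1, 0] > 0.0
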