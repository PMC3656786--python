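import itertools

import numpy as np
import pytest

from ssrpopkit import phylogeny as ph
from ssrpopkit.genotypes import GenotypeMatrix


# ---------------------------------------------------------------------------
# oracles


def all_unrooted_topologies(n):
    """All unrooted binary tree topologies on leaves 0..n-1 as edge lists."""
    trees = [[(0, n), (1, n), (2, n)]]  # star on 3 leaves, internal node n
    next_internal = n + 1
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                w = next_internal + (leaf - 3) * 0  # fresh id per insertion
                w = max(max(e) for e in edges) + 1
                new = edges[:k] + edges[k + 1:] + [(u, w), (w, v), (w, leaf)]
                new_trees.append(new)
        trees = new_trees
    return trees


def leaf_paths(edges, n):
    """Edge-index path between every leaf pair (BFS)."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    paths = {}
    for a in range(n):
        # BFS from a
        prev = {a: None}
        queue = [a]
        while queue:
            x = queue.pop(0)
            for y, idx in adj[x]:
                if y not in prev:
                    prev[y] = (x, idx)
                    queue.append(y)
        for b in range(a + 1, n):
            path = []
            node = b
            while prev[node] is not None:
                x, idx = prev[node]
                path.append(idx)
                node = x
            paths[(a, b)] = path
    return paths


def topology_bipartitions(edges, n, labels):
    """Nontrivial splits of a topology, canonicalized like Tree.bipartitions."""
    all_set = frozenset(labels)
    ref = min(labels)
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    splits = set()
    for u, v in edges:
        # leaves on v's side when edge removed
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if x < n:
                side.add(labels[x])
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        s = frozenset(side)
        s = s if ref not in s else all_set - s
        if 2 <= len(s) <= n - 2:
            splits.add(s)
    return splits


def best_topology_by_least_squares(dm: np.ndarray, labels):
    """Fit branch lengths of every topology by OLS; return the bipartition
    set of the minimum-RSS topology."""
    n = len(labels)
    best = None
    for edges in all_unrooted_topologies(n):
        paths = leaf_paths(edges, n)
        a = np.zeros((len(paths), len(edges)))
        y = np.zeros(len(paths))
        for r, ((i, j), path) in enumerate(paths.items()):
            a[r, path] = 1.0
            y[r] = dm[i, j]
        bl, res, *_ = np.linalg.lstsq(a, y, rcond=None)
        rss = float(((a @ bl - y) ** 2).sum())
        if best is None or rss < best[0] - 1e-12:
            best = (rss, topology_bipartitions(edges, n, labels))
    return best[1]


def random_additive_matrix(rng, labels):
    """Distances generated from a random binary tree with positive lengths."""
    n = len(labels)
    topo = all_unrooted_topologies(n)
    edges = topo[rng.integers(0, len(topo))]
    lengths = rng.uniform(0.5, 2.0, size=len(edges))
    paths = leaf_paths(edges, n)
    dm = np.zeros((n, n))
    for (i, j), path in paths.items():
        dm[i, j] = dm[j, i] = lengths[path].sum()
    return dm, topology_bipartitions(edges, n, labels)


# ---------------------------------------------------------------------------
# Nei minimum distance


class TestNeiMinimumDistance:
    def test_identical_genotypes_zero(self):
        calls = np.array([[[1, 2]], [[1, 2]]], dtype=np.int32)
        gm = GenotypeMatrix(["a", "b"], ["L1"], calls)
        assert ph.nei_minimum_distance(gm, "a", "b") == pytest.approx(0.0)

    def test_fixed_different_alleles(self):
        calls = np.array([[[1, 1]], [[2, 2]]], dtype=np.int32)
        gm = GenotypeMatrix(["a", "b"], ["L1"], calls)
        assert ph.nei_minimum_distance(gm, "a", "b") == pytest.approx(1.0)

    def test_het_vs_hom_sharing(self):
        calls = np.array([[[1, 2]], [[1, 1]]], dtype=np.int32)
        gm = GenotypeMatrix(["a", "b"], ["L1"], calls)
        assert ph.nei_minimum_distance(gm, "a", "b") == pytest.approx(0.25)

    def test_distance_axioms(self, flax_dataset):
        gm, _, _, _ = flax_dataset
        dm = ph.nei_minimum_distance_matrix(gm.subset(individuals=gm.individuals[:15]))
        v = dm.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0.0)
        assert v.min() >= 0.0


# ---------------------------------------------------------------------------
# neighbor joining


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = ph.DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        tree = ph.neighbor_joining(dm)
        lengths = {child.label: bl for child, bl in tree.root.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxon_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        labels = ["a", "b", "c", "d"]
        d = {("a", "b"): 3, ("a", "c"): 5, ("a", "d"): 6, ("b", "c"): 6, ("b", "d"): 7, ("c", "d"): 7}
        m = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            m[i, j] = m[j, i] = v
        tree = ph.neighbor_joining(ph.DistanceMatrix(labels, m))
        assert frozenset(["c", "d"]) in tree.bipartitions()
        # total length = 1+2+1+3+4
        total = []

        def walk(node):
            for c, bl in node.children:
                total.append(bl)
                walk(c)

        walk(tree.root)
        assert sum(total) == pytest.approx(11.0)
        assert tree.clamped_deficit == 0.0

    @pytest.mark.parametrize("n,seed", [(5, 0), (5, 1), (6, 2), (6, 3)])
    def test_additive_recovery_vs_all_topology_least_squares(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{k}" for k in range(n)]
        dm, true_bps = random_additive_matrix(rng, labels)
        tree = ph.neighbor_joining(ph.DistanceMatrix(labels, dm))
        oracle_bps = best_topology_by_least_squares(dm, labels)
        assert tree.bipartitions() == oracle_bps == true_bps

    @pytest.mark.parametrize("n,seed", [(7, 4), (8, 5)])
    def test_additive_recovery_generating_tree(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{k}" for k in range(n)]
        dm, true_bps = random_additive_matrix(rng, labels)
        tree = ph.neighbor_joining(ph.DistanceMatrix(labels, dm))
        assert tree.bipartitions() == true_bps

    def test_ultrametric_matches_single_linkage_nesting(self):
        # nested clusters ((a,b),(c,d)),e with increasing heights
        labels = list("abcde")
        m = np.array([
            [0, 1, 4, 4, 8],
            [1, 0, 4, 4, 8],
            [4, 4, 0, 2, 8],
            [4, 4, 2, 0, 8],
            [8, 8, 8, 8, 0],
        ], dtype=float)
        tree = ph.neighbor_joining(ph.DistanceMatrix(labels, m))
        # splits ab|cde and cd|abe (canonical side excludes leaf 'a')
        assert frozenset("cde") in tree.bipartitions()
        assert frozenset("cd") in tree.bipartitions()

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            ph.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))

    def test_matches_scikit_bio_on_random_distances(self):
        """Independent cross-check of NJ topology against scikit-bio."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(9)
        n = 7
        pts = rng.normal(size=(n, 3))
        m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"t{k}" for k in range(n)]
        tree = ph.neighbor_joining(ph.DistanceMatrix(labels, m))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(m, labels))
        sk_bps = set()
        all_set = frozenset(labels)
        ref = min(labels)
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            side = side if ref not in side else all_set - side
            if 2 <= len(side) <= n - 2:
                sk_bps.add(side)
        assert tree.bipartitions() == sk_bps


# ---------------------------------------------------------------------------
# bootstrap


class TestBootstrap:
    def test_identical_loci_full_support(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 6, size=(6, 1, 2)).astype(np.int32)
        calls = np.repeat(col, 5, axis=1)
        gm = GenotypeMatrix([f"i{k}" for k in range(6)], [f"L{j}" for j in range(5)],
                            np.sort(calls, axis=2))
        tree = ph.bootstrap_support(gm, n_reps=30, seed=3)

        def supports(node, out):
            for c, _ in node.children:
                if c.support is not None:
                    out.append(c.support)
                supports(c, out)
            return out

        vals = supports(tree.root, [])
        assert vals and all(v == 100.0 for v in vals)

    def test_two_fixed_clans_separating_edge(self):
        calls = np.zeros((6, 8, 2), dtype=np.int32)
        calls[:3] = 100
        calls[3:] = 200
        gm = GenotypeMatrix([f"i{k}" for k in range(6)], [f"L{j}" for j in range(8)], calls)
        tree = ph.bootstrap_support(gm, n_reps=50, seed=0)
        clan = frozenset(["i3", "i4", "i5"])
        found = []

        def walk(node):
            for c, _ in node.children:
                leaves = c.leaves()
                side = leaves if "i0" not in leaves else tree.leaves() - leaves
                if side == clan and c.support is not None:
                    found.append(c.support)
                walk(c)

        walk(tree.root)
        assert found and found[0] == 100.0

    def test_seed_determinism(self, flax_dataset):
        gm, _, _, _ = flax_dataset
        sub = gm.subset(individuals=gm.individuals[:10])
        t1 = ph.bootstrap_support(sub, n_reps=25, seed=7)
        t2 = ph.bootstrap_support(sub, n_reps=25, seed=7)
        assert t1.to_newick(with_support=True) == t2.to_newick(with_support=True)

    def test_newick_is_parseable(self, flax_dataset):
        dendropy = pytest.importorskip("dendropy")
        gm, _, _, _ = flax_dataset
        sub = gm.subset(individuals=gm.individuals[:8])
        tree = ph.bootstrap_support(sub, n_reps=10, seed=1)
        parsed = dendropy.Tree.get(data=tree.to_newick(with_support=True), schema="newick")
        assert len(parsed.leaf_nodes()) == 8
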