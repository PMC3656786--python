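"""Nei minimum genetic distance, neighbor-joining and locus bootstrap.

Accession-level trees from single-plant genotypes: each individual's
"allele frequency" vector at a locus is 0 / 0.5 / 1, so the per-locus Nei
minimum distance reduces to ``(s_ii + s_jj)/2 - s_ij`` with ``s`` the
identity-by-state score used for molecular coancestry.  NULL is treated as
an ordinary allele.  Neighbor-joining is the Saitou-Nei agglomeration with
deterministic lexicographic tie-breaking; negative branch lengths are
clamped to zero and the clamped deficit recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if np.nanmax(np.abs(np.diag(v))) > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < -1e-12:
                raise ValueError("negative distances")
        self.values = v


def _ibs_scores(gm: GenotypeMatrix):
    """Per-locus IBS cross-score s_ij and self-score s_ii for all pairs."""
    a1 = gm.calls[:, :, 0].astype(np.int64)
    a2 = gm.calls[:, :, 1].astype(np.int64)
    called = gm.calls[:, :, 0] != MISSING
    return a1, a2, called


def nei_minimum_distance_matrix(gm: GenotypeMatrix, loci: list[str] | None = None) -> DistanceMatrix:
    """All-pairs Nei minimum distance over shared called loci.

    Per locus, D_l = (sum x^2 + sum y^2)/2 - sum x y with x, y the 0/0.5/1
    genotype frequency vectors; D is the mean over loci called in both
    individuals.  Pairs sharing no called locus raise.
    """
    sub = gm if loci is None else gm.subset(loci=loci)
    a1, a2, called = _ibs_scores(sub)
    n = sub.n_individuals
    # self score sum x^2: 1 for homozygote, 0.5 for heterozygote
    self_sq = np.where(a1 == a2, 1.0, 0.5)  # (n, m)
    out = np.zeros((n, n))
    for i in range(n):
        cross = ((a1[i] == a1).astype(np.int8) + (a1[i] == a2) + (a2[i] == a1) + (a2[i] == a2)) / 4.0
        d_l = (self_sq[i] + self_sq) / 2.0 - cross  # (n, m)
        ok = called[i] & called
        cnt = ok.sum(axis=1)
        if (cnt == 0).any():
            k = int(np.argmax(cnt == 0))
            raise ValueError(f"no shared called loci between {sub.individuals[i]!r} and {sub.individuals[k]!r}")
        out[i] = (d_l * ok).sum(axis=1) / cnt
    out = np.clip((out + out.T) / 2.0, 0.0, None)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(list(sub.individuals), out)


def nei_minimum_distance(gm: GenotypeMatrix, i: str, j: str) -> float:
    """Nei minimum distance between two individuals."""
    dm = nei_minimum_distance_matrix(gm.subset(individuals=[i, j]))
    return float(dm.values[0, 1])


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    """Node of an unrooted tree (rooted representation at the last join)."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset:
        if self.is_leaf:
            return frozenset([self.label])
        return frozenset().union(*(c.leaves() for c, _ in self.children))

    def to_newick(self, with_support: bool = False) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, ws: bool) -> str:
        if self.is_leaf:
            return self.label
        inner = ",".join(f"{c._newick(ws)}:{bl:.6g}" for c, bl in self.children)
        lab = ""
        if ws and self.support is not None:
            lab = f"{self.support:g}"
        return f"({inner}){lab}"


@dataclass
class Tree:
    root: TreeNode
    clamped_deficit: float = 0.0  # total negative branch length clamped to 0

    def leaves(self) -> frozenset:
        return self.root.leaves()

    def bipartitions(self) -> set[frozenset]:
        """Nontrivial splits, each canonicalized as the side not containing
        the alphabetically first leaf."""
        all_leaves = self.leaves()
        ref = min(all_leaves)
        n = len(all_leaves)
        splits = set()

        def walk(node: TreeNode):
            for child, _ in node.children:
                below = child.leaves()
                side = below if ref not in below else all_leaves - below
                if 2 <= len(side) <= n - 2:
                    splits.add(side)
                walk(child)

        walk(self.root)
        return splits

    def to_newick(self, with_support: bool = False) -> str:
        return self.root.to_newick(with_support)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with lexicographic tie-breaking.

    Cluster labels for tie-breaking are the alphabetically smallest leaf in
    each cluster; among Q-minimal pairs (within 1e-12) the lowest
    (label_i, label_j) pair is joined.  Negative branch lengths are clamped
    to zero with the deficit accumulated on the returned tree.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    d = dm.values.copy()
    nodes = [TreeNode(label=l) for l in dm.labels]
    tags = list(dm.labels)  # representative (min) leaf label per cluster
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((tags[i], tags[j]))) + (i, j) for i, j in cand if i < j),
        )
        i, j = best[2], best[3]
        dij = d[i, j]
        li_raw = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        li = clamp(li_raw)
        lj = clamp(dij - li_raw)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (d[i] + d[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [new]
        tags = [tags[k] for k in keep] + [min(best[0], best[1])]

    # final 3-way join: closed-form lengths
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = clamp((dab + dac - dbc) / 2)
    lb = clamp((dab + dbc - dac) / 2)
    lc = clamp((dac + dbc - dab) / 2)
    order = sorted(range(3), key=lambda k: tags[k])
    lens = [la, lb, lc]
    root = TreeNode(children=[(nodes[k], lens[k]) for k in order])
    return Tree(root, clamped_deficit=deficit)


def bootstrap_support(gm: GenotypeMatrix, n_reps: int = 1000, seed: int = 0,
                      loci: list[str] | None = None) -> Tree:
    """Point-estimate NJ tree with locus-bootstrap supports (percent).

    Loci are resampled with replacement ``n_reps`` times; each internal
    edge of the point tree gets the percentage of replicate trees containing
    the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    use_loci = list(loci) if loci is not None else list(gm.loci)
    if len(use_loci) < 2:
        raise ValueError("bootstrap needs >= 2 loci")
    sub = gm.subset(loci=use_loci)
    tree = neighbor_joining(nei_minimum_distance_matrix(sub))
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        pick = rng.integers(0, len(use_loci), size=len(use_loci))
        # locus ids must stay unique, so resampled columns get fresh names
        calls = sub.calls[:, pick, :]
        rep = GenotypeMatrix(list(sub.individuals), [f"L{t}" for t in range(len(pick))], calls, sub.populations)
        rtree = neighbor_joining(nei_minimum_distance_matrix(rep))
        rbps = rtree.bipartitions()
        for bp in counts:
            if bp in rbps:
                counts[bp] += 1

    def annotate(node: TreeNode):
        all_leaves = tree.leaves()
        ref = min(all_leaves)
        for child, _ in node.children:
            below = child.leaves()
            side = below if ref not in below else all_leaves - below
            if 2 <= len(side) <= len(all_leaves) - 2 and not child.is_leaf:
                child.support = 100.0 * counts.get(side, 0) / n_reps
            annotate(child)

    annotate(tree.root)
    return tree
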