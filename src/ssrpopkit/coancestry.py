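"""Molecular coancestry (identity-by-state kinship) after Caballero & Toro.

The per-locus coancestry of individuals i and j is
``f = 1/4 (I11 + I12 + I21 + I22)`` where ``Ixy`` indicates identity of
allele x of i with allele y of j; over single-locus genotype pairs it can
take only the values 0, 1/4, 1/2 and 1.  The pairwise coancestry is the mean
over loci where both individuals are called (pairwise deletion).  The NULL
allele is an allele state: NULL vs NULL is identical, NULL vs a size is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


def locus_coancestry(cell_i, cell_j) -> float:
    """Per-locus coancestry of two genotype cells; neither may be MISSING."""
    a1, a2 = int(cell_i[0]), int(cell_i[1])
    b1, b2 = int(cell_j[0]), int(cell_j[1])
    if MISSING in (a1, a2, b1, b2):
        raise ValueError("locus coancestry undefined for MISSING cells; skip the locus")
    return ((a1 == b1) + (a1 == b2) + (a2 == b1) + (a2 == b2)) / 4.0


@dataclass
class CoancestryMatrix:
    """Symmetric f_ij matrix with undefined-pair bookkeeping."""

    individuals: list[str]
    values: np.ndarray          # (n, n) float, NaN where undefined
    n_shared_loci: np.ndarray   # (n, n) int

    def histogram(self, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        """Histogram of off-diagonal pairwise values (defined pairs only)."""
        iu = np.triu_indices(len(self.individuals), k=1)
        vals = self.values[iu]
        vals = vals[~np.isnan(vals)]
        return np.histogram(vals, bins=bins, range=(0.0, 1.0))

    def mean_offdiagonal(self) -> float:
        iu = np.triu_indices(len(self.individuals), k=1)
        return float(np.nanmean(self.values[iu]))


def coancestry_matrix(gm: GenotypeMatrix) -> CoancestryMatrix:
    """All-pairs molecular coancestry, averaged over shared called loci.

    Vectorized over loci: for each pair, the four ordered allele
    cross-comparisons are summed and divided by 4, then averaged over loci
    where both cells are called.  Pairs sharing no called locus get NaN.
    """
    calls = gm.calls  # (n, m, 2)
    n = gm.n_individuals
    called = calls[:, :, 0] != MISSING  # (n, m)
    vals = np.full((n, n), np.nan)
    shared = np.zeros((n, n), dtype=np.int64)
    a1 = calls[:, :, 0].astype(np.int64)
    a2 = calls[:, :, 1].astype(np.int64)
    for i in range(n):
        ok = called[i] & called  # (n, m)
        s = (
            (a1[i] == a1).astype(np.int8) + (a1[i] == a2) + (a2[i] == a1) + (a2[i] == a2)
        ) / 4.0
        cnt = ok.sum(axis=1)
        with np.errstate(invalid="ignore"):
            fi = np.where(cnt > 0, (s * ok).sum(axis=1) / np.maximum(cnt, 1), np.nan)
        vals[i] = fi
        shared[i] = cnt
    return CoancestryMatrix(list(gm.individuals), vals, shared)


def group_coancestry_summary(cm: CoancestryMatrix, grouping: dict[str, str]) -> dict:
    """Within- and between-group mean coancestries.

    Returns ``{"intra": {group: mean or nan}, "inter": {(g1, g2): mean}}``
    where intra means are over unordered pairs i<j inside a group (NaN for
    singleton groups) and inter means over all cross-group pairs.
    """
    idx = {ind: k for k, ind in enumerate(cm.individuals)}
    groups: dict[str, list[int]] = {}
    for ind, g in grouping.items():
        if ind in idx:
            groups.setdefault(g, []).append(idx[ind])
    for g, members in groups.items():
        if not members:
            raise ValueError(f"group {g!r} is empty")
    intra = {}
    for g, members in groups.items():
        if len(members) < 2:
            intra[g] = float("nan")
            continue
        ii, jj = np.triu_indices(len(members), k=1)
        m = np.asarray(members)
        intra[g] = float(np.nanmean(cm.values[m[ii], m[jj]]))
    inter = {}
    names = sorted(groups)
    for x in range(len(names)):
        for y in range(x + 1, len(names)):
            g1, g2 = names[x], names[y]
            block = cm.values[np.ix_(groups[g1], groups[g2])]
            inter[(g1, g2)] = float(np.nanmean(block))
    return {"intra": intra, "inter": inter}
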