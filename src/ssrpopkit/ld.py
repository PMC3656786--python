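"""Pairwise linkage disequilibrium for selfing, multiallelic panels.

Heterozygous and missing cells are dropped and each remaining individual
contributes one two-locus haplotype (justified by near-complete
homozygosity in highly selfing material).  The multiallelic r-squared is
the frequency-weighted average of allele-pair r-squared values:

    r2 = sum_i sum_j p_i q_j D_ij^2 / (p_i (1 - p_i) q_j (1 - q_j))

with D_ij = f_ij - p_i q_j.  Decay with genetic distance is fitted with the
drift-recombination expectation of Hill & Weir (as popularized for selfing
crops by Breseghello & Sorrells), and the LD-block extent is the map
distance at which the fitted curve crosses a threshold (default 0.1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import MISSING, GenotypeMatrix, LinkageMap


def _haplotypes(gm: GenotypeMatrix, ja: int, jb: int) -> tuple[np.ndarray, np.ndarray]:
    """Allele pairs from individuals homozygous and called at both loci."""
    a = gm.calls[:, ja, :]
    b = gm.calls[:, jb, :]
    keep = (a[:, 0] == a[:, 1]) & (b[:, 0] == b[:, 1]) & (a[:, 0] != MISSING) & (b[:, 0] != MISSING)
    return a[keep, 0], b[keep, 0]


def pair_r2(gm: GenotypeMatrix, locus_a: str, locus_b: str,
            rng: np.random.Generator | None = None, n_perm: int = 999):
    """Multiallelic r² between two loci with a significance p-value.

    Returns ``(r2, n, p)`` with ``n`` the number of haplotypes used, or
    ``(nan, n, nan)`` when fewer than two haplotypes remain or either locus
    is monomorphic in the retained set.  Significance is a chi-square test
    on the haplotype contingency table (df = (k-1)(l-1)); when any expected
    cell is below 5 a permutation p-value is used instead (add-one rule).
    """
    ja, jb = gm.locus_index(locus_a), gm.locus_index(locus_b)
    ha, hb = _haplotypes(gm, ja, jb)
    n = ha.size
    if n < 2:
        return float("nan"), int(n), float("nan")
    ua, ia = np.unique(ha, return_inverse=True)
    ub, ib = np.unique(hb, return_inverse=True)
    k, l = ua.size, ub.size
    if k < 2 or l < 2:
        return float("nan"), int(n), float("nan")
    table = np.zeros((k, l))
    np.add.at(table, (ia, ib), 1.0)
    r2 = _table_r2(table)

    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        if rng is None:
            rng = np.random.default_rng(0)
        hits = 0
        ib_perm = ib.copy()
        for _ in range(n_perm):
            rng.shuffle(ib_perm)
            t = np.zeros((k, l))
            np.add.at(t, (ia, ib_perm), 1.0)
            c = ((t - expected) ** 2 / expected).sum()
            if c >= chi2 - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return float(r2), int(n), float(p)


def _table_r2(table: np.ndarray) -> float:
    """Frequency-weighted multiallelic r² from a haplotype count table."""
    n = table.sum()
    f = table / n
    p = f.sum(axis=1)
    q = f.sum(axis=0)
    d = f - np.outer(p, q)
    denom = np.outer(p * (1 - p), q * (1 - q))
    w = np.outer(p, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(denom > 0, w * d * d / denom, 0.0)
    return float(terms.sum())


UNLINKED = float("inf")


@dataclass
class LDResult:
    """Long-format pair table plus the individuals count used per pair."""

    pairs: pd.DataFrame  # columns: locus_a, locus_b, r2, n, p, linked, distance_cM

    @property
    def linked(self) -> pd.DataFrame:
        return self.pairs[self.pairs["linked"]]

    @property
    def unlinked(self) -> pd.DataFrame:
        return self.pairs[~self.pairs["linked"]]


def classify_pairs(lmap: LinkageMap, loci: list[str]):
    """Split locus pairs into linked (same linkage group, |ΔcM|) and unlinked.

    Unmapped loci are excluded entirely.  Returns (linked, unlinked) where
    linked is a list of (locus_a, locus_b, distance_cM) and unlinked a list
    of (locus_a, locus_b).
    """
    mapped = [l for l in loci if l in lmap]
    linked, unlinked = [], []
    for a, b in itertools.combinations(mapped, 2):
        if lmap.linkage_group(a) == lmap.linkage_group(b):
            linked.append((a, b, abs(lmap.position(a) - lmap.position(b))))
        else:
            unlinked.append((a, b))
    return linked, unlinked


def ld_table(gm: GenotypeMatrix, lmap: LinkageMap, loci: list[str] | None = None,
             seed: int = 0, n_perm: int = 999) -> LDResult:
    """All mapped locus pairs with r², significance and linkage class."""
    loci = list(loci) if loci is not None else list(gm.loci)
    linked, unlinked = classify_pairs(lmap, loci)
    rng = np.random.default_rng(seed)
    rows = []
    for a, b, dist in linked:
        r2, n, p = pair_r2(gm, a, b, rng=rng, n_perm=n_perm)
        rows.append((a, b, r2, n, p, True, dist))
    for a, b in unlinked:
        r2, n, p = pair_r2(gm, a, b, rng=rng, n_perm=n_perm)
        rows.append((a, b, r2, n, p, False, np.nan))
    df = pd.DataFrame(rows, columns=["locus_a", "locus_b", "r2", "n", "p", "linked", "distance_cM"])
    return LDResult(df)


def ld_summary(ldr: LDResult, alpha: float = 0.05) -> dict:
    """Mean linked/unlinked r², 95th unlinked percentile, % significant pairs.

    The percentile uses linear interpolation and is flagged unstable when
    fewer than 20 unlinked pairs are available.
    """
    pairs = ldr.pairs.dropna(subset=["r2"])
    linked = pairs[pairs["linked"]]["r2"].to_numpy()
    unlinked = pairs[~pairs["linked"]]["r2"].to_numpy()
    out = {
        "n_linked": int(linked.size),
        "n_unlinked": int(unlinked.size),
        "mean_linked_r2": float(np.mean(linked)) if linked.size else float("nan"),
        "mean_unlinked_r2": float(np.mean(unlinked)) if unlinked.size else float("nan"),
        "unlinked_p95": float(np.percentile(unlinked, 95)) if unlinked.size else float("nan"),
        "p95_unstable": unlinked.size < 20,
        "pct_significant": float(100.0 * (pairs["p"] < alpha).mean()) if len(pairs) else float("nan"),
    }
    return out


def hill_weir_expected_r2(d, rho: float, n: int):
    """Expected r² at map distance d (cM) under drift-recombination balance.

    C = rho * d;  E[r²] = ((10+C)/((2+C)(11+C))) *
    (1 + ((3+C)(12+12C+C²)) / (n(2+C)(11+C))) with n the sample size.
    """
    c = rho * np.asarray(d, dtype=float)
    lead = (10 + c) / ((2 + c) * (11 + c))
    corr = 1 + ((3 + c) * (12 + 12 * c + c * c)) / (n * (2 + c) * (11 + c))
    return lead * corr


@dataclass
class DecayFit:
    rho: float
    distance_at_threshold: float
    threshold: float
    n: int
    rss: float
    poor_fit: bool = False


def fit_decay(ldr: LDResult, n_individuals: int, threshold: float = 0.1) -> DecayFit:
    """Fit the decay curve to linked (distance, r²) pairs and locate the
    distance where expected r² crosses ``threshold``.

    Returns ``distance_at_threshold = 0`` when the curve starts below the
    threshold and ``inf`` when it never crosses it.  A fit where the curve
    cannot decrease (rho pinned at 0) is flagged poor.
    """
    linked = ldr.linked.dropna(subset=["r2", "distance_cM"])
    if len(linked) < 10:
        raise ValueError("need >= 10 linked pairs with distances to fit decay")
    d = linked["distance_cM"].to_numpy()
    y = linked["r2"].to_numpy()

    def resid(log_rho):
        return hill_weir_expected_r2(d, np.exp(log_rho[0]), n_individuals) - y

    best = None
    for start in (-3.0, 0.0, 3.0):
        sol = optimize.least_squares(resid, x0=[start], method="lm", xtol=1e-15, ftol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    rho = float(np.exp(best.x[0]))
    rss = float(2 * best.cost)
    poor = False
    r2_at_0 = float(hill_weir_expected_r2(0.0, rho, n_individuals))
    if threshold >= r2_at_0:
        dist = 0.0
    else:
        limit = float(hill_weir_expected_r2(1e12, rho, n_individuals))
        if threshold <= limit or rho <= 0:
            dist = float("inf")
            poor = True
        else:
            hi = 1.0
            while hill_weir_expected_r2(hi, rho, n_individuals) > threshold:
                hi *= 2
                if hi > 1e9:
                    break
            dist = float(optimize.brentq(
                lambda x: hill_weir_expected_r2(x, rho, n_individuals) - threshold, 0.0, hi))
    # a flat or rising cloud that the monotone decreasing curve cannot follow
    if len(np.unique(y)) == 1 or np.corrcoef(d, y)[0, 1] >= 0:
        poor = True
    return DecayFit(rho=rho, distance_at_threshold=dist, threshold=threshold,
                    n=n_individuals, rss=rss, poor_fit=poor)


def bin_decay(ldr: LDResult, bin_width: float) -> pd.DataFrame:
    """Mean linked r² in distance bins of the given width (block-sized bins
    for cross-group decay comparisons)."""
    linked = ldr.linked.dropna(subset=["r2", "distance_cM"]).copy()
    linked["bin"] = (linked["distance_cM"] // bin_width) * bin_width
    g = linked.groupby("bin")["r2"].agg(["mean", "count"]).reset_index()
    return g.rename(columns={"bin": "distance_bin_cM", "mean": "mean_r2", "count": "n_pairs"})
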