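"""Per-population diversity statistics for multiallelic markers.

Implements the classical summary set for a germplasm panel: unbiased gene
diversity (Nei's He with the small-sample n/(n-1) correction over gene
copies), observed heterozygosity, allele counts, rare alleles (MAF below a
threshold), the inbreeding coefficient F_IS = 1 - Ho/He, percent polymorphic
loci, Botstein's polymorphism information content, and rarefaction-based
allelic richness and private allelic richness (hypergeometric expectation in
a standardized subsample of g gene copies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, AlleleFrequencyTable, GenotypeMatrix, allele_frequencies


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return out


def _comb_ratio(n_small: float, n_big: float, g: float) -> float:
    """C(n_small, g) / C(n_big, g), 0 when g > n_small."""
    if g > n_small:
        return 0.0
    return float(np.exp(_log_comb(n_small, g) - _log_comb(n_big, g)))


def unbiased_gene_diversity(freqs: dict[int, float], n_genes: int) -> float:
    """Nei's unbiased gene diversity (n/(n-1))(1 - sum p^2), n = gene copies.

    Undefined (ValueError) when fewer than two gene copies were sampled.
    """
    if n_genes < 2:
        raise ValueError("unbiased gene diversity needs >= 2 gene copies")
    p = np.fromiter(freqs.values(), dtype=float)
    he = n_genes / (n_genes - 1) * (1.0 - float(np.sum(p * p)))
    return min(he, 1.0)


def gene_diversity(freqs: dict[int, float]) -> float:
    """Plain (biased) gene diversity 1 - sum p^2."""
    p = np.fromiter(freqs.values(), dtype=float)
    return 1.0 - float(np.sum(p * p))


def observed_heterozygosity(gm: GenotypeMatrix, individuals: list[str], locus: str) -> float:
    """Fraction of non-missing individuals carrying two distinct allele codes."""
    j = gm.locus_index(locus)
    ii = [gm.individual_index(i) for i in individuals]
    cells = gm.calls[ii, j, :]
    called = cells[:, 0] != MISSING
    if not called.any():
        raise ValueError(f"no called individuals at locus {locus!r}")
    het = cells[called, 0] != cells[called, 1]
    return float(het.mean())


def fis(ho: float, he: float) -> float:
    """Inbreeding coefficient 1 - Ho/He; undefined when He == 0."""
    if he <= 0:
        raise ValueError("F_IS undefined for He = 0")
    return 1.0 - ho / he


def pic(freqs: dict[int, float]) -> float:
    """Botstein's polymorphism information content.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.
    """
    p = np.fromiter(freqs.values(), dtype=float)
    sp2 = float(np.sum(p * p))
    sp4 = float(np.sum(p ** 4))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    return 1.0 - sp2 - (sp2 * sp2 - sp4)


def rarefied_allelic_richness(counts: dict[int, int], g: int) -> float:
    """Expected number of distinct alleles in a subsample of g gene copies.

    ``counts`` maps allele -> observed copy count.  Hypergeometric
    expectation: sum_a [1 - C(n - n_a, g) / C(n, g)].
    """
    n = sum(counts.values())
    if g > n:
        raise ValueError(f"rarefaction size g={g} exceeds sampled gene copies n={n}; lower g")
    if g < 1:
        raise ValueError("g must be >= 1")
    return float(sum(1.0 - _comb_ratio(n - na, n, g) for na in counts.values()))


def rarefied_private_alleles(counts_by_pop: dict[str, dict[int, int]], g: int) -> dict[str, float]:
    """Kalinowski's rarefied private allelic richness per population.

    For population j, sums over alleles the probability that the allele is
    sampled in a g-copy subsample of j and simultaneously missed in g-copy
    subsamples of every other population (hypergeometric throughout).
    """
    pops = list(counts_by_pop)
    n_by_pop = {p: sum(counts_by_pop[p].values()) for p in pops}
    n_min = min(n_by_pop.values())
    if g > n_min:
        raise ValueError(f"g={g} exceeds smallest population gene count {n_min}; lower g")
    alleles = sorted({a for c in counts_by_pop.values() for a in c})
    out = {}
    for j in pops:
        total = 0.0
        for a in alleles:
            na = counts_by_pop[j].get(a, 0)
            p_in_j = 1.0 - _comb_ratio(n_by_pop[j] - na, n_by_pop[j], g)
            if p_in_j == 0.0:
                continue
            p_miss_elsewhere = 1.0
            for k in pops:
                if k == j:
                    continue
                nk = counts_by_pop[k].get(a, 0)
                p_miss_elsewhere *= _comb_ratio(n_by_pop[k] - nk, n_by_pop[k], g)
            total += p_in_j * p_miss_elsewhere
        out[j] = total
    return out


@dataclass
class DiversitySummary:
    """One row of the per-population diversity table (locus averages)."""

    population: str
    n_individuals: int
    uhe: float
    ho: float
    na: int
    rs: float
    pi_private: float
    ra: int
    fis: float
    pct_polymorphic: float
    pic: float
    unreliable: bool = False


def _allele_counts(freqs: AlleleFrequencyTable, pop: str, locus: str) -> dict[int, int]:
    key = (pop, locus)
    n = freqs.n_genes[key]
    return {a: int(round(f * n)) for a, f in freqs.freqs[key].items()}


def diversity_table(
    gm: GenotypeMatrix,
    grouping: dict[str, str] | None = None,
    maf_rare_threshold: float = 0.05,
    g: int | None = None,
    pooled_label: str = "all",
) -> pd.DataFrame:
    """Per-population diversity summary plus a pooled row.

    Statistics are averaged over loci with defined values (pairwise
    deletion).  ``g`` is the rarefaction standard (gene copies); by default
    twice the smallest population size.  Rare alleles are counted on each
    population's own frequencies; the pooled row uses pooled frequencies.
    Populations with fewer than two individuals are flagged unreliable.
    """
    if grouping is None:
        grouping = gm.populations or {i: "pop1" for i in gm.individuals}
    freqs = allele_frequencies(gm, grouping)
    pops = freqs.populations
    members = {p: [i for i in gm.individuals if grouping.get(i) == p] for p in pops}
    if g is None:
        g = 2 * min(len(m) for m in members.values())

    rows = []
    # rarefied private alleles need all populations at once, locus by locus
    private: dict[str, list[float]] = {p: [] for p in pops}
    if len(pops) >= 1:
        for locus in gm.loci:
            counts_by_pop = {
                p: _allele_counts(freqs, p, locus)
                for p in pops
                if (p, locus) not in freqs.undefined and freqs.n_genes[(p, locus)] >= g
            }
            if len(counts_by_pop) != len(pops):
                continue
            pa = rarefied_private_alleles(counts_by_pop, g)
            for p in pops:
                private[p].append(pa[p])

    def summarize(label: str, pop_list: list[str], inds: list[str]) -> DiversitySummary:
        uhe_l, ho_l, fis_l, pic_l, rs_l = [], [], [], [], []
        na = 0
        ra = 0
        n_poly = 0
        n_with_data = 0
        for locus in gm.loci:
            if len(pop_list) == 1:
                key = (pop_list[0], locus)
                if key in freqs.undefined:
                    continue
                fvec, n = freqs.freqs[key], freqs.n_genes[key]
            else:
                fvec, n = freqs.pooled(locus)
                if n == 0:
                    continue
            n_with_data += 1
            na += len(fvec)
            if len(fvec) >= 2:
                n_poly += 1
                ra += sum(1 for f in fvec.values() if f < maf_rare_threshold)
            if n >= 2:
                uhe = unbiased_gene_diversity(fvec, n)
                uhe_l.append(uhe)
                pic_l.append(pic(fvec))
                try:
                    ho = observed_heterozygosity(gm, inds, locus)
                except ValueError:
                    ho = np.nan
                ho_l.append(ho)
                if len(fvec) >= 2 and uhe > 0 and not np.isnan(ho):
                    fis_l.append(fis(ho, uhe))
                counts = {a: int(round(f * n)) for a, f in fvec.items()}
                if sum(counts.values()) >= g:
                    rs_l.append(rarefied_allelic_richness(counts, g))
        pi_vals = private[pop_list[0]] if len(pop_list) == 1 else []
        return DiversitySummary(
            population=label,
            n_individuals=len(inds),
            uhe=float(np.nanmean(uhe_l)) if uhe_l else np.nan,
            ho=float(np.nanmean(ho_l)) if ho_l else np.nan,
            na=na,
            rs=float(np.mean(rs_l)) if rs_l else np.nan,
            pi_private=float(np.mean(pi_vals)) if pi_vals else np.nan,
            ra=ra,
            fis=float(np.mean(fis_l)) if fis_l else np.nan,
            pct_polymorphic=100.0 * n_poly / n_with_data if n_with_data else np.nan,
            pic=float(np.mean(pic_l)) if pic_l else np.nan,
            unreliable=len(inds) < 2,
        )

    for p in pops:
        rows.append(summarize(p, [p], members[p]))
    all_inds = [i for p in pops for i in members[p]]
    rows.append(summarize(pooled_label, pops, all_inds))
    return pd.DataFrame([vars(r) for r in rows])
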