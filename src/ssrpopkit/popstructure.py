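"""Population structure: LD thinning, PCoA, admixture inference, Evanno's
delta-K, Q-threshold assignment and pairwise FST.

The admixture model is a reduced-fidelity reimplementation of the classic
Bayesian clustering sampler: cluster allele frequencies get a Dirichlet
(lambda = 1) prior, individual admixture proportions a symmetric
Dirichlet(alpha) prior with alpha updated by a Metropolis step, and allele
copies carry latent cluster-origin indicators updated by Gibbs sampling.
No linkage model and no prior population information are implemented.
lnP(D) is estimated as mean(lnL) - var(lnL)/2 over kept sweeps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix, LinkageMap, allele_frequencies, minor_allele_frequency
from .ld import pair_r2
from .phylogeny import DistanceMatrix

ADMIXED = "ADMIXED"


# ---------------------------------------------------------------------------
# marker thinning


def thin_by_ld(gm: GenotypeMatrix, lmap: LinkageMap, r2_max: float = 0.4,
               maf_min: float = 0.05, seed: int = 0) -> list[str]:
    """Greedy LD pruning along each linkage group.

    Loci with pooled MAF below ``maf_min`` are dropped first; then, scanning
    each linkage group in map order, a locus is kept only if its r² with
    every already-kept locus of the group is <= ``r2_max``.  Unmapped loci
    are retained untouched (their LD cannot be classified).
    """
    freqs = allele_frequencies(gm)
    ok_maf = []
    for l in gm.loci:
        try:
            maf = minor_allele_frequency(freqs, l)
        except ValueError:
            continue
        if maf >= maf_min:
            ok_maf.append(l)
    rng = np.random.default_rng(seed)
    kept: list[str] = [l for l in ok_maf if l not in lmap]
    by_lg: dict[str, list[str]] = {}
    for l in ok_maf:
        if l in lmap:
            by_lg.setdefault(lmap.linkage_group(l), []).append(l)
    for lg, loci in by_lg.items():
        loci = sorted(loci, key=lambda l: (lmap.position(l), l))
        chosen: list[str] = []
        for l in loci:
            ok = True
            for other in chosen:
                r2, _, _ = pair_r2(gm, l, other, rng=rng, n_perm=0)
                if not np.isnan(r2) and r2 > r2_max:
                    ok = False
                    break
            if ok:
                chosen.append(l)
        kept.extend(chosen)
    return [l for l in gm.loci if l in set(kept)]


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PCoAResult:
    labels: list[str]
    coordinates: np.ndarray      # (n, n_axes)
    eigenvalues: np.ndarray      # all eigenvalues, descending
    pct_variation: np.ndarray    # positive-eigenvalue shares (%), per axis


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Principal coordinate analysis by Gower double-centering of -d²/2."""
    d2 = dm.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = 100.0 * pos / pos.sum() if pos.sum() > 0 else np.full(n, np.nan)
    coords = evecs[:, :n_axes] * np.sqrt(pos[:n_axes])[None, :]
    return PCoAResult(list(dm.labels), coords, evals, shares[:n_axes])


# ---------------------------------------------------------------------------
# admixture model


@dataclass
class QMatrix:
    individuals: list[str]
    q: np.ndarray            # (n, K), rows sum to 1
    ln_prob_data: float
    k: int
    seed: int
    burn_in: int
    iters: int
    alpha: float             # posterior-mean admixture concentration


def _encode_alleles(gm: GenotypeMatrix):
    """Integer allele indices per locus; -1 marks missing slots."""
    n, m = gm.n_individuals, gm.n_loci
    x = np.full((n, m, 2), -1, dtype=np.int64)
    n_alleles = np.zeros(m, dtype=np.int64)
    for j in range(m):
        col = gm.calls[:, j, :]
        vals = np.unique(col[col != MISSING])
        lut = {int(v): k for k, v in enumerate(vals)}
        n_alleles[j] = len(vals)
        for i in range(n):
            for c in (0, 1):
                v = int(col[i, c])
                if v != MISSING:
                    x[i, j, c] = lut[v]
    return x, n_alleles


def admixture_gibbs(gm: GenotypeMatrix, k: int, burn_in: int = 10000,
                    iters: int = 100000, seed: int = 0,
                    alpha0: float = 1.0, lam: float = 1.0) -> QMatrix:
    """Gibbs sampler for the admixture model; returns posterior-mean Q.

    One sweep updates the latent origins of all allele copies, the cluster
    allele frequencies, the admixture rows, and alpha (random-walk
    Metropolis with a uniform(0, 10] prior).
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > gm.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    rng = np.random.default_rng(seed)
    x, n_alleles = _encode_alleles(gm)
    n, m = gm.n_individuals, gm.n_loci
    amax = int(n_alleles.max())
    called = x >= 0                       # (n, m, 2)
    xs = np.where(called, x, 0)

    if k == 1:
        q = np.ones((n, 1))
        # lnP(D) under the single-cluster model: posterior-mean frequencies
        lnls = []
        p = np.empty((1, m, amax))
        z = np.zeros((n, m, 2), dtype=np.int64)
        for sweep in range(max(iters // 100, 50)):
            p = _sample_freqs(rng, xs, called, z, 1, m, amax, n_alleles, lam)
            lnls.append(_loglik(q, p, xs, called))
        lnls = np.asarray(lnls)
        return QMatrix(list(gm.individuals), q, float(lnls.mean() - lnls.var() / 2),
                       1, seed, burn_in, iters, alpha0)

    z = rng.integers(0, k, size=(n, m, 2))
    q = np.full((n, k), 1.0 / k)
    alpha = alpha0
    q_sum = np.zeros((n, k))
    lnls = []
    kept = 0
    total = burn_in + iters
    for sweep in range(total):
        p = _sample_freqs(rng, xs, called, z, k, m, amax, n_alleles, lam)
        # z | p, q : gather p[k, j, a] for every copy, (k, n, m, 2) -> (n, m, 2, k)
        gj = np.arange(m)[None, :, None]
        pk = p[:, gj, xs]                 # (k, n, m, 2)
        probs = q.T[:, :, None, None] * pk  # (k, n, m, 2)
        probs = np.moveaxis(probs, 0, -1)   # (n, m, 2, k)
        probs[~called] = 1.0
        cdf = np.cumsum(probs, axis=-1)
        u = rng.random((n, m, 2)) * cdf[..., -1]
        z = (u[..., None] > cdf).sum(axis=-1)
        # q | z
        counts = np.zeros((n, k))
        zc = np.where(called, z, -1)
        for kk in range(k):
            counts[:, kk] = (zc == kk).sum(axis=(1, 2))
        q = rng.gamma(alpha + counts) + 1e-300
        q /= q.sum(axis=1, keepdims=True)
        # alpha | q : random-walk Metropolis, symmetric Dirichlet prior
        prop = alpha + rng.normal(0.0, 0.25)
        if 0 < prop <= 10.0:
            def lp(a):
                return n * (gammaln(k * a) - k * gammaln(a)) + (a - 1) * np.log(q).sum()
            if np.log(rng.random()) < lp(prop) - lp(alpha):
                alpha = prop
        if sweep >= burn_in:
            q_sum += q
            lnls.append(_loglik(q, p, xs, called))
            kept += 1
    qbar = q_sum / kept
    lnls = np.asarray(lnls)
    lnpd = float(lnls.mean() - lnls.var() / 2)
    return QMatrix(list(gm.individuals), qbar, lnpd, k, seed, burn_in, iters, float(alpha))


def _sample_freqs(rng, xs, called, z, k, m, amax, n_alleles, lam):
    """Dirichlet draw of cluster x locus allele frequencies given origins."""
    counts = np.zeros((k, m, amax))
    n = xs.shape[0]
    zc = np.where(called, z, 0)
    flat_k = zc.ravel()
    flat_j = np.broadcast_to(np.arange(m)[None, :, None], xs.shape).ravel()
    flat_a = xs.ravel()
    w = called.ravel().astype(float)
    np.add.at(counts, (flat_k, flat_j, flat_a), w)
    g = rng.gamma(counts + lam)
    # zero out allele slots beyond each locus's allele count
    mask = np.arange(amax)[None, :] < n_alleles[:, None]
    g = g * mask[None, :, :]
    g /= g.sum(axis=2, keepdims=True)
    return g


def _loglik(q, p, xs, called):
    """log P(X | P, Q) summing log sum_k q_ik p_k,j,a over called copies."""
    m = xs.shape[1]
    gj = np.arange(m)[None, :, None]
    pk = p[:, gj, xs]                    # (k, n, m, 2)
    lik = np.einsum("ik,kijc->ijc", q, pk)
    lik = np.where(called, lik, 1.0)
    return float(np.log(np.clip(lik, 1e-300, None)).sum())


# ---------------------------------------------------------------------------
# Evanno delta-K


def evanno_delta_k(scan: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno's second-difference statistic from replicate lnP(D) values.

    ``scan`` maps K -> replicate lnP(D) list; delta-K is defined for interior
    K with at least two replicates: |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)).
    """
    ks = sorted(scan)
    if len(ks) < 3:
        raise ValueError("delta-K needs at least 3 consecutive K values")
    means = {k: float(np.mean(scan[k])) for k in ks}
    sds = {k: float(np.std(scan[k], ddof=1)) if len(scan[k]) > 1 else np.nan for k in ks}
    rows = []
    for idx, k in enumerate(ks):
        lprime = means[k] - means[ks[idx - 1]] if idx > 0 else np.nan
        if 0 < idx < len(ks) - 1:
            lsec = abs(means[ks[idx + 1]] - 2 * means[k] + means[ks[idx - 1]])
            dk = lsec / sds[k] if sds[k] and sds[k] > 0 else np.nan
        else:
            lsec, dk = np.nan, np.nan
        rows.append((k, means[k], sds[k], lprime, lsec, dk))
    return pd.DataFrame(rows, columns=["K", "mean_lnP", "sd_lnP", "L_prime", "abs_L_second", "delta_k"])


def assign_groups(q: QMatrix, threshold: float = 0.70) -> dict[str, str]:
    """Assign each individual to its argmax cluster if maxQ >= threshold,
    else to the ADMIXED group."""
    out = {}
    for i, ind in enumerate(q.individuals):
        kk = int(np.argmax(q.q[i]))
        out[ind] = f"cluster{kk + 1}" if q.q[i, kk] >= threshold else ADMIXED
    return out


# ---------------------------------------------------------------------------
# FST


def _wc_components(calls: np.ndarray, labels: np.ndarray):
    """Weir-Cockerham (1984) variance components summed over alleles, per locus.

    ``calls``: (n, m, 2) allele codes; ``labels``: (n,) integer groups.
    Returns (a_sum, abc_sum, hs_sum, ht_sum) arrays of length m; hs/ht feed
    the Nei GST cross-check.
    """
    groups = np.unique(labels)
    r = len(groups)
    m = calls.shape[1]
    a_sum = np.zeros(m)
    abc_sum = np.zeros(m)
    hs_sum = np.full(m, np.nan)
    ht_sum = np.full(m, np.nan)
    for j in range(m):
        col = calls[:, j, :]
        called = col[:, 0] != MISSING
        alleles = np.unique(col[called])
        if alleles.size < 2:
            continue
        n_i = np.array([float((called & (labels == g)).sum()) for g in groups])
        if (n_i < 1).any() or n_i.sum() < 2:
            continue
        nbar = n_i.mean()
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        hs_j = 0.0
        ht_p = np.zeros(alleles.size)
        a_j = 0.0
        abc_j = 0.0
        for ai, a in enumerate(alleles):
            p_i = np.empty(r)
            h_i = np.empty(r)
            for gi, g in enumerate(groups):
                sub = col[called & (labels == g)]
                p_i[gi] = (sub == a).mean()
                h_i[gi] = ((sub[:, 0] == a) != (sub[:, 1] == a)).mean()
            pbar = (n_i * p_i).sum() / (r * nbar)
            ht_p[ai] = pbar
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            if nbar <= 1 or nc <= 0:
                continue
            va = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
            vb = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
            vc = hbar / 2
            a_j += va
            abc_j += va + vb + vc
        a_sum[j] = a_j
        abc_sum[j] = abc_j
        hs_sum[j] = np.mean([1 - sum(((col[called & (labels == g)] == a).mean()) ** 2 for a in alleles) for g in groups])
        ht_sum[j] = 1 - float((ht_p ** 2).sum())
    return a_sum, abc_sum, hs_sum, ht_sum


def wc_theta(gm: GenotypeMatrix, grouping: dict[str, str], per_locus: bool = False):
    """Multiallelic Weir-Cockerham theta over all groups in ``grouping``."""
    labels_str = [grouping[i] for i in gm.individuals if i in grouping]
    inds = [i for i in gm.individuals if i in grouping]
    sub = gm.subset(individuals=inds)
    uniq = sorted(set(labels_str))
    lab = np.array([uniq.index(s) for s in labels_str])
    a, abc, hs, ht = _wc_components(sub.calls, lab)
    if per_locus:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(abc != 0, a / abc, np.nan)
    tot = abc.sum()
    if tot == 0:
        return float("nan")
    return float(a.sum() / tot)


def nei_gst(gm: GenotypeMatrix, grouping: dict[str, str]) -> float:
    """Multilocus Nei GST = 1 - sum Hs / sum Ht (unweighted group means)."""
    labels_str = [grouping[i] for i in gm.individuals if i in grouping]
    inds = [i for i in gm.individuals if i in grouping]
    sub = gm.subset(individuals=inds)
    uniq = sorted(set(labels_str))
    lab = np.array([uniq.index(s) for s in labels_str])
    _, _, hs, ht = _wc_components(sub.calls, lab)
    ok = ~np.isnan(ht)
    if not ok.any() or np.nansum(ht) == 0:
        return float("nan")
    return float(1.0 - np.nansum(hs[ok]) / np.nansum(ht[ok]))


def pairwise_fst(gm: GenotypeMatrix, grouping: dict[str, str], n_perm: int = 999,
                 seed: int = 0) -> pd.DataFrame:
    """Pairwise Weir-Cockerham theta (with Nei GST cross-check) and
    permutation p-values (add-one rule)."""
    groups = sorted(set(grouping.values()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if sum(1 for v in grouping.values() if v == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        inds = [i for i in gm.individuals if grouping.get(i) in (g1, g2)]
        sub = gm.subset(individuals=inds)
        lab = np.array([0 if grouping[i] == g1 else 1 for i in inds])
        a, abc, hs, ht = _wc_components(sub.calls, lab)
        theta = float(a.sum() / abc.sum()) if abc.sum() != 0 else float("nan")
        gst = float(1.0 - np.nansum(hs) / np.nansum(ht)) if np.nansum(ht) else float("nan")
        if np.isnan(theta):
            rows.append((g1, g2, theta, gst, float("nan")))
            continue
        hits = 0
        perm = lab.copy()
        for _ in range(n_perm):
            rng.shuffle(perm)
            ap, abcp, _, _ = _wc_components(sub.calls, perm)
            tp = ap.sum() / abcp.sum() if abcp.sum() != 0 else -np.inf
            if tp >= theta - 1e-12:
                hits += 1
        rows.append((g1, g2, theta, gst, (hits + 1) / (n_perm + 1)))
    return pd.DataFrame(rows, columns=["group1", "group2", "theta", "gst", "p"])
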