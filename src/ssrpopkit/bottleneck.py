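"""Mutation-drift-equilibrium tests: heterozygosity-excess and mode-shift.

For each polymorphic locus the observed (unbiased) gene diversity is
compared with its expectation at mutation-drift equilibrium, simulated by a
single-deme coalescent conditioned on the observed number of alleles under
a two-phase microsatellite mutation model (single steps with probability
``p_smm``, geometric multi-step jumps with the configured variance).  A
recently bottlenecked population loses alleles faster than heterozygosity,
so an excess of loci with He above equilibrium expectation signals a
bottleneck; the global sign test compares the observed excess count with
its exact Poisson-binomial null.  The qualitative mode-shift test checks
whether the pooled allele-frequency spectrum keeps the L-shape expected at
equilibrium (rare alleles most numerous).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ._coalescent import sim_single_pop_batch
from .genotypes import GenotypeMatrix, allele_frequencies
from .diversity import unbiased_gene_diversity


def _geom_p_for_variance(variance: float) -> float:
    """Success probability of the multi-step geometric jump with the given
    variance: var = (1-p)/p^2."""
    if variance <= 0:
        return 1.0
    return (np.sqrt(1.0 + 4.0 * variance) - 1.0) / (2.0 * variance)


def _theta_for_k(n_genes: int, k: int) -> float:
    """theta with Ewens-formula expected allele count k in n_genes copies
    (the SMM-approximation starting point for conditioning)."""
    def ek(theta):
        return float(np.sum(theta / (theta + np.arange(n_genes))))
    if k >= n_genes:
        raise ValueError(f"k={k} unattainable with {n_genes} gene copies")
    return brentq(lambda t: ek(t) - k, 1e-6, 1e7)


def heq_distribution(k: int, n_genes: int, p_smm: float = 0.70,
                     variance: float = 30.0, n_sim: int = 1000, seed: int = 0,
                     n_states: int = 60, max_factor: int = 200) -> np.ndarray:
    """Simulated equilibrium He values conditional on k observed alleles.

    Coalescent loci are simulated at the theta whose Ewens-expected allele
    count is k; only loci whose simulated allele count equals k are kept.
    """
    if not (2 <= k <= n_genes):
        raise ValueError("need 2 <= k <= n_genes")
    theta = _theta_for_k(n_genes, k)
    geom_p = _geom_p_for_variance(variance)
    rng = np.random.default_rng(seed)
    out: list[float] = []
    attempts = 0
    while len(out) < n_sim and attempts < max_factor:
        s = int(rng.integers(0, 2**31 - 1))
        het, kk = sim_single_pop_batch(s, max(2 * n_sim, 500), n_genes, theta,
                                       n_states, p_smm, geom_p)
        out.extend(het[kk == k].tolist())
        attempts += 1
    if len(out) < n_sim:
        raise RuntimeError(f"conditioning on k={k} failed (acceptance too low)")
    return np.asarray(out[:n_sim])


def heq_simulate(k: int, n_genes: int, p_smm: float = 0.70, variance: float = 30.0,
                 n_sim: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Mean and sd of equilibrium He conditional on k alleles (TPM model)."""
    d = heq_distribution(k, n_genes, p_smm, variance, n_sim, seed)
    return float(d.mean()), float(d.std(ddof=1))


def _poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_l) by dynamic
    programming."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.concatenate([pmf * (1 - p), [0.0]]) + np.concatenate([[0.0], pmf * p])
    return pmf


def sign_test(he_obs: np.ndarray, heq_draws: list[np.ndarray]) -> dict:
    """Heterozygosity-excess sign test.

    ``he_obs[l]`` is the observed unbiased He at locus l and
    ``heq_draws[l]`` the simulated equilibrium He sample for that locus.
    A locus is in excess when He_obs exceeds the equilibrium mean; under
    the null each locus is in excess with probability
    P(Heq draw > mean Heq), and the two-tailed p-value of the observed
    excess count comes from the exact Poisson-binomial distribution.
    """
    he_obs = np.asarray(he_obs, dtype=float)
    if len(he_obs) != len(heq_draws):
        raise ValueError("he_obs and heq_draws lengths differ")
    excess = np.empty(len(he_obs), dtype=bool)
    p_l = np.empty(len(he_obs))
    for l, draws in enumerate(heq_draws):
        mu = draws.mean()
        excess[l] = he_obs[l] > mu
        p_l[l] = float((draws > mu).mean())
    n_excess = int(excess.sum())
    pmf = _poisson_binomial_pmf(p_l)
    # two-tailed: total probability of counts at most as likely as observed
    p_val = float(pmf[pmf <= pmf[n_excess] + 1e-15].sum())
    return {
        "n_loci": len(he_obs),
        "n_excess": n_excess,
        "expected_excess": float(p_l.sum()),
        "p": min(p_val, 1.0),
        "warning": "fewer than 10 informative loci" if len(he_obs) < 10 else None,
    }


def mode_shift(pooled_freqs: list[float]) -> dict:
    """Allele-frequency mode-shift verdict from frequencies pooled over loci.

    Alleles are binned into ten classes of width 0.1; the distribution is
    L-shaped iff the lowest class (0, 0.1] holds the strict maximum count.
    """
    f = np.asarray(pooled_freqs, dtype=float)
    f = f[(f > 0) & (f <= 1)]
    if f.size < 30:
        raise ValueError("mode-shift needs >= 30 pooled alleles")
    bins = np.clip(np.ceil(f / 0.1).astype(int) - 1, 0, 9)
    counts = np.bincount(bins, minlength=10)
    verdict = "L-shaped" if counts[0] > counts[1:].max() else "shifted"
    return {"class_counts": counts.tolist(), "verdict": verdict}


@dataclass
class BottleneckResult:
    per_locus: "object"         # DataFrame: locus, k, n_genes, he_obs, heq_mean, heq_sd, dh_sd, excess
    sign_test: dict
    mode_shift: dict


def bottleneck_test(gm: GenotypeMatrix, individuals: list[str], p_smm: float = 0.70,
                    variance: float = 30.0, n_sim: int = 1000, seed: int = 0) -> BottleneckResult:
    """Full bottleneck analysis of one group of individuals."""
    import pandas as pd

    sub = gm.subset(individuals=individuals)
    freqs = allele_frequencies(sub, {i: "g" for i in individuals})
    rng = np.random.default_rng(seed)
    rows = []
    he_obs = []
    draws_all = []
    pooled = []
    for locus in sub.loci:
        key = ("g", locus)
        if key in freqs.undefined:
            continue
        fvec, n = freqs.freqs[key], freqs.n_genes[key]
        pooled.extend(fvec.values())
        k = len(fvec)
        if k < 2 or n < 5:
            continue
        he = unbiased_gene_diversity(fvec, n)
        try:
            draws = heq_distribution(k, n, p_smm, variance, n_sim,
                                     seed=int(rng.integers(0, 2**31 - 1)))
        except (RuntimeError, ValueError):
            continue
        mu, sd = float(draws.mean()), float(draws.std(ddof=1))
        rows.append({
            "locus": locus, "k": k, "n_genes": n, "he_obs": he,
            "heq_mean": mu, "heq_sd": sd,
            "dh_sd": (he - mu) / sd if sd > 0 else np.nan,
            "excess": he > mu,
        })
        he_obs.append(he)
        draws_all.append(draws)
    if not rows:
        raise ValueError("no informative loci for the bottleneck test")
    st = sign_test(np.asarray(he_obs), draws_all)
    ms = mode_shift(pooled)
    return BottleneckResult(pd.DataFrame(rows), st, ms)
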