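"""Coalescent samplers behind the FST-outlier null and the bottleneck test.

Single-locus genealogies are simulated backwards in time, either in a
(possibly hierarchical) finite island model with two sampled demes, or in a
single panmictic deme.  Time is in units of 2N generations per deme;
per-lineage migration rates are M/2 with M = 4Nm.  Microsatellite mutations
are dropped on branches at rate theta/2 and move the allele state by single
steps (SMM) or geometric multi-step jumps (TPM), reflected into a finite
state ladder.

The hot loops are numba-compiled; determinism comes from seeding numpy's
legacy global RNG inside the jitted code.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _geom_steps(p_smm: float, geom_p: float) -> int:
    if np.random.random() < p_smm:
        return 1
    u = np.random.random()
    return 1 + int(np.log(1.0 - u) / np.log(1.0 - geom_p))


@njit(cache=True)
def _sim_locus(sample_a: int, sample_b: int, deme_b: int, n_demes: int,
               group_of: np.ndarray, rate_w: float, rate_b: float,
               theta: float, n_states: int, p_smm: float, geom_p: float,
               states_out: np.ndarray) -> None:
    """One genealogy; leaf allele states written into states_out (len n)."""
    n = sample_a + sample_b
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    ntime = np.zeros(n_nodes)
    lin_node = np.empty(n, dtype=np.int64)   # active lineage -> node id
    lin_deme = np.empty(n, dtype=np.int64)
    for i in range(n):
        lin_node[i] = i
        lin_deme[i] = 0 if i < sample_a else deme_b
    counts = np.zeros(n_demes, dtype=np.int64)
    counts[0] = sample_a
    counts[deme_b] += sample_b
    n_active = n
    next_node = n
    t = 0.0
    n_groups = group_of.max() + 1
    while n_active > 1:
        coal = 0.0
        for d in range(n_demes):
            coal += counts[d] * (counts[d] - 1) / 2.0
        per_lin_mig = 0.5 * (rate_w + rate_b)
        mig = n_active * per_lin_mig
        total = coal + mig
        t += np.random.exponential(1.0 / total)
        if np.random.random() * total < coal:
            # coalescence: pick deme weighted by pair count
            u = np.random.random() * coal
            acc = 0.0
            d = 0
            for dd in range(n_demes):
                acc += counts[dd] * (counts[dd] - 1) / 2.0
                if u < acc:
                    d = dd
                    break
            # pick two distinct active lineages in deme d
            i1 = np.random.randint(counts[d])
            i2 = np.random.randint(counts[d] - 1)
            if i2 >= i1:
                i2 += 1
            # map within-deme indices to lineage slots
            slot1 = -1
            slot2 = -1
            seen = 0
            for s in range(n_active):
                if lin_deme[s] == d:
                    if seen == i1:
                        slot1 = s
                    if seen == i2:
                        slot2 = s
                    seen += 1
            anc = next_node
            next_node += 1
            ntime[anc] = t
            parent[lin_node[slot1]] = anc
            parent[lin_node[slot2]] = anc
            lin_node[slot1] = anc
            # remove slot2 by swapping with the last active slot
            lin_node[slot2] = lin_node[n_active - 1]
            lin_deme[slot2] = lin_deme[n_active - 1]
            n_active -= 1
            counts[d] -= 1
        else:
            s = np.random.randint(n_active)
            d0 = lin_deme[s]
            g0 = group_of[d0]
            to_within = np.random.random() * (rate_w + rate_b) < rate_w
            # choose a destination by rejection within the target set
            if to_within:
                dest = d0
                tries = 0
                while dest == d0 and tries < 1000:
                    c = np.random.randint(n_demes)
                    if group_of[c] == g0 and c != d0:
                        dest = c
                    tries += 1
                if dest == d0:
                    continue
            else:
                dest = d0
                tries = 0
                while tries < 1000:
                    c = np.random.randint(n_demes)
                    if group_of[c] != g0:
                        dest = c
                        break
                    tries += 1
                if dest == d0:
                    continue
            counts[d0] -= 1
            counts[dest] += 1
            lin_deme[s] = dest
    root = next_node - 1
    # mutations: parent ids always exceed child ids, so a reverse sweep
    # assigns states root-down
    nstate = np.empty(n_nodes, dtype=np.int64)
    nstate[root] = n_states // 2
    for i in range(root - 1, -1, -1):
        bl = ntime[parent[i]] - ntime[i]
        nmut = np.random.poisson(0.5 * theta * bl)
        s = nstate[parent[i]]
        for _ in range(nmut):
            step = _geom_steps(p_smm, geom_p)
            if np.random.random() < 0.5:
                step = -step
            s += step
            # reflect into [0, n_states)
            while s < 0 or s >= n_states:
                if s < 0:
                    s = -s
                if s >= n_states:
                    s = 2 * (n_states - 1) - s
        nstate[i] = s
    for i in range(n):
        states_out[i] = nstate[i]


@njit(cache=True)
def _haploid_theta_components(states: np.ndarray, n_a: int, n_states: int):
    """Weir-Cockerham variance components (numerator, denominator) for two
    haploid samples, plus pooled He; theta = num/den, and multilocus theta
    is the ratio of summed components."""
    n = states.shape[0]
    n_b = n - n_a
    num = 0.0
    den = 0.0
    sum_p2 = 0.0
    n1 = float(n_a)
    n2 = float(n_b)
    ntot = n1 + n2
    nc = (ntot - (n1 * n1 + n2 * n2) / ntot) / 1.0  # r - 1 = 1
    for a in range(n_states):
        c1 = 0
        c2 = 0
        for i in range(n):
            if states[i] == a:
                if i < n_a:
                    c1 += 1
                else:
                    c2 += 1
        if c1 + c2 == 0:
            continue
        p1 = c1 / n1
        p2 = c2 / n2
        pbar = (c1 + c2) / ntot
        sum_p2 += pbar * pbar
        msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / 1.0
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2.0)
        num += msp - msg
        den += msp + (nc - 1.0) * msg
    he = 1.0 - sum_p2
    return num, den, he


@njit(cache=True)
def sim_island_batch(seed: int, thetas: np.ndarray, sample_a: int, sample_b: int,
                     n_demes: int, demes_per_group: int, rate_w: float,
                     rate_b: float, n_states: int, p_smm: float, geom_p: float):
    """Simulate len(thetas) island-model loci (per-locus mutation rates);
    returns (num, den, he) arrays of Weir-Cockerham components (per-locus
    theta-hat = num/den where den > 0).

    Demes 0..demes_per_group-1 form group 0, the next block group 1, etc.;
    the two samples are taken from deme 0 and from the first deme of the
    last group (a different deme of group 0 when there is a single group).
    """
    np.random.seed(seed)
    n_loci = thetas.shape[0]
    group_of = np.empty(n_demes, dtype=np.int64)
    for d in range(n_demes):
        group_of[d] = d // demes_per_group
    n_groups = group_of[n_demes - 1] + 1
    deme_b = demes_per_group if n_groups > 1 else 1
    num = np.empty(n_loci)
    den = np.empty(n_loci)
    he = np.empty(n_loci)
    states = np.empty(sample_a + sample_b, dtype=np.int64)
    for l in range(n_loci):
        _sim_locus(sample_a, sample_b, deme_b, n_demes, group_of, rate_w,
                   rate_b, thetas[l], n_states, p_smm, geom_p, states)
        a, b, h = _haploid_theta_components(states, sample_a, n_states)
        num[l] = a
        den[l] = b
        he[l] = h
    return num, den, he


@njit(cache=True)
def sim_single_pop_batch(seed: int, n_loci: int, n_genes: int, theta: float,
                         n_states: int, p_smm: float, geom_p: float):
    """Equilibrium single-deme loci; returns (unbiased He, allele count)."""
    np.random.seed(seed)
    group_of = np.zeros(1, dtype=np.int64)
    het = np.empty(n_loci)
    k_out = np.empty(n_loci, dtype=np.int64)
    states = np.empty(n_genes, dtype=np.int64)
    for l in range(n_loci):
        _sim_locus(n_genes, 0, 0, 1, group_of, 0.0, 0.0, theta, n_states,
                   p_smm, geom_p, states)
        sum_p2 = 0.0
        k = 0
        for a in range(n_states):
            c = 0
            for i in range(n_genes):
                if states[i] == a:
                    c += 1
            if c > 0:
                k += 1
                p = c / n_genes
                sum_p2 += p * p
        het[l] = n_genes / (n_genes - 1.0) * (1.0 - sum_p2)
        k_out[l] = k
    return het, k_out
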