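"""Divergent-selection scan between two predefined groups.

Four complementary neutrality tests are applied per locus and a consensus
outlier is a locus flagged by at least two of them:

1. Ewens-Watterson homozygosity test within each group, with the null
   distribution of F = sum p^2 simulated from the Ewens sampling formula
   conditional on the observed sample size and allele count; the flag uses
   the standardized heterozygosity deviation (Dh/sd < -2.5 and p < 0.05).
2. ln RH: the log ratio of variability-derived theta estimates between the
   two groups, standardized across loci; |z| > 1.96 flags a locus (a
   one-sided ``z > 1.96`` mode is also available).
3. An FDIST-style scan: the joint null distribution of (He, FST) is built
   by coalescent simulation of a finite island model with migration tuned
   so the simulated mean FST matches the observed trimmed mean; loci above
   the conditional 0.95 FST quantile are flagged.
4. The same machinery under a hierarchical island model (two groups of
   demes, more migration within than between groups).

Both scans compare haploid-sample Weir-Cockerham theta between the two
groups (allele copies pooled per group), which is appropriate for highly
selfing, nearly fully homozygous material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._coalescent import sim_island_batch
from .genotypes import MISSING, GenotypeMatrix, LinkageMap, allele_frequencies
from .diversity import unbiased_gene_diversity


# ---------------------------------------------------------------------------
# balanced subset selection


def total_allele_count(gm: GenotypeMatrix, individuals: list[str]) -> int:
    """Distinct alleles summed over loci among the given individuals."""
    sub = gm.subset(individuals=individuals)
    total = 0
    for j in range(sub.n_loci):
        col = sub.calls[:, j, :]
        total += int(np.unique(col[col != MISSING]).size)
    return total


def select_balanced_subset(gm: GenotypeMatrix, pool: list[str], size: int,
                           n_candidate_sets: int = 100, seed: int = 0) -> list[str]:
    """A random subset whose allele count is closest to the average allele
    count over ``n_candidate_sets`` random subsets of the same size (ties
    resolved in draw order)."""
    if size > len(pool):
        raise ValueError("subset size exceeds pool size")
    rng = np.random.default_rng(seed)
    candidates = []
    counts = []
    for _ in range(n_candidate_sets):
        pick = list(rng.choice(pool, size=size, replace=False))
        candidates.append(pick)
        counts.append(total_allele_count(gm, pick))
    mean = float(np.mean(counts))
    best = int(np.argmin([abs(c - mean) for c in counts]))
    return candidates[best]


# ---------------------------------------------------------------------------
# Ewens-Watterson test


def _ewens_theta_for_k(n: int, k: int) -> float:
    """theta such that the expected allele count of an Ewens sample of n
    gene copies equals k."""
    def expected_k(theta):
        i = np.arange(n)
        return float(np.sum(theta / (theta + i)))
    if k <= 1:
        return 1e-6
    if k >= n:
        return 1e6
    return brentq(lambda t: expected_k(t) - k, 1e-6, 1e6)


def _ewens_f_null(n: int, k: int, n_sim: int, rng: np.random.Generator,
                  max_batches: int = 400) -> np.ndarray:
    """Null F = sum p^2 values from Ewens samples conditioned on k alleles.

    Hoppe-urn construction vectorized across a batch; samples whose allele
    count is not k are rejected.
    """
    theta = _ewens_theta_for_k(n, k)
    out = []
    got = 0
    batch = max(2 * n_sim, 500)
    for _ in range(max_batches):
        labels = np.zeros((batch, n), dtype=np.int64)
        n_lab = np.ones(batch, dtype=np.int64)
        for i in range(1, n):
            new = rng.random(batch) < theta / (theta + i)
            src = rng.integers(0, i, size=batch)
            copied = labels[np.arange(batch), src]
            labels[:, i] = np.where(new, n_lab, copied)
            n_lab += new
        keep = n_lab == k
        if keep.any():
            sel = labels[keep]
            for row in sel:
                counts = np.bincount(row)
                p = counts[counts > 0] / n
                out.append(float(np.sum(p * p)))
                got += 1
                if got >= n_sim:
                    return np.asarray(out)
    if got == 0:
        raise RuntimeError(f"could not condition Ewens samples on k={k} at n={n}")
    return np.asarray(out)


@dataclass
class EWResult:
    f_obs: float
    p: float
    dh_sd: float
    significant: bool
    applicable: bool = True


def ew_test(counts: dict[int, int], n_sim: int = 1000, seed: int = 0,
            dh_threshold: float = -2.5, alpha: float = 0.05,
            f_null: np.ndarray | None = None) -> EWResult:
    """Ewens-Watterson homozygosity test for one (group, locus) sample.

    ``counts`` maps allele -> copy count.  Monomorphic or tiny samples are
    inapplicable and neutral by default.  p is the two-tailed rank of
    F_obs in the conditional null; the flag additionally requires the
    standardized heterozygosity deficit Dh/sd below ``dh_threshold``.
    A precomputed conditional null sample may be passed via ``f_null``
    (the null depends only on n and k, so it can be shared across loci).
    """
    n = sum(counts.values())
    k = len(counts)
    if n < 5 or k < 2:
        return EWResult(float("nan"), float("nan"), float("nan"), False, applicable=False)
    p_vec = np.array([c / n for c in counts.values()])
    f_obs = float(np.sum(p_vec * p_vec))
    if f_null is None:
        rng = np.random.default_rng(seed)
        f_null = _ewens_f_null(n, k, n_sim, rng)
    lo = float((f_null <= f_obs + 1e-12).mean())
    hi = float((f_null >= f_obs - 1e-12).mean())
    p = min(1.0, 2.0 * min(lo, hi))
    h_null = 1.0 - f_null
    sd = float(h_null.std(ddof=1))
    dh_sd = float(((1.0 - f_obs) - h_null.mean()) / sd) if sd > 0 else float("nan")
    sig = bool(not np.isnan(dh_sd) and dh_sd < dh_threshold and p < alpha)
    return EWResult(f_obs, p, dh_sd, sig)


# ---------------------------------------------------------------------------
# ln RH


def lnrh_test(he_a: np.ndarray, he_b: np.ndarray, z_threshold: float = 1.96,
              two_sided: bool = True):
    """Standardized ln RH per locus from two vectors of gene diversities.

    RH is the ratio of theta estimates derived from He under stepwise
    mutation: theta = (1/(1-He))^2 - 1.  Loci where either He is >= 1 or
    where either theta estimate is 0 are excluded (NaN in the output).
    Needs >= 10 usable loci.  Returns (z, flags).
    """
    he_a = np.asarray(he_a, dtype=float)
    he_b = np.asarray(he_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (1.0 / (1.0 - he_a)) ** 2 - 1.0
        tb = (1.0 / (1.0 - he_b)) ** 2 - 1.0
    usable = (he_a < 1) & (he_b < 1) & (ta > 0) & (tb > 0) & ~np.isnan(ta) & ~np.isnan(tb)
    if usable.sum() < 10:
        raise ValueError("ln RH needs >= 10 loci variable in both groups")
    lnrh = np.full(he_a.shape, np.nan)
    lnrh[usable] = np.log(ta[usable] / tb[usable])
    mu = np.nanmean(lnrh)
    sd = np.nanstd(lnrh, ddof=1)
    if sd == 0:
        raise ValueError("ln RH standardization undefined: zero variance across loci")
    z = (lnrh - mu) / sd
    flags = (np.abs(z) > z_threshold) if two_sided else (z > z_threshold)
    flags = np.where(np.isnan(z), False, flags)
    return z, flags.astype(bool)


# ---------------------------------------------------------------------------
# FDIST-style island-model scans


def _observed_fst_he(gm: GenotypeMatrix, group_a: list[str], group_b: list[str]):
    """Per-locus haploid-sample theta components and pooled He.

    Each called homozygous individual contributes one haploid allele copy
    (heterozygotes are dropped, the "U" convention for selfing material), so
    the sampling units are statistically independent and comparable with the
    island-model coalescent null.  Returns (fst, he, num, den): per-locus
    theta = num/den; the multilocus estimate is sum(num)/sum(den).
    """
    sub = gm.subset(individuals=list(group_a) + list(group_b))
    na = len(group_a)
    fst = np.full(sub.n_loci, np.nan)
    he = np.full(sub.n_loci, np.nan)
    nums = np.full(sub.n_loci, np.nan)
    dens = np.full(sub.n_loci, np.nan)
    for j in range(sub.n_loci):
        col = sub.calls[:, j, :]
        hom = (col[:, 0] == col[:, 1]) & (col[:, 0] != MISSING)
        ca = col[:na, 0][hom[:na]]
        cb = col[na:, 0][hom[na:]]
        if ca.size < 2 or cb.size < 2:
            continue
        alleles = np.unique(np.concatenate([ca, cb]))
        he[j] = 1.0 - float(np.sum(((np.concatenate([ca, cb])[:, None] == alleles).mean(axis=0)) ** 2))
        if alleles.size < 2:
            fst[j] = np.nan
            continue
        n1, n2 = float(ca.size), float(cb.size)
        ntot = n1 + n2
        nc = ntot - (n1 * n1 + n2 * n2) / ntot
        num = den = 0.0
        for al in alleles:
            p1 = float((ca == al).mean())
            p2 = float((cb == al).mean())
            pbar = (n1 * p1 + n2 * p2) / ntot
            msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
            msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2.0)
            num += msp - msg
            den += msp + (nc - 1.0) * msg
        fst[j] = num / den if den > 0 else np.nan
        nums[j] = num
        dens[j] = den
    return fst, he, nums, dens


def _trimmed_multilocus_fst(fst: np.ndarray, num: np.ndarray, den: np.ndarray,
                            trim: float = 0.05) -> float:
    """Ratio-of-sums multilocus theta over loci whose per-locus theta is
    inside the central 1 - 2*trim quantile band (FDIST's trimmed target)."""
    ok = ~np.isnan(fst) & (den > 0)
    f, nu, de = fst[ok], num[ok], den[ok]
    if f.size == 0:
        return float("nan")
    lo, hi = np.quantile(f, [trim, 1 - trim])
    keep = (f >= lo) & (f <= hi)
    if not keep.any():
        keep = np.ones_like(f, dtype=bool)
    return float(nu[keep].sum() / de[keep].sum())


@dataclass
class FdistResult:
    fst: np.ndarray
    he: np.ndarray
    quantile: np.ndarray     # conditional quantile of each locus's FST
    flags: np.ndarray
    target_fst: float
    achieved_fst: float
    migration: float


def _conditional_quantiles(sim_fst, sim_he, obs_fst, obs_he, min_bin: int = 50):
    """Quantile position of each observed FST among simulated loci of
    similar He (equal-count He bins with >= min_bin simulations each)."""
    ok = ~np.isnan(sim_fst) & ~np.isnan(sim_he)
    sf, sh = sim_fst[ok], sim_he[ok]
    n_bins = max(1, min(len(sf) // min_bin, 40))
    edges = np.quantile(sh, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    q = np.full(obs_fst.shape, np.nan)
    for i in range(len(obs_fst)):
        if np.isnan(obs_fst[i]) or np.isnan(obs_he[i]):
            continue
        b = np.searchsorted(edges, obs_he[i], side="right") - 1
        b = min(max(b, 0), n_bins - 1)
        pool = sf[(sh >= edges[b]) & (sh < edges[b + 1])]
        if pool.size < 2:
            continue
        # mid-rank quantile position
        q[i] = ((pool < obs_fst[i]).sum() + 0.5 * (pool == obs_fst[i]).sum()) / pool.size
    return q


def _theta_smm_from_he(he: np.ndarray) -> np.ndarray:
    """Invert the stepwise-mutation equilibrium He = 1 - 1/sqrt(1+2*theta)."""
    he = np.clip(np.asarray(he, dtype=float), 0.0, 0.95)
    return 0.5 * ((1.0 / (1.0 - he)) ** 2 - 1.0)


def _run_island_scan(gm, group_a, group_b, n_sim, n_demes, demes_per_group,
                     within_between_ratio, seed, quantile=0.95,
                     fst_tol=0.01, he_tol=0.02, max_tune=20, n_states=30,
                     p_smm=1.0, geom_p=0.5):
    obs_fst, obs_he, obs_num, obs_den = _observed_fst_he(gm, group_a, group_b)
    defined = ~np.isnan(obs_fst)
    if defined.sum() < 20:
        raise ValueError("need >= 20 loci with defined FST to set the island-model target")
    target = _trimmed_multilocus_fst(obs_fst, obs_num, obs_den)
    target = max(target, 1e-3)
    n_groups = n_demes // demes_per_group
    # one haploid copy per individual (homozygous-line convention)
    sample_a = len(group_a)
    sample_b = len(group_b)
    rng = np.random.default_rng(seed)

    # per-locus mutation rates: resample the observed He spectrum (with
    # jitter) so the simulated loci cover the same diversity range, and
    # rescale by c so realized simulated He matches observed He on average
    he_pool = obs_he[defined & (obs_he > 0)]
    if he_pool.size == 0:
        raise ValueError("no polymorphic loci for the island-model null")
    he_obs_mean = float(he_pool.mean())

    def theta_draw(n):
        base = rng.choice(he_pool, size=n, replace=True)
        jitter = rng.uniform(0.7, 1.4, size=n)
        return np.clip(_theta_smm_from_he(base) * jitter, 1e-4, None)

    def simulate_batch(n, s):
        num, den, he = sim_island_batch(
            s, theta_scale * theta_draw(n), sample_a, sample_b, n_demes,
            demes_per_group, rate_w, rate_b, n_states, p_smm, geom_p)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(den > 0, num / den, np.nan)
        return fst, he, num, den

    m_total = max(1.0 / target - 1.0, 1e-3)  # infinite-island initial guess
    theta_scale = 1.0
    achieved = np.nan
    rate_w = rate_b = 0.0
    tune_n = max(n_sim // 10, 500)
    for it in range(max_tune):
        if n_groups == 1:
            rate_w, rate_b = m_total, 0.0
        else:
            rate_b = m_total / (1.0 + within_between_ratio)
            rate_w = m_total - rate_b
        fst_sim, he_sim, num_sim, den_sim = simulate_batch(tune_n, int(rng.integers(0, 2**31 - 1)))
        achieved = _trimmed_multilocus_fst(fst_sim, num_sim, den_sim)
        he_sim_mean = float(he_sim[~np.isnan(he_sim)].mean())
        if abs(achieved - target) <= fst_tol and abs(he_sim_mean - he_obs_mean) <= he_tol:
            break
        achieved = max(achieved, 1e-4)
        m_total *= (1.0 / target - 1.0) / max(1.0 / achieved - 1.0, 1e-6)
        m_total = min(max(m_total, 1e-4), 1e5)
        # pull the simulated diversity toward the observed spectrum
        ratio = _theta_smm_from_he(np.array([he_obs_mean]))[0] / max(
            _theta_smm_from_he(np.array([he_sim_mean]))[0], 1e-4)
        theta_scale = min(max(theta_scale * np.clip(ratio, 0.5, 2.0), 1e-3), 1e3)
    else:
        raise RuntimeError(
            f"island-model FST tuning failed: target {target:.4f}, achieved {achieved:.4f}")

    fst_sim, he_sim, num_sim, den_sim = simulate_batch(n_sim, int(rng.integers(0, 2**31 - 1)))
    q = _conditional_quantiles(fst_sim, he_sim, obs_fst, obs_he)
    flags = np.where(np.isnan(q), False, q > quantile)
    return FdistResult(obs_fst, obs_he, q, flags.astype(bool), target,
                       float(_trimmed_multilocus_fst(fst_sim, num_sim, den_sim)), m_total)


def fdist_scan(gm: GenotypeMatrix, group_a: list[str], group_b: list[str],
               n_sim: int = 20000, demes: int = 100, seed: int = 0,
               quantile: float = 0.95) -> FdistResult:
    """FDIST-style outlier scan under a plain island model.

    Coalescent samples of two demes from a ``demes``-island model, stepwise
    mutation capped at 30 allele states, migration tuned so the simulated
    trimmed-mean FST matches the observed one; per-locus conditional
    quantiles of FST given He.
    """
    return _run_island_scan(gm, group_a, group_b, n_sim, demes, demes, 1.0,
                            seed, quantile)


def hierarchical_scan(gm: GenotypeMatrix, group_a: list[str], group_b: list[str],
                      k_within: int = 5, n_sim: int = 20000, seed: int = 0,
                      within_between_ratio: float = 10.0,
                      quantile: float = 0.95) -> FdistResult:
    """Outlier scan under a hierarchical island model: two groups of
    ``k_within`` demes, within-group migration ``within_between_ratio``
    times the between-group rate."""
    return _run_island_scan(gm, group_a, group_b, n_sim, 2 * k_within, k_within,
                            within_between_ratio, seed, quantile)


# ---------------------------------------------------------------------------
# consensus + report


def consensus_outliers(flags: np.ndarray, min_tests: int = 2) -> np.ndarray:
    """Consensus call: flagged by at least ``min_tests`` of the per-test
    boolean columns (loci x tests)."""
    flags = np.asarray(flags, dtype=bool)
    return flags.sum(axis=1) >= min_tests


def outlier_report(gm: GenotypeMatrix, group_a: list[str], group_b: list[str],
                   lmap: LinkageMap | None = None, n_sim: int = 20000,
                   ew_sims: int = 1000, seed: int = 0, k_within: int = 5,
                   demes: int = 100) -> pd.DataFrame:
    """Run all four tests and assemble the per-locus outlier table."""
    rng = np.random.default_rng(seed)
    grouping = {i: "A" for i in group_a} | {i: "B" for i in group_b}
    sub = gm.subset(individuals=list(group_a) + list(group_b))
    freqs = allele_frequencies(sub, grouping)

    # per-group He for ln RH, and EW within the combined sample per group
    he_a, he_b = [], []
    ew_rows = []
    ew_null_cache: dict[tuple[int, int], np.ndarray] = {}
    for locus in sub.loci:
        vals = {}
        for gname in ("A", "B"):
            key = (gname, locus)
            if key in freqs.undefined or freqs.n_genes[key] < 2:
                vals[gname] = np.nan
            else:
                vals[gname] = unbiased_gene_diversity(freqs.freqs[key], freqs.n_genes[key])
        he_a.append(vals["A"])
        he_b.append(vals["B"])
        # EW on each group; the locus-level flag is significance in either
        res = []
        for gname in ("A", "B"):
            key = (gname, locus)
            if key in freqs.undefined:
                res.append(EWResult(np.nan, np.nan, np.nan, False, applicable=False))
                continue
            n = freqs.n_genes[key]
            counts = {a: int(round(f * n)) for a, f in freqs.freqs[key].items()}
            nk = (n, len(counts))
            if len(counts) >= 2 and n >= 5 and nk not in ew_null_cache:
                ew_null_cache[nk] = _ewens_f_null(n, len(counts), ew_sims,
                                                  np.random.default_rng(int(rng.integers(0, 2**31 - 1))))
            res.append(ew_test(counts, n_sim=ew_sims, f_null=ew_null_cache.get(nk)))
        ew_rows.append(res)

    he_a = np.asarray(he_a)
    he_b = np.asarray(he_b)
    lnrh_z, lnrh_flags = lnrh_test(he_a, he_b)
    fd = fdist_scan(sub, group_a, group_b, n_sim=n_sim, demes=demes,
                    seed=int(rng.integers(0, 2**31 - 1)))
    hi = hierarchical_scan(sub, group_a, group_b, k_within=k_within, n_sim=n_sim,
                           seed=int(rng.integers(0, 2**31 - 1)))

    rows = []
    for j, locus in enumerate(sub.loci):
        ew_sig = ew_rows[j][0].significant or ew_rows[j][1].significant
        dh = np.nanmin([ew_rows[j][0].dh_sd, ew_rows[j][1].dh_sd]) if not all(
            np.isnan([ew_rows[j][0].dh_sd, ew_rows[j][1].dh_sd])) else np.nan
        per_test = [bool(ew_sig), bool(lnrh_flags[j]), bool(fd.flags[j]), bool(hi.flags[j])]
        rows.append({
            "locus": locus,
            "linkage_group": lmap.linkage_group(locus) if lmap and locus in lmap else None,
            "ew_dh_sd": dh,
            "ew_significant": per_test[0],
            "lnrh_z": lnrh_z[j],
            "lnrh_significant": per_test[1],
            "fdist_fst": fd.fst[j],
            "fdist_he": fd.he[j],
            "fdist_quantile": fd.quantile[j],
            "fdist_significant": per_test[2],
            "hier_quantile": hi.quantile[j],
            "hier_significant": per_test[3],
            "n_significant": int(sum(per_test)),
            "consensus_outlier": sum(per_test) >= 2,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# candidate-window arithmetic


@dataclass
class CandidateWindow:
    window_kb: float
    mode: str            # "ratio", "decay", "fallback"
    warning: str | None = None


def candidate_window(outlier: str, neighbor: str, r2: float, lmap: LinkageMap,
                     scaffolds: dict[str, tuple[str, float]],
                     decay_span_cm: float | None = None,
                     fallback_kb: float = 10.0) -> CandidateWindow:
    """Physical search window around an outlier locus.

    Same scaffold and r² > 0.4: window = (|bp difference| / |cM difference|)
    x cM span (the local kb/cM ratio times the genetic distance).  Different
    scaffolds or r² < 0.2: fixed ±``fallback_kb`` around the outlier.
    Intermediate LD (0.2 <= r² <= 0.4): the ratio times the map distance at
    which group LD decays to 0.4 (``decay_span_cm``, from the decay fit).
    """
    for marker in (outlier, neighbor):
        if marker not in lmap:
            raise KeyError(f"marker {marker!r} is not on the linkage map")
    d_cm = abs(lmap.position(outlier) - lmap.position(neighbor))
    same_scaffold = (
        outlier in scaffolds and neighbor in scaffolds
        and scaffolds[outlier][0] == scaffolds[neighbor][0]
    )
    if not same_scaffold or r2 < 0.2:
        return CandidateWindow(2 * fallback_kb, "fallback")
    if d_cm == 0:
        return CandidateWindow(2 * fallback_kb, "fallback",
                               warning="zero cM span on shared scaffold; kb/cM ratio undefined")
    ratio_kb_per_cm = abs(scaffolds[outlier][1] - scaffolds[neighbor][1]) / 1000.0 / d_cm
    if r2 > 0.4:
        return CandidateWindow(ratio_kb_per_cm * d_cm, "ratio")
    if decay_span_cm is None:
        raise ValueError("moderate LD window needs decay_span_cm from the LD decay fit")
    return CandidateWindow(ratio_kb_per_cm * decay_span_cm, "decay")
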