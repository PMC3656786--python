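"""Forward-in-time simulator of structured, selfing, SSR-genotyped populations.

Wright-Fisher demes exchange migrants under an island model (optionally
hierarchical: demes belong to groups with separate within- and between-group
migration rates).  Reproduction is selfing with probability ``selfing_rate``,
otherwise random outcrossing within the deme.  Gametes recombine along a
multi-linkage-group cM map (Haldane, no interference).  Microsatellite
mutation is stepwise (SMM) or two-phase (TPM: single steps with probability
``p_smm``, otherwise a geometric multi-step jump); alleles are fragment
sizes in bp moving by one repeat unit per step.  Null alleles arise as
mutations to the NULL state; missing data is applied uniformly at sampling.

The generator doubles as the test substrate for every analysis module, so
it keeps an audit trail (:class:`SimTruth`): realized allele counts, the
realized FST trajectory, optional pedigree kinship of the sampled
individuals, and the fixation status of sweep loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, NULL, GenotypeMatrix, LinkageMap


@dataclass
class Sweep:
    """Divergent selection for carriers of one allele, in one deme group.

    When ``allele`` is left unset it is resolved at the start generation as
    the allele whose frequency advantage inside the swept group (frequency
    there minus frequency elsewhere) is largest -- the locally favored
    variant, as expected under divergent selection between groups.
    """

    locus: int                  # locus index
    group: int                  # deme group whose demes experience selection
    start_generation: int
    s: float                    # fitness advantage of carriers
    allele: int | None = None   # bp size
    divergent: bool = True      # disfavor carriers (1/(1+s)) outside the group


@dataclass
class SimConfig:
    seed: int = 0
    n_demes: int = 2
    deme_size: int = 100
    migration_rate: float = 0.01        # per-individual per-generation
    selfing_rate: float = 0.98
    n_generations: int = 100
    mutation_model: str = "SMM"         # "SMM" or "TPM"
    p_smm: float = 0.70                 # TPM single-step probability
    tpm_variance: float = 30.0          # TPM multi-step variance (geometric)
    mutation_rate: float = 5e-4
    n_loci: int = 100
    n_linkage_groups: int = 15
    lg_length_cm: float = 100.0
    founder_k0: int = 8                 # founder alleles per locus
    founder_concentration: float = 1.0  # Dirichlet concentration
    step_bp: int = 2                    # repeat-unit size
    sweeps: list[Sweep] = field(default_factory=list)
    sample_size: int = 30               # diploids sampled per deme
    missing_rate: float = 0.0
    null_allele_rate: float = 0.0
    # hierarchical structure: deme -> group; None = plain island model
    deme_groups: list[int] | None = None
    migration_rate_between: float | None = None  # between-group rate (hierarchical)
    track_kinship: bool = False
    fst_track_loci: int = 50            # loci used for the per-generation FST trace

    def validate(self) -> None:
        for name in ("migration_rate", "selfing_rate", "mutation_rate",
                     "missing_rate", "null_allele_rate", "p_smm"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.mutation_model not in ("SMM", "TPM"):
            raise ValueError(f"unknown mutation model {self.mutation_model!r}")
        if self.sample_size > self.deme_size:
            raise ValueError("sample_size exceeds deme_size")
        if self.deme_groups is not None and len(self.deme_groups) != self.n_demes:
            raise ValueError("deme_groups must list one group per deme")
        for sw in self.sweeps:
            if not (0 <= sw.locus < self.n_loci):
                raise ValueError(f"sweep locus {sw.locus} outside 0..{self.n_loci - 1}")


@dataclass
class SimTruth:
    """Generator bookkeeping used as an oracle by tests."""

    realized_allele_counts: dict[str, int]
    fst_trajectory: np.ndarray            # per generation, multi-locus Nei GST
    per_locus_fst_final: np.ndarray       # per locus, deme-level GST at the end
    sweep_fixation: list[dict]
    kinship: np.ndarray | None = None     # pedigree coancestry of the sample
    realized_he: np.ndarray | None = None  # per-locus pooled gene diversity


def _wc_fst_census(geno: np.ndarray, deme: np.ndarray, loci: np.ndarray) -> np.ndarray:
    """Per-locus Weir-Cockerham theta over demes on the full census of gene
    copies (NaN where monomorphic), so the record is directly comparable
    with the package's sample-based theta estimators."""
    demes = np.unique(deme)
    r = len(demes)
    out = np.full(len(loci), np.nan)
    for k, j in enumerate(loci):
        col = geno[:, j, :]
        alleles = np.unique(col)
        if alleles.size < 2:
            continue
        n_i = np.array([2.0 * (deme == d).sum() for d in demes])
        ntot = n_i.sum()
        if r < 2 or ntot < 4:
            continue
        nc = (ntot - (n_i ** 2).sum() / ntot) / (r - 1)
        num = den = 0.0
        for a in alleles:
            p_i = np.array([(col[deme == d] == a).mean() for d in demes])
            pbar = (n_i * p_i).sum() / ntot
            msp = (n_i * (p_i - pbar) ** 2).sum() / (r - 1)
            msg = (n_i * p_i * (1 - p_i)).sum() / (ntot - r)
            num += msp - msg
            den += msp + (nc - 1.0) * msg
        out[k] = num / den if den > 0 else np.nan
    return out


def simulate(cfg: SimConfig):
    """Run the forward simulation.

    Returns ``(GenotypeMatrix, LinkageMap, grouping, SimTruth)``; fully
    reproducible from ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_demes * cfg.deme_size
    m = cfg.n_loci

    # map: loci spread uniformly over linkage groups
    lg_of = np.sort(rng.integers(0, cfg.n_linkage_groups, size=m))
    pos = np.empty(m)
    for lg in range(cfg.n_linkage_groups):
        k = int((lg_of == lg).sum())
        pos[lg_of == lg] = np.sort(rng.uniform(0, cfg.lg_length_cm, size=k))
    loci_names = [f"L{j:04d}" for j in range(m)]
    lmap = LinkageMap({loci_names[j]: (f"LG{lg_of[j] + 1}", float(pos[j])) for j in range(m)})

    # per-locus switch probabilities between adjacent loci (Haldane); a fresh
    # 0.5 draw at each linkage-group start makes chromosomes independent
    r_vec = np.full(m, 0.5)
    for j in range(1, m):
        if lg_of[j] == lg_of[j - 1]:
            d = pos[j] - pos[j - 1]
            r_vec[j] = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))

    # founders: per-locus allele ladders with Dirichlet frequencies
    base = 100 + 10 * rng.integers(0, 20, size=m)
    founder_sizes = base[:, None] + cfg.step_bp * np.arange(cfg.founder_k0)[None, :]
    founder_freq = rng.dirichlet([cfg.founder_concentration] * cfg.founder_k0, size=m)
    geno = np.empty((n_total, m, 2), dtype=np.int32)
    for j in range(m):
        geno[:, j, :] = rng.choice(founder_sizes[j], size=(n_total, 2), p=founder_freq[j])
    deme = np.repeat(np.arange(cfg.n_demes), cfg.deme_size)
    groups = np.asarray(cfg.deme_groups) if cfg.deme_groups is not None else np.zeros(cfg.n_demes, dtype=int)

    # sweep target alleles resolved lazily at each sweep's start generation
    sweeps = [Sweep(**vars(sw)) if not isinstance(sw, Sweep) else sw for sw in cfg.sweeps]

    track = min(cfg.fst_track_loci, m)
    track_loci = rng.choice(m, size=track, replace=False) if track < m else np.arange(m)

    def mean_fst() -> float:
        vals = _wc_fst_census(geno, deme, track_loci)
        ok = ~np.isnan(vals)
        return float(vals[ok].mean()) if ok.any() else float("nan")

    fst_traj = np.empty(cfg.n_generations + 1)
    fst_traj[0] = mean_fst()

    kin = np.zeros((n_total, n_total)) if cfg.track_kinship else None
    if kin is not None:
        np.fill_diagonal(kin, 0.5)

    def make_gametes(parents: np.ndarray) -> np.ndarray:
        n = len(parents)
        sw = rng.random((n, m)) < r_vec[None, :]
        h = np.bitwise_xor.accumulate(sw.astype(np.int8), axis=1)
        return geno[parents[:, None], np.arange(m)[None, :], h]

    def mutate(gam: np.ndarray) -> None:
        mask = (rng.random(gam.shape) < cfg.mutation_rate) & (gam != NULL)
        idx = np.nonzero(mask)
        k = idx[0].size
        if k:
            if cfg.mutation_model == "SMM":
                steps = np.ones(k, dtype=np.int64)
            else:
                # geometric jump size with the configured variance
                p_geom = ((np.sqrt(1.0 + 4.0 * cfg.tpm_variance) - 1.0) / (2.0 * cfg.tpm_variance))
                multi = rng.random(k) >= cfg.p_smm
                steps = np.ones(k, dtype=np.int64)
                steps[multi] = rng.geometric(p_geom, size=int(multi.sum()))
            sign = rng.choice([-1, 1], size=k)
            gam[idx] = np.maximum(gam[idx] + sign * steps * cfg.step_bp, 10)
        if cfg.null_allele_rate > 0:
            nmask = rng.random(gam.shape) < cfg.null_allele_rate
            gam[nmask] = NULL

    for gen in range(cfg.n_generations):
        # fitness from active sweeps
        w = np.ones(n_total)
        for swp in sweeps:
            if gen == swp.start_generation and swp.allele is None:
                in_group = np.isin(deme, np.nonzero(groups == swp.group)[0])
                col = geno[:, swp.locus, :]
                vals = np.unique(col[in_group])
                fin = np.array([(col[in_group] == v).mean() for v in vals])
                if in_group.all():
                    swp.allele = int(vals[np.argmax(fin)])
                else:
                    fout = np.array([(col[~in_group] == v).mean() for v in vals])
                    swp.allele = int(vals[np.argmax(fin - fout)])
            if gen >= swp.start_generation and swp.allele is not None:
                carriers = (geno[:, swp.locus, :] == swp.allele).any(axis=1)
                in_group = np.isin(deme, np.nonzero(groups == swp.group)[0])
                w[carriers & in_group] *= 1.0 + swp.s
                if swp.divergent and not in_group.all():
                    w[carriers & ~in_group] /= 1.0 + swp.s

        # migration: source deme of each offspring slot
        src = deme.copy()
        u = rng.random(n_total)
        if cfg.deme_groups is not None and cfg.migration_rate_between is not None:
            m_w, m_b = cfg.migration_rate, cfg.migration_rate_between
            for i in np.nonzero(u < m_w + m_b)[0]:
                d0 = deme[i]
                if u[i] < m_w:
                    cand = np.nonzero((groups == groups[d0]) & (np.arange(cfg.n_demes) != d0))[0]
                else:
                    cand = np.nonzero(groups != groups[d0])[0]
                if cand.size:
                    src[i] = rng.choice(cand)
        else:
            mig = np.nonzero(u < cfg.migration_rate)[0]
            for i in mig:
                cand = np.delete(np.arange(cfg.n_demes), deme[i])
                if cand.size:
                    src[i] = rng.choice(cand)

        mothers = np.empty(n_total, dtype=np.int64)
        fathers = np.empty(n_total, dtype=np.int64)
        selfed = rng.random(n_total) < cfg.selfing_rate
        for d in range(cfg.n_demes):
            res = np.nonzero(deme == d)[0]
            slots = np.nonzero(src == d)[0]
            if slots.size == 0:
                continue
            p = w[res] / w[res].sum()
            mothers[slots] = rng.choice(res, size=slots.size, p=p)
            fathers[slots] = rng.choice(res, size=slots.size, p=p)
        fathers[selfed] = mothers[selfed]

        g1 = make_gametes(mothers)
        g2 = make_gametes(fathers)
        mutate(g1)
        mutate(g2)
        geno = np.stack([g1, g2], axis=2)

        if kin is not None:
            cross = 0.25 * (kin[mothers[:, None], mothers[None, :]]
                            + kin[mothers[:, None], fathers[None, :]]
                            + kin[fathers[:, None], mothers[None, :]]
                            + kin[fathers[:, None], fathers[None, :]])
            self_f = kin[mothers, fathers]
            np.fill_diagonal(cross, 0.5 * (1.0 + self_f))
            kin = cross

        fst_traj[gen + 1] = mean_fst()

    # sample individuals per deme
    sample_idx = np.concatenate([
        rng.choice(np.nonzero(deme == d)[0], size=cfg.sample_size, replace=False)
        for d in range(cfg.n_demes)
    ])
    calls = geno[sample_idx].copy()
    if cfg.missing_rate > 0:
        miss = rng.random((calls.shape[0], m)) < cfg.missing_rate
        calls[miss] = MISSING

    individuals = [f"ind{t:04d}" for t in range(len(sample_idx))]
    grouping = {individuals[t]: f"deme{deme[sample_idx[t]] + 1}" for t in range(len(sample_idx))}
    gm = GenotypeMatrix(individuals, loci_names, calls, dict(grouping))

    # truth bookkeeping on the final full population
    allele_counts = {loci_names[j]: int(np.unique(geno[:, j, :]).size) for j in range(m)}
    he = np.empty(m)
    for j in range(m):
        vals, cnt = np.unique(geno[:, j, :], return_counts=True)
        p = cnt / cnt.sum()
        he[j] = 1.0 - float((p ** 2).sum())
    sweep_status = []
    for swp in sweeps:
        in_group = np.isin(deme, np.nonzero(groups == swp.group)[0])
        freq = float((geno[in_group, swp.locus, :] == swp.allele).mean()) if swp.allele is not None else 0.0
        sweep_status.append({"locus": loci_names[swp.locus], "allele": swp.allele,
                             "group": swp.group, "final_frequency": freq,
                             "fixed": freq >= 0.99})
    truth = SimTruth(
        realized_allele_counts=allele_counts,
        fst_trajectory=fst_traj,
        per_locus_fst_final=_wc_fst_census(geno, deme, np.arange(m)),
        sweep_fixation=sweep_status,
        kinship=kin[np.ix_(sample_idx, sample_idx)] if kin is not None else None,
        realized_he=he,
    )
    return gm, lmap, grouping, truth


def engineer_sweeps(gm: GenotypeMatrix, group_a: list[str], loci: list[str],
                    seed: int = 0, fix_prob: float = 0.97) -> GenotypeMatrix:
    """Plant completed divergent sweeps onto a (neutral) genotype matrix.

    At each listed locus a novel allele (one repeat unit beyond the largest
    existing size) is made near-fixed in ``group_a``: each group-A individual
    becomes homozygous for it with probability ``fix_prob``; all other
    individuals are untouched.  This isolates the per-locus footprint of a
    finished sweep from the genome-wide isolation that mechanistic
    multi-locus divergent selection causes in a highly selfing population.
    """
    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    ia = [gm.individual_index(i) for i in group_a]
    for locus in loci:
        j = gm.locus_index(locus)
        col = calls[:, j, :]
        novel = int(col.max()) + 2
        hit = rng.random(len(ia)) < fix_prob
        for t, i in enumerate(ia):
            if hit[t]:
                calls[i, j, :] = novel
    return GenotypeMatrix(list(gm.individuals), list(gm.loci), calls,
                          dict(gm.populations) if gm.populations else None)


def flaxlike_preset(seed: int = 0, n_loci: int = 100, sweeps: list[Sweep] | None = None) -> SimConfig:
    """Conditions emulating a world core collection of a selfing SSR-typed crop.

    Two clusters of demes under hierarchical migration, selfing 0.98 (so
    observed heterozygosity lands near 0.02), two-phase microsatellite
    mutation, ~5 alleles per locus and mild structure (FST around 0.1),
    loci spread over 15 linkage groups.
    """
    return SimConfig(
        seed=seed,
        n_demes=6,
        deme_size=80,
        migration_rate=0.04,
        migration_rate_between=0.012,
        deme_groups=[0, 0, 0, 1, 1, 1],
        selfing_rate=0.98,
        n_generations=100,
        mutation_model="TPM",
        p_smm=0.70,
        tpm_variance=30.0,
        mutation_rate=1e-3,
        n_loci=n_loci,
        n_linkage_groups=15,
        lg_length_cm=100.0,
        founder_k0=8,
        founder_concentration=0.4,
        sample_size=20,
        missing_rate=0.01,
        null_allele_rate=0.001,
        sweeps=list(sweeps) if sweeps else [],
    )


def two_group_scan_config(seed: int, n_loci: int = 200,
                          sweeps: list[Sweep] | None = None) -> SimConfig:
    """Two groups of four demes with mild divergence (group FST below ~0.1),
    the study conditions for divergent-selection-scan experiments."""
    return SimConfig(
        seed=seed,
        n_demes=8,
        deme_size=50,
        deme_groups=[0, 0, 0, 0, 1, 1, 1, 1],
        migration_rate=0.08,
        migration_rate_between=0.02,
        selfing_rate=0.98,
        n_generations=60,
        mutation_model="TPM",
        mutation_rate=1e-3,
        n_loci=n_loci,
        founder_k0=6,
        sample_size=8,
        sweeps=list(sweeps) if sweeps else [],
    )


def two_deme_neutral_config(seed: int, n_loci: int = 500, sample_size: int = 50) -> SimConfig:
    """Neutral two-deme island model with SMM mutation, equal deme sizes."""
    return SimConfig(
        seed=seed,
        n_demes=2,
        deme_size=100,
        migration_rate=0.02,
        selfing_rate=0.98,
        n_generations=100,
        mutation_model="SMM",
        mutation_rate=1e-3,
        n_loci=n_loci,
        founder_k0=6,
        founder_concentration=1.0,
        sample_size=sample_size,
    )
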