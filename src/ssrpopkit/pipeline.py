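"""End-to-end orchestration of the core-collection analysis workflow.

Stage order mirrors the analysis a breeder's panel goes through: a
neutrality pre-filter, diversity statistics, relationship analyses
(neighbor joining, PCoA, admixture clustering), molecular coancestry,
linkage disequilibrium, the divergent-selection scan and the bottleneck
tests.  Every stage writes its artifact into the report directory, and a
machine-readable JSON log records seeds, parameters and the locus count
after each filter (locus counts can only decrease along the pipeline).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bottleneck as bn
from . import coancestry as co
from . import diversity as dv
from . import ld as ldmod
from . import phylogeny as ph
from . import popstructure as ps
from . import selection as sel
from .genotypes import GenotypeMatrix, LinkageMap, allele_frequencies, read_genotypes


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    genotype_path: str
    genotype_format: str = "csv"
    map_path: str | None = None
    out_dir: str = "report"
    seed: int = 0
    # neutrality pre-filter
    ew_prefilter: bool = True
    ew_alpha: float = 0.05
    ew_dh_threshold: float = -2.5
    ew_sims: int = 1000
    # thresholds from the standard workflow
    maf_min: float = 0.05
    ld_thin_r2: float = 0.4
    q_threshold: float = 0.70
    ld_alpha: float = 0.05
    ld_block_r2: float = 0.1
    # structure stage
    k_min: int = 1
    k_max: int = 6
    k_reps: int = 2
    burn_in: int = 200
    iters: int = 600
    # phylogeny
    bootstrap_reps: int = 100
    # scan stage: two population labels to contrast (None = skip)
    scan_groups: tuple[str, str] | None = None
    scan_sims: int = 4000
    bottleneck_sims: int = 300
    fst_permutations: int = 99

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "scan_groups" in raw and raw["scan_groups"] is not None:
            raw["scan_groups"] = tuple(raw["scan_groups"])
        return cls(**raw)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages; returns the report directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": cfg.seed, "parameters": {k: v for k, v in asdict(cfg).items()},
                 "stages": []}
    rng = np.random.default_rng(cfg.seed)

    def stage(name):
        def deco(fn):
            try:
                info = fn() or {}
            except Exception as e:  # halt with stage name, keep partial outputs
                log["stages"].append({"stage": name, "status": "failed", "error": str(e)})
                (out / "pipeline_log.json").write_text(json.dumps(log, indent=2, default=str))
                raise PipelineError(name, e) from e
            log["stages"].append({"stage": name, "status": "ok", **info})
            return info
        return deco

    state: dict = {}

    @stage("load")
    def _load():
        gm = read_genotypes(cfg.genotype_path, cfg.genotype_format)
        state["gm"] = gm
        state["grouping"] = gm.populations or {i: "pop1" for i in gm.individuals}
        state["lmap"] = LinkageMap.read_tsv(cfg.map_path) if cfg.map_path else None
        return {"individuals": gm.n_individuals, "loci": gm.n_loci}

    @stage("ew_prefilter")
    def _prefilter():
        gm = state["gm"]
        if not cfg.ew_prefilter:
            state["neutral_loci"] = list(gm.loci)
            return {"loci_kept": gm.n_loci, "skipped": True}
        freqs = allele_frequencies(gm, {i: "all" for i in gm.individuals})
        kept = []
        null_cache: dict[tuple[int, int], object] = {}
        for locus in gm.loci:
            key = ("all", locus)
            if key in freqs.undefined:
                continue
            n = freqs.n_genes[key]
            counts = {a: int(round(f * n)) for a, f in freqs.freqs[key].items()}
            nk = (n, len(counts))
            if len(counts) >= 2 and n >= 5 and nk not in null_cache:
                null_cache[nk] = sel._ewens_f_null(
                    n, len(counts), cfg.ew_sims,
                    np.random.default_rng(int(rng.integers(0, 2**31 - 1))))
            res = sel.ew_test(counts, n_sim=cfg.ew_sims, f_null=null_cache.get(nk),
                              dh_threshold=cfg.ew_dh_threshold, alpha=cfg.ew_alpha)
            if not res.significant:
                kept.append(locus)
        state["neutral_loci"] = kept
        return {"loci_in": gm.n_loci, "loci_kept": len(kept)}

    @stage("diversity")
    def _diversity():
        gm = state["gm"].subset(loci=state["neutral_loci"])
        table = dv.diversity_table(gm, state["grouping"])
        table.to_csv(out / "diversity.tsv", sep="\t", index=False)
        return {"loci_used": gm.n_loci}

    @stage("phylogeny")
    def _phylo():
        gm = state["gm"].subset(loci=state["neutral_loci"])
        tree = ph.bootstrap_support(gm, n_reps=cfg.bootstrap_reps,
                                    seed=int(rng.integers(0, 2**31 - 1)))
        (out / "nj_tree.nwk").write_text(tree.to_newick(with_support=True) + "\n")
        state["dm"] = ph.nei_minimum_distance_matrix(gm)
        return {"bootstrap_reps": cfg.bootstrap_reps}

    @stage("pcoa")
    def _pcoa():
        res = ps.pcoa(state["dm"], n_axes=2)
        df = pd.DataFrame(res.coordinates, columns=["axis1", "axis2"])
        df.insert(0, "id", res.labels)
        df.to_csv(out / "pcoa.tsv", sep="\t", index=False)
        return {"pct_variation": [float(x) for x in res.pct_variation]}

    @stage("structure")
    def _structure():
        gm = state["gm"].subset(loci=state["neutral_loci"])
        if state["lmap"] is not None:
            thinned = ps.thin_by_ld(gm, state["lmap"], r2_max=cfg.ld_thin_r2,
                                    maf_min=cfg.maf_min, seed=int(rng.integers(0, 2**31 - 1)))
        else:
            thinned = list(gm.loci)
        gm_thin = gm.subset(loci=thinned)
        scan: dict[int, list[float]] = {}
        best_q = {}
        for k in range(cfg.k_min, cfg.k_max + 1):
            scan[k] = []
            for rep in range(cfg.k_reps):
                q = ps.admixture_gibbs(gm_thin, k, burn_in=cfg.burn_in, iters=cfg.iters,
                                       seed=int(rng.integers(0, 2**31 - 1)))
                scan[k].append(q.ln_prob_data)
                best_q[(k, rep)] = q
        dk = ps.evanno_delta_k(scan) if len(scan) >= 3 else None
        if dk is not None:
            dk.to_csv(out / "evanno.tsv", sep="\t", index=False)
            interior = dk.dropna(subset=["delta_k"])
            k_opt = int(interior.loc[interior["delta_k"].idxmax(), "K"]) if len(interior) else cfg.k_min
        else:
            k_opt = cfg.k_min
        q = best_q[(k_opt, 0)]
        qdf = pd.DataFrame(q.q, columns=[f"Q{c + 1}" for c in range(k_opt)])
        qdf.insert(0, "id", q.individuals)
        qdf.to_csv(out / f"qmatrix_K{k_opt}.tsv", sep="\t", index=False)
        assign = ps.assign_groups(q, threshold=cfg.q_threshold)
        pd.Series(assign, name="group").rename_axis("id").to_csv(out / "assignments.tsv", sep="\t")
        state["assignments"] = assign
        state["loci_structure"] = thinned
        # pairwise FST between the a-priori populations
        if len(set(state["grouping"].values())) >= 2:
            fst = ps.pairwise_fst(gm, state["grouping"], n_perm=cfg.fst_permutations,
                                  seed=int(rng.integers(0, 2**31 - 1)))
            fst.to_csv(out / "pairwise_fst.tsv", sep="\t", index=False)
        return {"loci_in": gm.n_loci, "loci_after_thinning": len(thinned), "k_optimal": k_opt}

    @stage("coancestry")
    def _coan():
        cm = co.coancestry_matrix(state["gm"])  # all loci, as is conventional
        df = pd.DataFrame(cm.values, index=cm.individuals, columns=cm.individuals)
        df.to_csv(out / "coancestry.tsv", sep="\t")
        summ = co.group_coancestry_summary(cm, state["grouping"])
        with open(out / "coancestry_groups.tsv", "w") as fh:
            fh.write("kind\tgroup1\tgroup2\tmean_f\n")
            for g, v in summ["intra"].items():
                fh.write(f"intra\t{g}\t{g}\t{v:.6g}\n")
            for (g1, g2), v in summ["inter"].items():
                fh.write(f"inter\t{g1}\t{g2}\t{v:.6g}\n")
        return {"mean_offdiagonal": cm.mean_offdiagonal()}

    @stage("ld")
    def _ld():
        if state["lmap"] is None:
            return {"skipped": True}
        gm = state["gm"].subset(loci=state["neutral_loci"])
        ldr = ldmod.ld_table(gm, state["lmap"], seed=int(rng.integers(0, 2**31 - 1)), n_perm=99)
        ldr.pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
        summary = ldmod.ld_summary(ldr, alpha=cfg.ld_alpha)
        try:
            fit = ldmod.fit_decay(ldr, gm.n_individuals, threshold=cfg.ld_block_r2)
            summary["decay_rho_per_cM"] = fit.rho
            summary["block_cM"] = fit.distance_at_threshold
        except ValueError as e:
            summary["decay_error"] = str(e)
        pd.Series(summary).to_csv(out / "ld_summary.tsv", sep="\t", header=False)
        state["ld_summary"] = summary
        return {k: v for k, v in summary.items() if isinstance(v, (int, float))}

    @stage("selection_scan")
    def _scan():
        if cfg.scan_groups is None:
            return {"skipped": True}
        ga_label, gb_label = cfg.scan_groups
        group_a = [i for i, g in state["grouping"].items() if g == ga_label]
        pool_b = [i for i, g in state["grouping"].items() if g == gb_label]
        size = min(len(group_a), len(pool_b))
        group_b = sel.select_balanced_subset(state["gm"], pool_b, size,
                                             seed=int(rng.integers(0, 2**31 - 1)))
        report = sel.outlier_report(state["gm"], group_a, group_b, lmap=state["lmap"],
                                    n_sim=cfg.scan_sims, ew_sims=cfg.ew_sims,
                                    seed=int(rng.integers(0, 2**31 - 1)))
        report.to_csv(out / "outliers.tsv", sep="\t", index=False)
        state["scan_members"] = (group_a, group_b)
        return {"n_outliers": int(report["consensus_outlier"].sum()), "loci": len(report)}

    @stage("bottleneck")
    def _bottleneck():
        if cfg.scan_groups is None or "scan_members" not in state:
            return {"skipped": True}
        results = {}
        for name, members in zip(cfg.scan_groups, state["scan_members"]):
            res = bn.bottleneck_test(state["gm"], members, n_sim=cfg.bottleneck_sims,
                                     seed=int(rng.integers(0, 2**31 - 1)))
            res.per_locus.to_csv(out / f"bottleneck_{name}.tsv", sep="\t", index=False)
            results[name] = {"sign_test": res.sign_test, "mode_shift": res.mode_shift["verdict"]}
        (out / "bottleneck_summary.json").write_text(json.dumps(results, indent=2, default=str))
        return {name: r["mode_shift"] for name, r in results.items()}

    (out / "pipeline_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out
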