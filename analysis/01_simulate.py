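"""Generate the study panel: a flax-like core collection of selfing lines.

Forward-simulates six demes in two groups (fiber-like vs linseed-like)
under hierarchical island migration with two-phase microsatellite mutation,
selfing rate 0.98 and 100 SSR loci on a 15-linkage-group map, then plants
five completed divergent sweeps (novel allele near-fixed in the fiber-like
group) so the downstream scan has known true outliers.  Writes the panel,
the map, the group labels and the generator's truth record.
"""

import importlib.util
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
common = importlib.import_module("00_common")

import ssrpopkit as sk
from ssrpopkit.genotypes import write_genotypes
from ssrpopkit.simulate import engineer_sweeps

SEED = 2024
SWEEP_LOCI = ["L0005", "L0025", "L0045", "L0065", "L0085"]

common.DATA.mkdir(parents=True, exist_ok=True)

cfg = sk.flaxlike_preset(seed=SEED, n_loci=100)
gm, lmap, grouping, truth = sk.simulate(cfg)

# fiber-like group = demes 1-3; plant completed sweeps there
fiber = [i for i, g in grouping.items() if g in ("deme1", "deme2", "deme3")]
gm = engineer_sweeps(gm, fiber, SWEEP_LOCI, seed=SEED + 1)
# relabel demes with interpretable group names
relabel = {f"deme{d}": ("fiber" if d <= 3 else "linseed") for d in range(1, 7)}
gm.populations = {i: relabel[g] for i, g in grouping.items()}

write_genotypes(gm, common.DATA / "panel.csv", "csv")
write_genotypes(gm, common.DATA / "panel.gen", "genepop")
lmap.write_tsv(common.DATA / "map.tsv")

# synthetic scaffold coordinates for the candidate-window arithmetic:
# each mapped marker gets a scaffold shared with its nearest map neighbor
rng = np.random.default_rng(SEED + 2)
with open(common.DATA / "scaffolds.tsv", "w") as fh:
    fh.write("marker\tscaffold\tbp\n")
    for k, (marker, (lg, cm)) in enumerate(sorted(lmap.entries.items(), key=lambda kv: (kv[1][0], kv[1][1]))):
        scaffold = f"scaffold_{k // 2}"  # pairs of adjacent markers share a scaffold
        fh.write(f"{marker}\t{scaffold}\t{int(cm * rng.uniform(150, 400) * 1000)}\n")

summary = {
    "seed": SEED,
    "individuals": gm.n_individuals,
    "loci": gm.n_loci,
    "planted_outliers": SWEEP_LOCI,
    "mean_alleles_per_locus_population": float(np.mean(list(truth.realized_allele_counts.values()))),
    "realized_fst_final": float(truth.fst_trajectory[-1]),
}
(common.DATA / "truth.json").write_text(json.dumps(summary, indent=2))
print("wrote panel:", gm.n_individuals, "accessions x", gm.n_loci, "loci")
print("realized deme-level FST:", round(summary["realized_fst_final"], 3))
print("mean alleles/locus (full population):", round(summary["mean_alleles_per_locus_population"], 2))
print("planted outlier loci:", ", ".join(SWEEP_LOCI))
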