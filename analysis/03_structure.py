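"""Relationships and population structure of the panel.

Neighbor-joining tree (Nei minimum distance, locus bootstrap), PCoA,
LD-thinned admixture analysis over K = 1..6 with Evanno's delta-K,
Q >= 0.70 group assignment, and pairwise FST between the a-priori groups.
"""

import importlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
common = importlib.import_module("00_common")

from ssrpopkit import popstructure as ps
from ssrpopkit.phylogeny import bootstrap_support, nei_minimum_distance_matrix

gm, lmap, grouping = common.load_panel()
kept = json.loads((common.RESULTS / "neutral_loci.json").read_text())
neutral = gm.subset(loci=kept)

tree = bootstrap_support(neutral, n_reps=200, seed=31)
(common.RESULTS / "nj_tree.nwk").write_text(tree.to_newick(with_support=True) + "\n")
print("NJ tree written (200 locus bootstraps)")

dm = nei_minimum_distance_matrix(neutral)
pc = ps.pcoa(dm, n_axes=2)
df = pd.DataFrame(pc.coordinates, columns=["axis1", "axis2"])
df.insert(0, "id", pc.labels)
df["group"] = [grouping[i] for i in pc.labels]
df.to_csv(common.RESULTS / "pcoa.tsv", sep="\t", index=False)
print(f"PCoA axes explain {pc.pct_variation[0]:.1f}% + {pc.pct_variation[1]:.1f}% of variation")

thinned = ps.thin_by_ld(neutral, lmap, r2_max=0.4, maf_min=0.05, seed=32)
print(f"LD thinning for structure: {neutral.n_loci} -> {len(thinned)} loci")
gm_thin = neutral.subset(loci=thinned)

rng = np.random.default_rng(33)
scan = {}
qmats = {}
for k in range(1, 7):
    scan[k] = []
    for rep in range(3):
        q = ps.admixture_gibbs(gm_thin, k, burn_in=300, iters=900,
                               seed=int(rng.integers(0, 2**31 - 1)))
        scan[k].append(q.ln_prob_data)
        qmats[(k, rep)] = q
dk = ps.evanno_delta_k(scan)
dk.to_csv(common.RESULTS / "evanno.tsv", sep="\t", index=False)
interior = dk.dropna(subset=["delta_k"])
k_opt = int(interior.loc[interior["delta_k"].idxmax(), "K"])
print(f"Evanno delta-K maximal at K = {k_opt}")

q = qmats[(k_opt, 0)]
assign = ps.assign_groups(q, threshold=0.70)
pd.Series(assign, name="cluster").rename_axis("id").to_csv(common.RESULTS / "assignments.tsv", sep="\t")
n_adm = sum(1 for v in assign.values() if v == ps.ADMIXED)
print(f"{gm.n_individuals - n_adm} accessions assigned at Q >= 0.70; {n_adm} admixed")

fst = ps.pairwise_fst(neutral, grouping, n_perm=199, seed=34)
fst.to_csv(common.RESULTS / "pairwise_fst.tsv", sep="\t", index=False)
print(fst.round(4).to_string(index=False))
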