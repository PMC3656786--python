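"""Four-test divergent-selection scan between the fiber and linseed groups.

Balances the linseed sample to the fiber group size by the average-allele-
count criterion, runs the Ewens-Watterson, ln RH, FDIST island-model and
hierarchical island-model tests, calls consensus outliers (>= 2 of 4) and
computes candidate physical windows around each outlier from the scaffold
table and the group-level LD decay.
"""

import importlib
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
common = importlib.import_module("00_common")

from ssrpopkit import ld as ldm
from ssrpopkit import selection as sel
from ssrpopkit.genotypes import LinkageMap

gm, lmap, grouping = common.load_panel()
truth = json.loads((common.DATA / "truth.json").read_text())

fiber = [i for i, g in grouping.items() if g == "fiber"]
linseed_pool = [i for i, g in grouping.items() if g == "linseed"]
linseed = sel.select_balanced_subset(gm, linseed_pool, len(fiber), n_candidate_sets=100, seed=61)
print(f"groups: {len(fiber)} fiber vs {len(linseed)} balanced linseed "
      f"(pool of {len(linseed_pool)})")

report = sel.outlier_report(gm, fiber, linseed, lmap=lmap, n_sim=10000,
                            ew_sims=1000, seed=62, k_within=3)
report.to_csv(common.RESULTS / "outliers.tsv", sep="\t", index=False)
outliers = report[report["consensus_outlier"]]
planted = set(truth["planted_outliers"])
print(f"consensus outliers (>=2 of 4 tests): {len(outliers)} of {len(report)} loci")
print(f"planted sweeps recovered: {sum(l in planted for l in outliers['locus'])} of {len(planted)}")

# candidate windows: nearest mapped neighbor with its LD to the outlier
scaff = {}
for line in (common.DATA / "scaffolds.tsv").read_text().splitlines()[1:]:
    marker, scaffold, bp = line.split("\t")
    scaff[marker] = (scaffold, float(bp))

# group-level decay-to-0.4 span for moderate-LD windows
ldr = ldm.ld_table(gm.subset(individuals=fiber + linseed), lmap, seed=63, n_perm=0)
try:
    decay_span = ldm.fit_decay(ldr, len(fiber) + len(linseed), threshold=0.4).distance_at_threshold
except ValueError:
    decay_span = None

rows = []
for locus in outliers["locus"]:
    if locus not in lmap:
        continue
    lg = lmap.linkage_group(locus)
    neighbors = [l for l in gm.loci if l != locus and l in lmap and lmap.linkage_group(l) == lg]
    if not neighbors:
        continue
    nb = min(neighbors, key=lambda l: abs(lmap.position(l) - lmap.position(locus)))
    r2, _, _ = ldm.pair_r2(gm, locus, nb, n_perm=0)
    try:
        w = sel.candidate_window(locus, nb, 0.0 if pd.isna(r2) else r2, lmap, scaff,
                                 decay_span_cm=decay_span)
    except ValueError:
        continue
    rows.append({"outlier": locus, "neighbor": nb, "r2": r2,
                 "window_kb": w.window_kb, "mode": w.mode})
windows = pd.DataFrame(rows)
windows.to_csv(common.RESULTS / "candidate_windows.tsv", sep="\t", index=False)
if len(windows):
    print(windows.round(3).to_string(index=False))
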