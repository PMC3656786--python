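"""Molecular coancestry of all accession pairs.

Computes the identity-by-state kinship matrix over all loci (the usual
convention, independent of the neutrality filter), its distribution
histogram, and within/between-group means.
"""

import importlib
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
common = importlib.import_module("00_common")

from ssrpopkit.coancestry import coancestry_matrix, group_coancestry_summary

gm, lmap, grouping = common.load_panel()

cm = coancestry_matrix(gm)
pd.DataFrame(cm.values, index=cm.individuals, columns=cm.individuals).to_csv(
    common.RESULTS / "coancestry.tsv", sep="\t")
counts, edges = cm.histogram(bins=20)
pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "n_pairs": counts}).to_csv(
    common.RESULTS / "coancestry_hist.tsv", sep="\t", index=False)

print(f"mean pairwise coancestry: {cm.mean_offdiagonal():.3f}")
summ = group_coancestry_summary(cm, grouping)
for g, v in summ["intra"].items():
    print(f"intra-group f ({g}): {v:.3f}")
for (g1, g2), v in summ["inter"].items():
    print(f"inter-group f ({g1} vs {g2}): {v:.3f}")
with open(common.RESULTS / "coancestry_groups.tsv", "w") as fh:
    fh.write("kind\tgroup1\tgroup2\tmean_f\n")
    for g, v in summ["intra"].items():
        fh.write(f"intra\t{g}\t{g}\t{v:.6g}\n")
    for (g1, g2), v in summ["inter"].items():
        fh.write(f"inter\t{g1}\t{g2}\t{v:.6g}\n")
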