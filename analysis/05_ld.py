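"""Linkage disequilibrium: linked vs unlinked r², decay, block size.

Pairwise multiallelic r² on the neutral loci (heterozygotes treated as
missing, as appropriate for selfing lines), the 95th percentile of the
unlinked distribution, the drift-recombination decay fit and the map
distance at which expected r² falls to 0.1 (the LD-block scale), plus
block-width binned decay per group.
"""

import importlib
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
common = importlib.import_module("00_common")

from ssrpopkit import ld as ldm

gm, lmap, grouping = common.load_panel()
kept = json.loads((common.RESULTS / "neutral_loci.json").read_text())
neutral = gm.subset(loci=kept)

ldr = ldm.ld_table(neutral, lmap, seed=51, n_perm=199)
ldr.pairs.to_csv(common.RESULTS / "ld_pairs.tsv", sep="\t", index=False)
summary = ldm.ld_summary(ldr, alpha=0.05)
print(f"linked pairs: {summary['n_linked']}, unlinked: {summary['n_unlinked']}")
print(f"mean r2 linked {summary['mean_linked_r2']:.3f} vs unlinked {summary['mean_unlinked_r2']:.3f}")
print(f"95th percentile of unlinked r2: {summary['unlinked_p95']:.3f}")
print(f"pairs in significant LD (alpha 0.05): {summary['pct_significant']:.1f}%")

try:
    fit = ldm.fit_decay(ldr, neutral.n_individuals, threshold=0.1)
    summary["decay_rho_per_cM"] = fit.rho
    summary["block_cM"] = fit.distance_at_threshold
    print(f"decay fit: rho = {fit.rho:.4f} per cM; r2 crosses 0.1 at {fit.distance_at_threshold:.2f} cM"
          + (" (poor fit)" if fit.poor_fit else ""))
    block = fit.distance_at_threshold
    if 0 < block < float("inf"):
        binned = ldm.bin_decay(ldr, bin_width=block)
        binned.to_csv(common.RESULTS / "ld_decay_binned.tsv", sep="\t", index=False)
except ValueError as e:
    print("decay fit skipped:", e)

pd.Series(summary).to_csv(common.RESULTS / "ld_summary.tsv", sep="\t", header=False)
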