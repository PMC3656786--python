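"""Neutrality pre-filter and per-group diversity statistics.

Applies the Ewens-Watterson pre-filter to the panel, then computes the
standard diversity table (UHe, Ho, Na, rarefied richness and private
alleles, rare alleles, FIS, % polymorphic, PIC) per group and pooled.
"""

import importlib.util
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
common = __import__("00_common")

from ssrpopkit.diversity import diversity_table
from ssrpopkit.genotypes import allele_frequencies
from ssrpopkit.selection import _ewens_f_null, ew_test

gm, lmap, grouping = common.load_panel()

# Ewens-Watterson pre-filter on the pooled panel
freqs = allele_frequencies(gm, {i: "all" for i in gm.individuals})
kept = []
cache = {}
rng = np.random.default_rng(7)
for locus in gm.loci:
    key = ("all", locus)
    if key in freqs.undefined:
        continue
    n = freqs.n_genes[key]
    counts = {a: int(round(f * n)) for a, f in freqs.freqs[key].items()}
    nk = (n, len(counts))
    if len(counts) >= 2 and n >= 5 and nk not in cache:
        cache[nk] = _ewens_f_null(n, len(counts), 1000, np.random.default_rng(int(rng.integers(0, 2**31 - 1))))
    if not ew_test(counts, f_null=cache.get(nk)).significant:
        kept.append(locus)
print(f"EW pre-filter: {gm.n_loci} loci -> {len(kept)} retained as neutral")

neutral = gm.subset(loci=kept)
table = diversity_table(neutral, grouping, pooled_label="core collection")
table.to_csv(common.RESULTS / "diversity.tsv", sep="\t", index=False)
(common.RESULTS / "neutral_loci.json").write_text(json.dumps(kept))

pooled = table[table["population"] == "core collection"].iloc[0]
print(table.round(3).to_string(index=False))
print(f"\npooled: UHe={pooled.uhe:.3f} Ho={pooled.ho:.3f} FIS={pooled.fis:.3f} "
      f"Na={pooled.na} ({pooled.na / neutral.n_loci:.2f}/locus) PIC={pooled.pic:.3f}")
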