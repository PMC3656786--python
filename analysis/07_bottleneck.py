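"""Mutation-drift equilibrium checks on the fiber and linseed groups.

Runs the heterozygosity-excess sign test under the two-phase mutation model
and the allele-frequency mode-shift test on each group (bottlenecks can
masquerade as selection in the outlier scan, so this contextualizes 06).
"""

import importlib
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
common = importlib.import_module("00_common")

from ssrpopkit.bottleneck import bottleneck_test

gm, lmap, grouping = common.load_panel()

results = {}
for group in ("fiber", "linseed"):
    members = [i for i, g in grouping.items() if g == group]
    res = bottleneck_test(gm, members, p_smm=0.70, variance=30.0, n_sim=500, seed=71)
    res.per_locus.to_csv(common.RESULTS / f"bottleneck_{group}.tsv", sep="\t", index=False)
    st = res.sign_test
    print(f"{group}: {st['n_excess']}/{st['n_loci']} loci in He excess "
          f"(expected {st['expected_excess']:.1f}), sign-test p = {st['p']:.3f}; "
          f"mode-shift: {res.mode_shift['verdict']}")
    results[group] = {"sign_test": st, "mode_shift": res.mode_shift["verdict"]}

(common.RESULTS / "bottleneck_summary.json").write_text(json.dumps(results, indent=2))
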