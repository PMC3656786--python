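"""Shared paths and loaders for the numbered analysis scripts."""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"


def load_panel():
    """Load the simulated core-collection panel written by 01_simulate.py."""
    from ssrpopkit.genotypes import LinkageMap, read_genotypes

    matrix = DATA / "panel.csv"
    if not matrix.exists():
        raise SystemExit("run analysis/01_simulate.py first (results/data/panel.csv missing)")
    gm = read_genotypes(matrix, "csv")
    lmap = LinkageMap.read_tsv(DATA / "map.tsv")
    return gm, lmap, dict(gm.populations)
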