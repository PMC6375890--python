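#!/usr/bin/env python
"""Build the candidate AIMs panels from the four score tables.

Per-method top-500 panels (~2.8% of the markers at this
m), the variance>=0.15 panel for the K-variance method, the >=3-of-4
consensus panel, a size-matched random negative control, and a re-ranked
compact subset of the consensus (by informativeness, at a
262/1,531 ~ 17% ratio — a stand-in for a genotyping-friendly subset).
Writes panels and an overlap table to results/.
"""

import math
from pathlib import Path

import pandas as pd

from aimpanel import (
    ScoreTable,
    consensus_panel,
    random_panel,
    read_plink_text,
    rerank_panel,
    threshold_panel,
    top_n,
)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 1
TOP_N = 500
VARIANCE_THRESHOLD = 0.15
MIN_METHODS = 3
RERANK_FRACTION = 262 / 1531


def main() -> None:
    G = read_plink_text(SCRATCH / "cohort.ped", SCRATCH / "cohort.map")
    tables = {
        name: ScoreTable.read(SCRATCH / f"scores_{name}.tsv")
        for name in ("informativeness", "fst", "pca_weight", "k_variance")
    }

    method_panels = {
        "informativeness": top_n(tables["informativeness"], TOP_N),
        "fst": top_n(tables["fst"], TOP_N),
        "pca_weight": top_n(tables["pca_weight"], TOP_N),
        "k_variance": threshold_panel(tables["k_variance"], VARIANCE_THRESHOLD),
    }
    consensus = consensus_panel(list(method_panels.values()), MIN_METHODS, universe=G, name="consensus")
    control = random_panel(G, size=len(consensus), seed=SEED, name="random")
    compact = rerank_panel(
        consensus, tables["informativeness"], size=math.ceil(RERANK_FRACTION * len(consensus)),
        name="consensus_compact",
    )

    panels = {**method_panels, "consensus": consensus, "random": control, "consensus_compact": compact}
    panel_dir = RESULTS / "panels"
    panel_dir.mkdir(parents=True, exist_ok=True)
    for name, panel in panels.items():
        panel.write(panel_dir / f"{name}.txt")

    four = list(method_panels)
    overlap = pd.DataFrame(
        [
            {
                "panel_a": a,
                "panel_b": b,
                "overlap": len(set(method_panels[a].snp_ids) & set(method_panels[b].snp_ids)),
            }
            for i, a in enumerate(four)
            for b in four[i + 1 :]
        ]
    )
    overlap.to_csv(RESULTS / "panel_overlap.tsv", sep="\t", index=False)

    sizes = pd.DataFrame([{"panel": n, "size": len(p)} for n, p in panels.items()])
    sizes.to_csv(RESULTS / "panel_sizes.tsv", sep="\t", index=False)
    all_four = consensus_panel(list(method_panels.values()), 4, universe=G)
    print(sizes.to_string(index=False))
    print(f"SNPs common to all four methods: {len(all_four)}")
    print(overlap.to_string(index=False))


if __name__ == "__main__":
    main()
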