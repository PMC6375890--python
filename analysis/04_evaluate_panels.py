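#!/usr/bin/env python
"""Evaluate every panel against the complete-SNP-set reference fit.

For each panel: refit the K=3 admixture model on the panel's SNPs alone
(same seed policy as the reference), align components, and measure
per-individual Euclidean distances between the two ancestry vectors.
Panels are then compared by one-way ANOVA + Tukey HSD. Also projects PCA
on the full set and the consensus panel for the qualitative picture.
Summary tables go to results/, figures to scratch/.
"""

from pathlib import Path

import pandas as pd

from aimpanel import (
    Panel,
    compare_panels,
    evaluate_panel,
    fit_admixture,
    project_pca,
    read_plink_text,
    subset_genotypes,
)
from aimpanel.viz import plot_admixture_bars, plot_pca

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 1
K = 3
PANELS = (
    "informativeness", "fst", "pca_weight", "k_variance",
    "consensus", "random", "consensus_compact",
)


def main() -> None:
    G = read_plink_text(SCRATCH / "cohort.ped", SCRATCH / "cohort.map")
    labels = dict(
        line.split("\t") for line in (SCRATCH / "labels.tsv").read_text().strip().split("\n")
    )
    reference = fit_admixture(G, K=K, seed=SEED)

    reports = {}
    rows = []
    for name in PANELS:
        panel = Panel.read(RESULTS / "panels" / f"{name}.txt")
        report = evaluate_panel(G, panel, K=K, seed=SEED, reference=reference)
        reports[name] = report
        report.write(SCRATCH / f"distances_{name}.tsv")
        rows.append(
            {
                "panel": name,
                "size": len(panel),
                "mean_distance": report.mean,
                "median_distance": report.median,
                "n_zero": report.n_zero,
            }
        )

    summary = pd.DataFrame(rows).sort_values("mean_distance")
    summary.to_csv(RESULTS / "distance_summary.tsv", sep="\t", index=False, float_format="%.4f")
    print(summary.to_string(index=False))

    comparison = compare_panels(list(reports.values()))
    comparison.write(RESULTS / "panel_comparison.tsv")
    print(f"\nANOVA: F={comparison.anova_f:.2f}, p={comparison.anova_p:.3g}")
    print("Tukey HSD adjusted p, consensus vs random: "
          f"{comparison.pair_p('consensus', 'random'):.4g}")

    figures = SCRATCH / "figures"
    figures.mkdir(parents=True, exist_ok=True)
    label_list = [labels[i] for i in G.individual_ids]
    plot_admixture_bars(reference, figures / "admixture_full.png", title="complete SNP set, K=3")
    full_pca = project_pca(G, n_components=2)
    plot_pca(full_pca, figures / "pca_full.png", labels=label_list, title="complete SNP set")
    consensus_G = subset_genotypes(G, Panel.read(RESULTS / "panels" / "consensus.txt"))
    cons_pca = project_pca(consensus_G, n_components=2)
    plot_pca(cons_pca, figures / "pca_consensus.png", labels=label_list, title="consensus panel")
    ve_rows = [
        {"dataset": "complete", "pc1_var": full_pca.variance_explained[0], "pc2_var": full_pca.variance_explained[1]},
        {"dataset": "consensus", "pc1_var": cons_pca.variance_explained[0], "pc2_var": cons_pca.variance_explained[1]},
    ]
    pd.DataFrame(ve_rows).to_csv(RESULTS / "pca_variance.tsv", sep="\t", index=False, float_format="%.4f")
    print(f"\nPC1/PC2 variance explained, complete set: "
          f"{full_pca.variance_explained[0]:.2%} / {full_pca.variance_explained[1]:.2%}; "
          f"consensus panel: {cons_pca.variance_explained[0]:.2%} / {cons_pca.variance_explained[1]:.2%}")


if __name__ == "__main__":
    main()
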