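"""Survival stratification and integrative feature clustering.

Features are binned high/low (median for burdens, cluster-vs-rest for
subtypes), compared by Kaplan-Meier log-rank with BH across the screen, and
the continuous features are clustered into correlation blocks.

Reads results/, writes results/survival.tsv and results/feature_blocks.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from icbscreen.io import read_clinical
from icbscreen.stats import bin_feature, cross_correlation_cluster, survival_screen

OUT = Path("results")


def main(seed: int = 1) -> None:
    table = pd.read_csv(OUT / "features.tsv", sep="\t").set_index("sample_id")
    clinical = read_clinical(OUT / "cohort/clinical.tsv")

    binned = pd.DataFrame(index=table.index)
    for col in table.columns:
        if col.startswith("log_"):
            binned[col] = bin_feature(table[col], "burden")
        elif col.startswith("subtype_"):
            binned[col] = bin_feature(table[col], "alteration")
    surv = survival_screen(clinical, binned)
    surv.reset_index().to_csv(OUT / "survival.tsv", sep="\t", index=False)
    print("log-rank screen (q = BH over the screen):")
    print(surv.round(4).to_string())

    numeric = table[[c for c in table.columns if not c.startswith("subtype_")]]
    corr, blocks, order = cross_correlation_cluster(numeric, n_blocks=3)
    corr.rename_axis("feature").reset_index().to_csv(
        OUT / "feature_correlation.tsv", sep="\t", index=False
    )
    blocks.rename_axis("feature").reset_index().to_csv(
        OUT / "feature_blocks.tsv", sep="\t", index=False
    )
    print("\ncorrelation blocks:")
    print(blocks.sort_values().to_string())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
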