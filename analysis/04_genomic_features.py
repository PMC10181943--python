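"""Assemble the per-sample genomic feature table: log TMB with the
one-event-per-MB pseudocount, clonal/subclonal burdens from the CCF > 0.85
split, subclone counts, neoantigen binder burden (percentile rank <= 2),
and subtype-membership indicators.

Reads results/cohort/ and results/subtypes/, writes results/features.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from icbscreen.config import PipelineConfig
from icbscreen.features import build_feature_table
from icbscreen.io import read_ranks, read_variants

IN = Path("results/cohort")
OUT = Path("results")


def main(seed: int = 1) -> None:
    cfg = PipelineConfig(seed=seed)
    variants = read_variants(IN / "variants.tsv")
    ranks = read_ranks(IN / "ranks.tsv")
    assignments = pd.read_csv(
        "results/subtypes/assignments.tsv", sep="\t"
    ).set_index("sample_id")["cluster"]

    binary = pd.get_dummies(assignments, prefix="subtype", prefix_sep="_").astype(float)
    table = build_feature_table(
        variants=variants,
        ranks=ranks,
        territory_mb=cfg.territory_mb,
        ccf_threshold=cfg.ccf_clonal_threshold,
        rank_threshold=cfg.binder_rank_threshold,
        binary_features=binary,
    )
    table.rename_axis("sample_id").reset_index().to_csv(
        OUT / "features.tsv", sep="\t", index=False
    )
    print(f"wrote {table.shape[1]} features for {table.shape[0]} samples")
    print(table.describe().loc[["mean", "50%"]].T.to_string())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
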