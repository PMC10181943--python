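"""Derive expression subtypes from the simulated cohort.

Differential expression of responders vs nonresponders seeds the gene list;
consensus clustering over K = 2..10 plus B-NMF of the summed consensus
matrix picks the cluster number; B-NMF of the expression matrix at that K
yields cluster assignments and per-cluster marker genes.

Reads results/cohort/, writes results/subtypes/.
"""

import sys
from pathlib import Path

import pandas as pd

from icbscreen.config import PipelineConfig, SeedSplitter
from icbscreen.io import read_clinical, read_expression
from icbscreen.stats import differential_expression
from icbscreen.subtypes import derive_m_subtypes

IN = Path("results/cohort")
OUT = Path("results/subtypes")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=seed, consensus_iterations=100)
    expr = read_expression(IN / "expression.tsv")
    clinical = read_clinical(IN / "clinical.tsv").set_index("sample_id")

    de = differential_expression(expr, clinical["response"])
    de.reset_index().to_csv(OUT / "differential_expression.tsv", sep="\t", index=False)
    n_de = int(((de["p"] < cfg.de_p_threshold) & (de["lfc"].abs() > cfg.de_lfc_threshold)).sum())

    run = derive_m_subtypes(expr, de, cfg, seed=SeedSplitter(seed).seed_for("subtype"))
    model = run.model
    model.training_assignments.rename_axis("sample_id").reset_index().to_csv(
        OUT / "assignments.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"cluster": lab, "gene": g} for lab, genes in model.marker_genes.items()
         for g in genes]
    ).to_csv(OUT / "markers.tsv", sep="\t", index=False)
    model.W_markers.rename_axis("gene").reset_index().to_csv(
        OUT / "W_markers.tsv", sep="\t", index=False
    )

    truth = pd.read_csv(IN / "truth_labels.tsv", sep="\t").set_index("sample_id")
    tab = pd.crosstab(model.training_assignments, truth["program"])
    print(f"{n_de} DE genes seeded the pipeline; determined K = {run.K}")
    print("cluster x true-program cross-tabulation:")
    print(tab.to_string())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
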