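"""Simulate the study cohort: expression with three latent microenvironment
programs, SBS96 mutation catalogs from seven-signature mixtures, a CCF-
annotated variant table with MHC-I peptide ranks, and clinical outcomes in
which the first program and tumor mutational burden favor response.

Writes the cohort tables under results/cohort/.
"""

import sys
from pathlib import Path

import pandas as pd

from icbscreen.config import PipelineConfig, SeedSplitter
from icbscreen.features import compute_tmb
from icbscreen.io import write_expression, write_mutation_catalog, write_table
from icbscreen.pipeline import DEMO_INTERCEPT, demo_effects
from icbscreen.simulate import (
    load_expression_scenario,
    load_signature_scenario,
    simulate_clinical,
    simulate_expression,
    simulate_mutation_catalog,
    simulate_ranks,
    simulate_variants,
)

OUT = Path("results/cohort")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=seed)
    seeds = SeedSplitter(cfg.seed)

    expr_sc = load_expression_scenario("m_default")
    expr, truth = simulate_expression(expr_sc, seed=seeds.seed_for("expression"))
    sig_sc = load_signature_scenario("sig_default")
    catalog, _ = simulate_mutation_catalog(sig_sc, seed=seeds.seed_for("catalog"))
    variants = simulate_variants(
        expr.n_samples, seed=seeds.seed_for("variants"), sample_ids=expr.sample_ids
    )
    ranks = simulate_ranks(variants, seed=seeds.seed_for("ranks"))

    tmb = compute_tmb(variants, cfg.territory_mb).reindex(expr.sample_ids)
    feats = pd.DataFrame(index=expr.sample_ids)
    for k in range(expr_sc.n_programs):
        feats[f"program_{k}"] = (truth.program_labels == k).astype(float)
    feats["log_tmb_centered"] = tmb["log_tmb"] - tmb["log_tmb"].mean()
    truth.features = feats
    clinical = simulate_clinical(
        truth, demo_effects(expr_sc.n_programs), intercept=DEMO_INTERCEPT,
        seed=seeds.seed_for("clinical"),
    )

    write_expression(expr, OUT / "expression.tsv")
    write_mutation_catalog(catalog, OUT / "mutation_catalog.tsv")
    write_table(variants, OUT / "variants.tsv")
    write_table(ranks, OUT / "ranks.tsv")
    write_table(clinical, OUT / "clinical.tsv")
    write_table(
        pd.DataFrame({"sample_id": expr.sample_ids, "program": truth.program_labels}),
        OUT / "truth_labels.tsv",
    )
    rate = clinical["response"].mean()
    print(f"simulated {expr.n_samples} samples, {expr.n_genes} genes; "
          f"response rate {rate:.2f}; median TMB {tmb['rate_per_mb'].median():.1f}/MB")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
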