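"""Cluster-number recovery experiments on the packaged scenarios.

Each function simulates fresh cohorts from a packaged scenario and measures
how often the pipeline recovers the scenario's true latent dimension:
the consensus -> B-NMF cluster number for the expression scenarios, and the
ARD effective rank for the mutational-signature scenario.  Shared by the
test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .signatures import extract_signatures
from .simulate import (
    load_expression_scenario,
    load_signature_scenario,
    simulate_expression,
    simulate_mutation_catalog,
)
from .subtypes import (
    consensus_matrix,
    determine_k,
    filter_low_quality_genes,
    median_center,
)


def expression_k_runs(
    scenario_name: str,
    n_runs: int = 10,
    seed: int = 0,
    consensus_iterations: int = 100,
    n_restarts: int = 10,
    k_range=range(2, 11),
) -> list[int]:
    """Determined cluster numbers over ``n_runs`` fresh cohort draws.

    Each run simulates a cohort, applies the sparse/low-expression gene
    filter, median-centers, builds the consensus matrix over the K range,
    and determines K by ARD B-NMF of the summed consensus matrix.
    """
    scenario = load_expression_scenario(scenario_name)
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    ks = []
    for s in seeds:
        s = int(s)
        expr, _ = simulate_expression(scenario, seed=s)
        genes = filter_low_quality_genes(expr)
        fc = median_center(expr.subset_genes(genes))
        cons = consensus_matrix(
            fc, k_range=k_range, iterations=consensus_iterations, seed=s + 1
        )
        ks.append(
            determine_k(cons, n_restarts=n_restarts, seed=s + 2, k_max=max(k_range))
        )
    return ks


def signature_k_runs(
    scenario_name: str = "sig_default",
    n_runs: int = 10,
    seed: int = 0,
    n_restarts: int = 20,
    k_max: int = 15,
) -> list[int]:
    """ARD effective ranks over ``n_runs`` fresh catalog draws."""
    scenario = load_signature_scenario(scenario_name)
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    ks = []
    for s in seeds:
        s = int(s)
        catalog, _ = simulate_mutation_catalog(scenario, seed=s)
        fact = extract_signatures(catalog, n_restarts=n_restarts, seed=s + 1, k_max=k_max)
        ks.append(fact.K_eff)
    return ks
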