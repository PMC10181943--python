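"""End-to-end orchestration of the synthetic-cohort analysis.

Stages communicate only via TSV files under the output directory, in
dependency order: simulate -> differential expression -> subtype ->
signatures -> features -> associate -> survive -> integrate.  A JSON run
manifest ties every output file to the configuration, the master seed and
a content digest, so a rerun with the same config and seed reproduces the
digests of all deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig, SeedSplitter
from .features import build_feature_table, compute_tmb, immunoproteasome_set, metagene_score
from .io import (
    ExpressionMatrix,
    write_expression,
    write_mutation_catalog,
    write_table,
)
from .signatures import SignatureSet, attribute_burden, extract_signatures, label_signatures
from .simulate import (
    CohortTruth,
    load_expression_scenario,
    load_signature_scenario,
    simulate_clinical,
    simulate_expression,
    simulate_mutation_catalog,
    simulate_ranks,
    simulate_variants,
)
from .stats import (
    bin_feature,
    cross_correlation_cluster,
    differential_expression,
    logistic_screen,
    prevalence_filter,
    survival_screen,
)
from .subtypes import derive_m_subtypes

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    timestamp: str
    master_seed: int
    config: dict
    package_version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, Path]) -> None:
        self.stages[stage] = {
            name: {"path": str(p), "sha256": _digest(p)} for name, p in outputs.items()
        }

    def write(self, path: Path) -> None:
        payload = self.__dict__.copy()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


# demo clinical model: the first and last expression programs carry opposite
# response effects and TMB adds a positive log-odds contribution, giving an
# overall response rate in the mid-30s of percent
DEMO_INTERCEPT = -0.55


def demo_effects(n_programs: int) -> dict[str, float]:
    effects = {"program_0": 1.2, "log_tmb_centered": 0.5}
    if n_programs >= 2:
        effects[f"program_{n_programs - 1}"] = -1.2
    return effects


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    expression_scenario: str = "m_default",
    signature_scenario: str = "sig_default",
) -> RunManifest:
    """Run every stage on a freshly simulated cohort and write all tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = SeedSplitter(config.seed)
    manifest = RunManifest(
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        master_seed=config.seed,
        config=config.to_dict(),
    )

    stage = "simulate"
    try:
        expr_sc = load_expression_scenario(expression_scenario)
        sig_sc = load_signature_scenario(signature_scenario)
        expr, truth = simulate_expression(expr_sc, seed=seeds.seed_for("expression"))
        catalog, sig_truth = simulate_mutation_catalog(sig_sc, seed=seeds.seed_for("catalog"))
        variants = simulate_variants(
            expr.n_samples, seed=seeds.seed_for("variants"), sample_ids=expr.sample_ids
        )
        ranks = simulate_ranks(variants, seed=seeds.seed_for("ranks"))

        tmb = compute_tmb(variants, config.territory_mb).reindex(expr.sample_ids)
        feats = pd.DataFrame(index=expr.sample_ids)
        for k in range(expr_sc.n_programs):
            feats[f"program_{k}"] = (truth.program_labels == k).astype(float)
        feats["log_tmb_centered"] = tmb["log_tmb"] - tmb["log_tmb"].mean()
        truth.features = feats
        clinical = simulate_clinical(
            truth,
            demo_effects(expr_sc.n_programs),
            intercept=DEMO_INTERCEPT,
            seed=seeds.seed_for("clinical"),
        )
        paths = {
            "expression": outdir / "expression.tsv",
            "catalog": outdir / "mutation_catalog.tsv",
            "variants": outdir / "variants.tsv",
            "ranks": outdir / "ranks.tsv",
            "clinical": outdir / "clinical.tsv",
            "truth": outdir / "truth_labels.tsv",
        }
        write_expression(expr, paths["expression"])
        write_mutation_catalog(catalog, paths["catalog"])
        write_table(variants, paths["variants"])
        write_table(ranks, paths["ranks"])
        write_table(clinical, paths["clinical"])
        write_table(
            pd.DataFrame(
                {"sample_id": expr.sample_ids, "program": truth.program_labels}
            ),
            paths["truth"],
        )
        manifest.record(stage, paths)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "differential_expression"
    try:
        response = clinical.set_index("sample_id")["response"]
        de = differential_expression(expr, response)
        de_path = outdir / "differential_expression.tsv"
        de.reset_index().to_csv(de_path, sep="\t", index=False)
        manifest.record(stage, {"de": de_path})
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "subtype"
    try:
        run = derive_m_subtypes(expr, de, config, seed=seeds.seed_for("subtype"))
        model = run.model
        marker_path = outdir / "subtype_markers.tsv"
        model.W_markers.reset_index(names="gene").merge(
            pd.DataFrame(
                [
                    {"gene": g, "cluster": lab}
                    for lab, genes in model.marker_genes.items()
                    for g in genes
                ]
            ),
            on="gene",
        ).to_csv(marker_path, sep="\t", index=False)
        assign_path = outdir / "subtype_assignments.tsv"
        model.training_assignments.rename_axis("sample_id").reset_index().to_csv(
            assign_path, sep="\t", index=False
        )
        manifest.record(stage, {"markers": marker_path, "assignments": assign_path})
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "signatures"
    try:
        fact = extract_signatures(
            catalog,
            n_restarts=config.signature_restarts,
            seed=seeds.seed_for("signatures"),
        )
        reference = SignatureSet(sig_sc.signature_labels, sig_sc.reference_signatures)
        labels = label_signatures(fact.W_active, reference, config.min_label_cosine)
        burden = attribute_burden(fact, catalog)
        sig_paths = {
            "labels": outdir / "signature_labels.tsv",
            "burden": outdir / "signature_burden.tsv",
        }
        labels.to_csv(sig_paths["labels"], sep="\t", index=False)
        burden.rename_axis("sample_id").reset_index().to_csv(
            sig_paths["burden"], sep="\t", index=False
        )
        manifest.record(stage, sig_paths)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "features"
    try:
        ipro = metagene_score_or_none(expr)
        metagenes = pd.DataFrame(index=expr.sample_ids)
        if ipro is not None:
            metagenes[ipro.name] = ipro
        cluster_assign = model.training_assignments
        binary = pd.DataFrame(index=expr.sample_ids)
        for lab in model.cluster_labels:
            binary[f"subtype_{lab}"] = (cluster_assign == lab).astype(float)
        table = build_feature_table(
            variants=variants,
            ranks=ranks,
            territory_mb=config.territory_mb,
            ccf_threshold=config.ccf_clonal_threshold,
            rank_threshold=config.binder_rank_threshold,
            metagenes=metagenes if not metagenes.empty else None,
            binary_features=binary,
        ).reindex(expr.sample_ids)
        feat_path = outdir / "features.tsv"
        table.rename_axis("sample_id").reset_index().to_csv(feat_path, sep="\t", index=False)
        manifest.record(stage, {"features": feat_path})
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "associate"
    try:
        kinds = {c: ("binary" if c.startswith("subtype_") else "continuous") for c in table}
        screened = prevalence_filter(table, kinds, config.min_prevalence)
        assoc = logistic_screen(
            screened,
            response,
            config.fdr_significant,
            config.fdr_near_significant,
        )
        assoc_path = outdir / "associations.tsv"
        assoc.reset_index().to_csv(assoc_path, sep="\t", index=False)
        manifest.record(stage, {"associations": assoc_path})
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "survive"
    try:
        binned = pd.DataFrame(index=table.index)
        binned["log_tmb"] = bin_feature(table["log_tmb"], "burden")
        if "immunoproteasome_inducible" in table:
            binned["immunoproteasome_inducible"] = bin_feature(
                table["immunoproteasome_inducible"], "zscore"
            )
        binned["subtype_top"] = bin_feature(
            cluster_assign, "cluster", cluster=model.cluster_labels[0]
        )
        surv = survival_screen(clinical, binned)
        surv_path = outdir / "survival.tsv"
        surv.reset_index().to_csv(surv_path, sep="\t", index=False)
        manifest.record(stage, {"survival": surv_path})
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "integrate"
    try:
        numeric = table.select_dtypes(include=[float, int])
        corr, blocks, order = cross_correlation_cluster(numeric, n_blocks=4)
        corr_path = outdir / "feature_correlation.tsv"
        corr.rename_axis("feature").reset_index().to_csv(corr_path, sep="\t", index=False)
        block_path = outdir / "feature_blocks.tsv"
        blocks.rename_axis("feature").reset_index().to_csv(block_path, sep="\t", index=False)
        manifest.record(stage, {"correlation": corr_path, "blocks": block_path})
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest.write(outdir / "run_manifest.json")
    return manifest


def metagene_score_or_none(expr: ExpressionMatrix):
    """Immunoproteasome metagene if any of its genes are simulated; the
    synthetic gene space uses positional identifiers, so usually None."""
    gs = immunoproteasome_set()
    try:
        return metagene_score(expr, gs)
    except ValueError:
        return None
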