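"""Synthetic-cohort generators.

These emulate the statistical structure the downstream analysis assumes —
latent expression programs with additive log2-scale marker effects, mutation
catalogs as multinomial draws from signature mixtures, and clinical outcomes
tied to genomic features through a logistic link — so the whole pipeline can
be exercised without any controlled-access data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .io import BOR_CATEGORIES, ExpressionMatrix, MutationCatalog, sbs96_channels


@dataclass
class ExpressionScenario:
    """Latent-program expression cohort: each sample belongs to one program
    whose marker genes are shifted up by ``marker_effect`` on the log2 scale."""

    n_samples: int = 120
    n_genes: int = 800
    n_programs: int = 3
    markers_per_program: int = 60
    marker_effect: float = 2.0
    noise_sd: float = 0.6
    baseline_mean: float = 3.0
    baseline_gene_sd: float = 1.0
    mixing: tuple[float, ...] | None = None
    dropout_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_programs < 1:
            raise ValueError("n_programs must be >= 1")
        if self.markers_per_program * self.n_programs > self.n_genes:
            raise ValueError("marker blocks exceed the number of genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.mixing is not None:
            self.mixing = tuple(float(p) for p in self.mixing)
            if len(self.mixing) != self.n_programs:
                raise ValueError("mixing proportions must match n_programs")
            if not np.isclose(sum(self.mixing), 1.0):
                raise ValueError("mixing proportions must sum to 1")

    @property
    def proportions(self) -> np.ndarray:
        if self.mixing is None:
            return np.full(self.n_programs, 1.0 / self.n_programs)
        return np.asarray(self.mixing)


@dataclass
class SignatureScenario:
    """Mutation catalogs as sparse mixtures of reference SBS96 signatures."""

    reference_signatures: np.ndarray
    signature_labels: tuple[str, ...]
    n_samples: int = 200
    min_mutations: int = 500
    max_mutations: int = 2000
    concentration: float = 1.0
    max_active_signatures: int = 4

    def __post_init__(self) -> None:
        R = np.asarray(self.reference_signatures, dtype=float)
        if R.ndim != 2 or R.shape[1] != 96:
            raise ValueError("reference signatures must be S x 96")
        if not np.allclose(R.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each reference signature must sum to 1")
        if (R < 0).any():
            raise ValueError("reference signatures must be nonnegative")
        self.reference_signatures = R
        if len(self.signature_labels) != R.shape[0]:
            raise ValueError("one label per reference signature required")
        if not 1 <= self.max_active_signatures <= R.shape[0]:
            raise ValueError("max_active_signatures out of range")
        if self.min_mutations < 1 or self.max_mutations < self.min_mutations:
            raise ValueError("invalid mutation count range")

    @property
    def n_signatures(self) -> int:
        return self.reference_signatures.shape[0]


@dataclass
class CohortTruth:
    """Ground truth carried alongside every simulated table."""

    sample_ids: list[str]
    program_labels: np.ndarray | None = None
    marker_blocks: dict[int, list[str]] | None = None
    exposures: np.ndarray | None = None
    features: pd.DataFrame | None = None
    response_prob: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.exposures is not None:
            rows = self.exposures.sum(axis=1)
            nonzero = rows > 0
            if not np.allclose(rows[nonzero], 1.0, atol=1e-8):
                raise ValueError("exposures must sum to 1 per sample")


def simulate_expression(
    scenario: ExpressionScenario, seed: int = 0
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Draw a log2(TPM+1) matrix with latent program structure.

    Gene-level baselines are Gaussian on the log2 scale (clipped at 0);
    marker genes of a sample's program are shifted by ``marker_effect``
    before noise and dropout are applied.
    """
    rng = np.random.default_rng(seed)
    sc = scenario
    gene_ids = [f"G{i:04d}" for i in range(sc.n_genes)]
    sample_ids = [f"S{i:03d}" for i in range(sc.n_samples)]
    labels = rng.choice(sc.n_programs, size=sc.n_samples, p=sc.proportions)

    baseline = np.clip(
        rng.normal(sc.baseline_mean, sc.baseline_gene_sd, size=sc.n_genes), 0.1, None
    )
    values = np.tile(baseline[:, None], (1, sc.n_samples))
    marker_blocks: dict[int, list[str]] = {}
    for k in range(sc.n_programs):
        rows = slice(k * sc.markers_per_program, (k + 1) * sc.markers_per_program)
        marker_blocks[k] = gene_ids[rows]
        values[rows, :][:, labels == k] += sc.marker_effect
    values += rng.normal(0.0, sc.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    if sc.dropout_rate > 0:
        values[rng.random(values.shape) < sc.dropout_rate] = 0.0

    truth = CohortTruth(sample_ids, program_labels=labels, marker_blocks=marker_blocks)
    return ExpressionMatrix(gene_ids, sample_ids, values), truth


def simulate_mutation_catalog(
    scenario: SignatureScenario, seed: int = 0
) -> tuple[MutationCatalog, CohortTruth]:
    """Draw per-sample SBS96 catalogs from sparse signature mixtures.

    Each sample is active in a random subset of at most
    ``max_active_signatures`` references; its exposure vector is Dirichlet
    over that subset and its catalog multinomial over the mixed spectrum.
    """
    rng = np.random.default_rng(seed)
    sc = scenario
    S = sc.n_signatures
    sample_ids = [f"S{i:03d}" for i in range(sc.n_samples)]
    exposures = np.zeros((sc.n_samples, S))
    counts = np.zeros((sc.n_samples, 96), dtype=np.int64)
    for i in range(sc.n_samples):
        n_active = int(rng.integers(1, sc.max_active_signatures + 1))
        active = rng.choice(S, size=n_active, replace=False)
        e = rng.dirichlet(np.full(n_active, sc.concentration))
        exposures[i, active] = e
        total = int(rng.integers(sc.min_mutations, sc.max_mutations + 1))
        spectrum = exposures[i] @ sc.reference_signatures
        counts[i] = rng.multinomial(total, spectrum)
    truth = CohortTruth(sample_ids, exposures=exposures)
    return MutationCatalog(sample_ids, counts), truth


def simulate_clinical(
    truth: CohortTruth,
    feature_effects: dict[str, float],
    intercept: float = 0.0,
    censoring_rate: float = 0.05,
    seed: int = 0,
    responder_median_pfs: float = 12.0,
    nonresponder_median_pfs: float = 3.0,
) -> pd.DataFrame:
    """Draw BOR/response and censored PFS from the truth feature table.

    response ~ Bernoulli(logistic(intercept + sum beta * feature)); PFS is
    exponential with a shorter median for nonresponders, independently
    censored at ``censoring_rate`` events per month.
    """
    rng = np.random.default_rng(seed)
    n = len(truth.sample_ids)
    eta = np.full(n, float(intercept))
    if feature_effects:
        if truth.features is None:
            raise KeyError("truth carries no feature table")
        for name, beta in feature_effects.items():
            if name not in truth.features.columns:
                raise KeyError(f"unknown feature name: {name!r}")
            eta += beta * truth.features[name].to_numpy(dtype=float)
    prob = 1.0 / (1.0 + np.exp(-eta))
    response = (rng.random(n) < prob).astype(int)

    bor = np.where(
        response == 1,
        np.where(rng.random(n) < 0.3, "CR", "PR"),
        np.where(rng.random(n) < 0.45, "SD", "PD"),
    )
    rate = np.where(
        response == 1,
        np.log(2.0) / responder_median_pfs,
        np.log(2.0) / nonresponder_median_pfs,
    )
    event_time = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        censor_time = rng.exponential(1.0 / censoring_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    pfs_time = np.minimum(event_time, censor_time)
    pfs_event = (event_time <= censor_time).astype(int)
    pdl1 = np.round(np.clip(rng.beta(0.6, 1.2, size=n) * 100, 0, 100), 1)
    pdl1[rng.random(n) < 0.1] = np.nan

    truth.response_prob = prob
    df = pd.DataFrame(
        {
            "sample_id": truth.sample_ids,
            "bor": pd.Categorical(bor, categories=list(BOR_CATEGORIES)),
            "response": response,
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
            "pdl1_tps": pdl1,
        }
    )
    return df


def simulate_variants(
    n_samples: int,
    seed: int = 0,
    mean_variants: float = 150.0,
    dispersion: float = 0.8,
    clonal_fraction: float = 0.7,
    max_subclones: int = 3,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """MAF-lite variant table with CCF cluster assignments.

    Per-sample mutation rates are log-normally dispersed around
    ``mean_variants`` (tumor mutational burden spans orders of magnitude
    across patients); cluster 1 is the clonal cluster (CCF near 1) and
    additional clusters sit at lower CCF so the clonal/subclonal split at
    CCF > 0.85 is exercised.
    """
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    rows = []
    classes = ["nonsynonymous_snv", "dnv", "indel", "other"]
    class_p = [0.75, 0.05, 0.1, 0.1]
    for sid in sample_ids:
        lam = rng.lognormal(np.log(mean_variants), dispersion)
        n_var = max(1, int(rng.poisson(lam)))
        n_sub = int(rng.integers(0, max_subclones + 1))
        cluster_ccf = {1: float(rng.uniform(0.9, 1.0))}
        for c in range(2, n_sub + 2):
            cluster_ccf[c] = float(rng.uniform(0.1, 0.8))
        cluster_ids = list(cluster_ccf)
        p = np.full(len(cluster_ids), (1 - clonal_fraction) / max(1, len(cluster_ids) - 1))
        p[0] = clonal_fraction if len(cluster_ids) > 1 else 1.0
        for v in range(n_var):
            cid = int(rng.choice(cluster_ids, p=p))
            rows.append(
                {
                    "sample_id": sid,
                    "gene": f"G{int(rng.integers(0, 500)):04d}",
                    "variant_class": str(rng.choice(classes, p=class_p)),
                    "ccf_cluster_id": cid,
                    "cluster_ccf": cluster_ccf[cid],
                }
            )
    return pd.DataFrame(rows)


def simulate_ranks(
    variants: pd.DataFrame,
    seed: int = 0,
    peptides_per_variant: float = 0.5,
    alleles: tuple[str, ...] = ("A*02:01", "B*07:02", "C*07:01"),
) -> pd.DataFrame:
    """Per-peptide MHC-I percentile ranks for a subset of variants."""
    rng = np.random.default_rng(seed)
    rows = []
    for (sid, gene), idx in variants.groupby(["sample_id", "gene"]).groups.items():
        for j in range(len(idx)):
            if rng.random() > peptides_per_variant:
                continue
            vid = f"{gene}_v{j}"
            for allele in alleles:
                # log-uniform ranks: a minority fall under the binder cut
                rank = float(10 ** rng.uniform(-1, 2))
                rows.append(
                    {
                        "sample_id": sid,
                        "variant_id": vid,
                        "allele": allele,
                        "percentile_rank": round(rank, 3),
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "variant_id", "allele", "percentile_rank"])


# --- Reference signatures and packaged scenarios ------------------------------


def synthetic_reference_signatures(
    n_signatures: int = 7, seed: int = 20240001
) -> tuple[np.ndarray, tuple[str, ...]]:
    """A synthetic stand-in for a COSMIC-style SBS96 reference set.

    Three signatures mimic the shape of well-known mutational processes —
    aging-like (C>T at NpCpG), smoking-like (C>A-heavy), APOBEC-like
    (C>T/C>G at TpCpW) — so that cosine-similarity labeling is exercised;
    the remainder are sparse random spectra with a fixed seed.  These are
    NOT the COSMIC signatures; they only share their qualitative geometry.
    """
    rng = np.random.default_rng(seed)
    channels = sbs96_channels()
    sigs = []
    labels = []

    def channel_weight(pattern) -> np.ndarray:
        w = np.array([pattern(ch) for ch in channels], dtype=float)
        w += 1e-4
        return w / w.sum()

    # aging-like: C>T at CpG dinucleotides (3' G)
    sigs.append(
        channel_weight(lambda ch: 3.0 if "[C>T]" in ch and ch[-1] == "G" else 0.1)
    )
    labels.append("aging-like")
    # smoking-like: C>A across contexts
    sigs.append(channel_weight(lambda ch: 2.0 if "[C>A]" in ch else 0.05))
    labels.append("smoking-like")
    # APOBEC-like: C>T / C>G at TpC with 3' A or T
    sigs.append(
        channel_weight(
            lambda ch: 3.0
            if ch[0] == "T" and ("[C>G]" in ch or "[C>T]" in ch) and ch[-1] in "AT"
            else 0.05
        )
    )
    labels.append("APOBEC-like")
    for j in range(3, n_signatures):
        sigs.append(rng.dirichlet(np.full(96, 0.08)))
        labels.append(f"synthetic-{j + 1}")
    sigs, labels = sigs[:n_signatures], labels[:n_signatures]
    return np.vstack(sigs), tuple(labels)


_SCENARIO_PACKAGE = "icbscreen.scenarios"


def load_expression_scenario(name_or_path: str) -> ExpressionScenario:
    raw = _load_scenario_yaml(name_or_path)
    if raw.pop("kind", "expression") != "expression":
        raise ValueError(f"{name_or_path} is not an expression scenario")
    if "mixing" in raw and raw["mixing"] is not None:
        raw["mixing"] = tuple(raw["mixing"])
    return ExpressionScenario(**raw)


def load_signature_scenario(name_or_path: str) -> SignatureScenario:
    raw = _load_scenario_yaml(name_or_path)
    if raw.pop("kind") != "signature":
        raise ValueError(f"{name_or_path} is not a signature scenario")
    ref_spec = raw.pop("reference", {"synthetic": True, "n_signatures": 7})
    sigs, labels = synthetic_reference_signatures(
        n_signatures=int(ref_spec.get("n_signatures", 7)),
        seed=int(ref_spec.get("seed", 20240001)),
    )
    return SignatureScenario(reference_signatures=sigs, signature_labels=labels, **raw)


def _load_scenario_yaml(name_or_path: str) -> dict:
    import os

    if os.path.exists(name_or_path):
        with open(name_or_path) as fh:
            return yaml.safe_load(fh)
    ref = resources.files(_SCENARIO_PACKAGE).joinpath(f"{name_or_path}.yaml")
    if not ref.is_file():
        raise FileNotFoundError(f"no scenario file or packaged scenario {name_or_path!r}")
    return yaml.safe_load(ref.read_text())
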