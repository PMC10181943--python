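"""Per-sample genomic feature computations.

Tumor mutational burden with its one-event-per-MB pseudocount, CCF-based
clonality classification, subclone counting, neoantigen binder counting,
rearranged-receptor burden, metagene z-scores and the fixed
immunoproteasome gene set.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

NONSYN_CLASSES = frozenset({"nonsynonymous_snv", "dnv", "indel"})


def compute_tmb(
    variants: pd.DataFrame, territory_mb: float, sample: str | None = None
) -> pd.DataFrame:
    """Tumor mutational burden per sample.

    rate = (nonsynonymous SNV + DNV + indel count) / territory_mb;
    the log burden is ln(rate + 1), i.e. a pseudocount of one event per MB.
    Returns columns ``n_events``, ``rate_per_mb`` (for binning) and
    ``log_tmb``.
    """
    if territory_mb <= 0:
        raise ValueError("territory_mb must be > 0")
    df = variants if sample is None else variants[variants["sample_id"] == sample]
    counts = (
        df[df["variant_class"].isin(NONSYN_CLASSES)]
        .groupby("sample_id")
        .size()
        .reindex(df["sample_id"].unique(), fill_value=0)
    )
    rate = counts / territory_mb
    out = pd.DataFrame(
        {
            "n_events": counts,
            "rate_per_mb": rate,
            "log_tmb": np.log(rate + 1.0),
        }
    )
    out.index.name = "sample_id"
    return out


def log_burden(rate: float | np.ndarray) -> float | np.ndarray:
    """The shared burden transform: ln(events per MB + 1)."""
    return np.log(np.asarray(rate, dtype=float) + 1.0)


def classify_clonality(
    variants: pd.DataFrame, ccf_threshold: float = 0.85
) -> tuple[pd.Series, pd.DataFrame]:
    """Clonal iff cluster CCF strictly exceeds the threshold (default 0.85).

    Returns the per-variant label series and per-sample clonal/subclonal
    counts.
    """
    ccf = variants["cluster_ccf"].to_numpy(dtype=float)
    if np.any((ccf < 0) | (ccf > 1)):
        raise ValueError("cluster_ccf must lie in [0, 1]")
    labels = pd.Series(
        np.where(ccf > ccf_threshold, "clonal", "subclonal"),
        index=variants.index,
        name="clonality",
    )
    per_sample = (
        pd.DataFrame({"sample_id": variants["sample_id"], "clonality": labels})
        .groupby("sample_id")["clonality"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["clonal", "subclonal"], fill_value=0)
    )
    return labels, per_sample


def subclone_count(variants: pd.DataFrame, sample: str) -> int:
    """Number of distinct CCF clusters observed for a sample."""
    sub = variants[variants["sample_id"] == sample]
    return int(sub["ccf_cluster_id"].nunique())


def count_neoantigen_binders(
    ranks: pd.DataFrame,
    sample: str,
    rank_threshold: float = 2.0,
    per_variant: bool = False,
) -> int:
    """Predicted binders: peptides whose best percentile rank over the
    patient's class-I alleles is at or below the threshold ("two or less").

    Deduplicated at the peptide (``variant_id``) level by default; with
    ``per_variant=True`` peptides are collapsed to their parent variant
    (everything before the last ``_``).
    """
    sub = ranks[ranks["sample_id"] == sample]
    if sub.empty:
        return 0
    best = sub.groupby("variant_id")["percentile_rank"].min()
    binders = best[best <= rank_threshold]
    if per_variant:
        parents = {vid.rsplit("_", 1)[0] for vid in binders.index}
        return len(parents)
    return int(binders.size)


def receptor_burden(rearranged_reads: int, aligned_reads: int) -> tuple[float, float]:
    """T-/B-cell receptor burden: (rearranged + 1) / (aligned / 1e6), plus
    its natural log used for significance testing."""
    if aligned_reads <= 0:
        raise ValueError("aligned_reads must be > 0")
    burden = (rearranged_reads + 1) / (aligned_reads / 1e6)
    return burden, math.log(burden)


def metagene_score(expr: ExpressionMatrix, gene_set: GeneSet) -> pd.Series:
    """Metagene activity: per-sample mean of log2 TPM over the set's genes
    present in the matrix, z-scored across samples (ddof=1)."""
    present = [g for g in gene_set.members if g in set(expr.gene_ids)]
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} present in the matrix")
    missing = set(gene_set.members) - set(present)
    if missing:
        logger.info("metagene %s: %d genes absent", gene_set.name, len(missing))
    if expr.n_samples < 3:
        raise ValueError("metagene z-scoring needs at least 3 samples")
    sub = expr.subset_genes(present)
    means = np.nanmean(sub.values, axis=0)
    sd = means.std(ddof=1)
    if sd == 0:
        raise ValueError(f"metagene {gene_set.name!r} is constant across samples")
    z = (means - means.mean()) / sd
    return pd.Series(z, index=expr.sample_ids, name=gene_set.name)


def immunoproteasome_set() -> GeneSet:
    """The five interferon-inducible immunoproteasome components: the three
    inducible catalytic subunits plus the PA28 alpha/beta activator genes."""
    return GeneSet(
        "immunoproteasome_inducible",
        ("PSMB8", "PSMB9", "PSMB10", "PSME1", "PSME2"),
    )


def build_feature_table(
    variants: pd.DataFrame | None = None,
    ranks: pd.DataFrame | None = None,
    territory_mb: float = 33.0,
    ccf_threshold: float = 0.85,
    rank_threshold: float = 2.0,
    metagenes: pd.DataFrame | None = None,
    binary_features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-sample feature table consumed by the screen.

    Burden features (TMB, clonal/subclonal burden, neoantigen binders) are
    emitted on the natural-log one-per-MB pseudocount scale with a
    ``log_`` prefix; metagene z-scores and tagged binary indicators pass
    through unchanged.
    """
    pieces = []
    if variants is not None:
        tmb = compute_tmb(variants, territory_mb)
        pieces.append(tmb["log_tmb"].rename("log_tmb"))
        _, clon = classify_clonality(variants, ccf_threshold)
        pieces.append(
            pd.Series(log_burden(clon["clonal"] / territory_mb), index=clon.index,
                      name="log_clonal_burden")
        )
        pieces.append(
            pd.Series(log_burden(clon["subclonal"] / territory_mb), index=clon.index,
                      name="log_subclonal_burden")
        )
        subclones = variants.groupby("sample_id")["ccf_cluster_id"].nunique()
        pieces.append(subclones.rename("subclone_count").astype(float))
    if ranks is not None and variants is not None:
        samples = variants["sample_id"].unique()
        binders = pd.Series(
            {s: count_neoantigen_binders(ranks, s, rank_threshold) for s in samples}
        )
        pieces.append(
            pd.Series(log_burden(binders / territory_mb), index=binders.index,
                      name="log_neoantigen_burden")
        )
    if metagenes is not None:
        pieces.append(metagenes)
    if binary_features is not None:
        pieces.append(binary_features)
    if not pieces:
        raise ValueError("no inputs supplied")
    table = pd.concat(pieces, axis=1)
    table.index.name = "sample_id"
    return table
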