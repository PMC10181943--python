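"""Expression subtyping by consensus clustering and Bayesian NMF.

The full procedure: restrict to differentially expressed (M variant) or
high-variance (TI variant) genes, drop sparse/low genes, median-center to
fold changes, build a consensus co-clustering matrix over K = 2..10 with
resampled hierarchical clustering on Spearman distance, determine the
cluster number by ARD B-NMF of the summed consensus matrix, factorize the
expression matrix at that K, extract per-cluster marker genes from W, and
classify held-out samples by nonnegative least squares against the marker
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .ardnmf import FactorizationResult, factorize_restarts, ml_refit, select_best_run
from .config import PipelineConfig
from .io import ExpressionMatrix


@dataclass
class ConsensusResult:
    per_k_consensus: dict[int, np.ndarray]
    summed_normalized: np.ndarray
    sample_ids: list[str]
    k_range: tuple[int, ...]
    iterations_per_k: int
    resample_fraction: float


@dataclass
class SubtypeModel:
    """Per-cluster marker genes plus the restricted W used for classification."""

    K: int
    cluster_labels: list[str]
    marker_genes: dict[str, list[str]]
    W_markers: pd.DataFrame  # markers x K
    training_assignments: pd.Series  # sample_id -> cluster label
    prefix: str = "M"

    def __post_init__(self) -> None:
        all_markers = [g for genes in self.marker_genes.values() for g in genes]
        if len(set(all_markers)) != len(all_markers):
            raise ValueError("marker lists must be disjoint across clusters")
        missing = set(all_markers) - set(self.W_markers.index)
        if missing:
            raise ValueError(f"markers absent from W_markers: {sorted(missing)[:5]}")

    @property
    def markers(self) -> list[str]:
        return list(self.W_markers.index)


# --- Gene filtering -----------------------------------------------------------


def filter_de_genes(
    expr: ExpressionMatrix,
    de: pd.DataFrame,
    p_thresh: float = 0.05,
    lfc_thresh: float = 0.5,
) -> list[str]:
    """Genes with DE p < ``p_thresh`` and |log-fold-change| > ``lfc_thresh``
    (both strict, as specified).  ``de`` must index every gene of ``expr``
    and carry columns ``p`` and ``lfc``."""
    missing = set(expr.gene_ids) - set(de.index)
    if missing:
        raise KeyError(f"genes missing from DE table: {sorted(missing)[:5]}")
    sub = de.loc[expr.gene_ids]
    keep = (sub["p"] < p_thresh) & (sub["lfc"].abs() > lfc_thresh)
    return [g for g, k in zip(expr.gene_ids, keep.to_numpy()) if k]


def filter_low_quality_genes(
    expr: ExpressionMatrix,
    max_na_or_zero_fraction: float = 0.10,
    low_mean_quantile: float = 0.10,
) -> list[str]:
    """Drop sparse/low genes: NA-or-zero fraction above the cut, or mean
    expression in the bottom decile of the input genes."""
    if expr.n_genes < 10:
        raise ValueError("need at least 10 genes to apply the low-quality filter")
    V = expr.values
    na_or_zero = (np.isnan(V) | (V == 0)).mean(axis=1)
    means = np.nanmean(np.where(np.isnan(V), np.nan, V), axis=1)
    cut = np.quantile(means, low_mean_quantile)
    keep = (na_or_zero <= max_na_or_zero_fraction) & (means > cut)
    return [g for g, k in zip(expr.gene_ids, keep) if k]


def filter_high_variance_genes(expr: ExpressionMatrix, top_n: int = 2000) -> list[str]:
    """Top-``top_n`` genes by variance across samples (TI seed gene list)."""
    if top_n > expr.n_genes:
        raise ValueError(f"variance_top_n={top_n} exceeds {expr.n_genes} genes")
    variances = np.nanvar(expr.values, axis=1)
    order = np.argsort(variances)[::-1][:top_n]
    order.sort()
    return [expr.gene_ids[i] for i in order]


def median_center(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene fold changes: subtract each gene's median across samples."""
    V = expr.values
    n_obs = (~np.isnan(V)).sum(axis=1)
    if (n_obs < 2).any():
        bad = expr.gene_ids[int(np.argmax(n_obs < 2))]
        raise ValueError(f"gene {bad!r} has fewer than 2 observed values")
    med = np.nanmedian(V, axis=1, keepdims=True)
    return ExpressionMatrix.unchecked(expr.gene_ids, expr.sample_ids, V - med)


# --- Consensus clustering -----------------------------------------------------


def _spearman_distance(fc_values: np.ndarray) -> np.ndarray:
    """1 - Spearman correlation between samples (columns)."""
    corr = spearmanr(fc_values, axis=0, nan_policy="omit").statistic
    corr = np.atleast_2d(corr)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def consensus_matrix(
    fc: ExpressionMatrix,
    k_range=range(2, 11),
    iterations: int = 500,
    resample_fraction: float = 0.8,
    seed: int = 0,
    linkage: str = "average",
) -> ConsensusResult:
    """Co-clustering frequencies over resampled hierarchical clusterings.

    Each iteration subsamples ``resample_fraction`` of the samples without
    replacement, clusters them on 1 - Spearman distance with the given
    linkage, cuts at K, and records co-membership.  Per-K consensus is
    co-membership count / co-sampling count; the summed matrix is the sum of
    co-membership counts over all K divided by the total iteration count.
    """
    k_range = tuple(k_range)
    n = fc.n_samples
    if max(k_range) > n - 1 or min(k_range) < 2:
        raise ValueError(f"K range {k_range} outside [2, {n - 1}]")
    rng = np.random.default_rng(seed)
    dist_full = _spearman_distance(fc.values)
    m = max(2, int(round(resample_fraction * n)))

    co_count = {k: np.zeros((n, n)) for k in k_range}
    seen_count = {k: np.zeros((n, n)) for k in k_range}
    for k in k_range:
        for _ in range(iterations):
            idx = rng.choice(n, size=m, replace=False)
            idx.sort()
            seen_count[k][np.ix_(idx, idx)] += 1
            sub = dist_full[np.ix_(idx, idx)]
            Z = sch.linkage(squareform(sub, checks=False), method=linkage)
            labels = sch.fcluster(Z, t=min(k, m), criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co_count[k][np.ix_(idx, idx)] += same

    per_k = {}
    for k in k_range:
        seen = seen_count[k]
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(seen > 0, co_count[k] / np.maximum(seen, 1), 0.0)
        np.fill_diagonal(c, 1.0)
        per_k[k] = np.clip(c, 0.0, 1.0)
    summed = sum(co_count.values()) / (iterations * len(k_range))
    np.fill_diagonal(summed, 1.0)
    return ConsensusResult(
        per_k_consensus=per_k,
        summed_normalized=summed,
        sample_ids=list(fc.sample_ids),
        k_range=k_range,
        iterations_per_k=iterations,
        resample_fraction=resample_fraction,
    )


def determine_k(
    consensus: ConsensusResult | np.ndarray,
    n_restarts: int = 10,
    seed: int = 0,
    k_max: int = 10,
    **nmf_kwargs,
) -> int:
    """Cluster number: effective rank of the summed consensus matrix under
    ARD B-NMF with a half-normal prior, with multi-restart modal selection."""
    M = (
        consensus.summed_normalized
        if isinstance(consensus, ConsensusResult)
        else np.asarray(consensus)
    )
    runs = factorize_restarts(
        M,
        n_restarts=n_restarts,
        seed=seed,
        prior="half-normal",
        divergence="gaussian",
        K_max=k_max,
        **nmf_kwargs,
    )
    return select_best_run(runs).K_eff


# --- Subtype derivation and classification ------------------------------------


def hierarchical_labels(fc: ExpressionMatrix, K: int, linkage: str = "average") -> np.ndarray:
    """Cut an average-linkage tree on 1 - Spearman distance into K clusters
    (0-based labels); the warm start for the membership factorization."""
    dist = _spearman_distance(fc.values)
    Z = sch.linkage(squareform(dist, checks=False), method=linkage)
    return sch.fcluster(Z, t=K, criterion="maxclust") - 1


def derive_subtypes(
    expr: ExpressionMatrix,
    K: int,
    n_restarts: int = 10,
    seed: int = 0,
    init_labels: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    **nmf_kwargs,
) -> tuple[FactorizationResult, np.ndarray]:
    """B-NMF of the (gene-filtered) log2TPM matrix at K_max = K; samples are
    assigned to the argmax of the normalized H columns.

    The cluster number is fixed upstream, so restarts are compared by
    reconstruction fit at that rank (each restart ML-refit on its active
    components).  ``init_labels`` adds a warm-started candidate whose H is
    initialized from a hard clustering and whose W columns start at the
    cluster centroids; this anchors the factorization to the co-clustering
    structure instead of the shared-baseline local optima that random
    initializations tend to find.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    V = np.nan_to_num(expr.values, nan=0.0)
    runs = factorize_restarts(
        V,
        n_restarts=n_restarts,
        seed=seed,
        refit=False,
        prior="half-normal",
        divergence="gaussian",
        K_max=K,
        tol=tol,
        max_iter=max_iter,
        **nmf_kwargs,
    )
    candidates = [ml_refit(r, V, tol=tol) for r in runs]
    if init_labels is not None and K > 1:
        candidates.append(_warm_start_candidate(V, K, np.asarray(init_labels), tol))
    best = min(
        candidates,
        key=lambda r: float(((V - r.W @ r.H) ** 2).sum()),
    )
    return best, best.sample_assignments()


def _warm_start_candidate(
    V: np.ndarray, K: int, labels: np.ndarray, tol: float
) -> FactorizationResult:
    overall = V.mean(axis=1)
    W0 = np.empty((V.shape[0], K))
    for k in range(K):
        members = labels == k
        W0[:, k] = V[:, members].mean(axis=1) if members.any() else overall
    H0 = np.eye(K)[:, labels] + 0.01
    res = FactorizationResult(
        W=W0,
        H=H0,
        relevance=np.ones(K),
        active_components=np.arange(K),
        K_eff=K,
        objective_trace=np.array([float(((V - W0 @ H0) ** 2).sum())]),
        converged=True,
        log_posterior=-float(((V - W0 @ H0) ** 2).sum()),
        seed=-1,
        prior="half-normal",
        divergence="gaussian",
        extras={"warm_start": True},
    )
    return ml_refit(res, V, tol=tol)


def extract_markers(
    fact: FactorizationResult,
    expr: ExpressionMatrix,
    assignments: np.ndarray,
    top_fraction: float = 0.5,
    markers_per_cluster: int = 50,
    prefix: str = "M",
) -> SubtypeModel:
    """Marker genes per cluster from the W matrix.

    Candidates are genes at or above the within-cluster median of normalized
    W weights (top 50%); each gene is owned by the single cluster where its
    normalized weight is largest; candidates must have a positive
    within-minus-outside mean expression difference and the top
    ``markers_per_cluster`` by that difference are kept.
    """
    if len(assignments) != expr.n_samples:
        raise ValueError("assignments must cover all samples")
    W = fact.W_active  # genes x K, columns sum to 1
    K = W.shape[1]
    V = np.nan_to_num(expr.values, nan=np.nan)
    owner = np.argmax(W, axis=1)

    # clusters ordered by decreasing training sample count for naming
    counts = np.bincount(assignments, minlength=K)
    order = np.argsort(-counts, kind="stable")
    labels = [f"{prefix}-{i + 1}" for i in range(K)]
    comp_to_label = {comp: labels[rank] for rank, comp in enumerate(order)}

    marker_genes: dict[str, list[str]] = {lab: [] for lab in labels}
    w_rows: dict[str, np.ndarray] = {}
    for comp in range(K):
        col = W[:, comp]
        cut = np.quantile(col, 1.0 - top_fraction)
        in_mask = assignments == comp
        if not in_mask.any() or in_mask.all():
            raise ValueError(f"cluster {comp} has no inside/outside contrast")
        mean_in = np.nanmean(V[:, in_mask], axis=1)
        mean_out = np.nanmean(V[:, ~in_mask], axis=1)
        diff = mean_in - mean_out
        cand = np.flatnonzero((col >= cut) & (owner == comp) & (diff > 0))
        if cand.size == 0:
            raise ValueError(f"cluster {comp} has no qualifying marker genes")
        top = cand[np.argsort(-diff[cand], kind="stable")][:markers_per_cluster]
        top.sort()
        lab = comp_to_label[comp]
        marker_genes[lab] = [expr.gene_ids[i] for i in top]
        for i in top:
            w_rows[expr.gene_ids[i]] = W[i, :]

    marker_list = [g for lab in labels for g in marker_genes[lab]]
    W_markers = pd.DataFrame(
        np.vstack([w_rows[g] for g in marker_list]),
        index=marker_list,
        columns=[comp_to_label[c] for c in range(K)],
    )[labels]
    train = pd.Series(
        [comp_to_label[a] for a in assignments], index=expr.sample_ids, name="cluster"
    )
    return SubtypeModel(
        K=K,
        cluster_labels=labels,
        marker_genes=marker_genes,
        W_markers=W_markers,
        training_assignments=train,
        prefix=prefix,
    )


def classify_samples(model: SubtypeModel, expr_new: ExpressionMatrix) -> pd.Series:
    """Assign new samples to subtypes by NNLS projection onto W_markers.

    Requires at least half of the model's marker genes in ``expr_new``;
    assignment is the argmax of the normalized NNLS coefficients, ties
    broken toward the lowest cluster index.
    """
    available = [g for g in model.markers if g in set(expr_new.gene_ids)]
    coverage = len(available) / len(model.markers)
    if coverage < 0.5:
        raise ValueError(
            f"only {coverage:.0%} of model markers present; need at least 50%"
        )
    W = model.W_markers.loc[available].to_numpy()
    sub = expr_new.subset_genes(available)
    V = np.nan_to_num(sub.values, nan=0.0)
    if (V < 0).any():
        raise ValueError("expression for classification must be nonnegative")
    out = []
    for j in range(sub.n_samples):
        h, _ = nnls(W, V[:, j])
        total = h.sum()
        props = h / total if total > 0 else h
        out.append(model.cluster_labels[int(np.argmax(props))])
    return pd.Series(out, index=expr_new.sample_ids, name="cluster")


# --- End-to-end drivers -------------------------------------------------------


@dataclass
class SubtypeRun:
    gene_list: list[str]
    consensus: ConsensusResult
    K: int
    factorization: FactorizationResult
    model: SubtypeModel


def derive_m_subtypes(
    expr: ExpressionMatrix,
    de: pd.DataFrame,
    config: PipelineConfig | None = None,
    seed: int = 0,
    prefix: str = "M",
) -> SubtypeRun:
    """The microenvironmental (M) variant: DE-gene seed list, then the shared
    consensus -> B-NMF -> marker pipeline."""
    cfg = config or PipelineConfig()
    genes = filter_de_genes(expr, de, cfg.de_p_threshold, cfg.de_lfc_threshold)
    return _run_subtype_pipeline(expr, genes, cfg, seed, prefix)


def derive_ti_subtypes(
    expr_reference: ExpressionMatrix,
    config: PipelineConfig | None = None,
    seed: int = 0,
    variance_top_n: int | None = None,
    prefix: str = "TI",
) -> SubtypeRun:
    """The tumor-intrinsic (TI) variant: identical pipeline but seeded with
    the top high-variance genes of a reference collection."""
    cfg = config or PipelineConfig()
    if expr_reference.n_samples < 100:
        raise ValueError("TI derivation expects a reference collection of >= 100 samples")
    if variance_top_n is not None:
        top_n = variance_top_n  # explicit request: out-of-range errors
    else:
        top_n = min(cfg.variance_top_n, expr_reference.n_genes)
    genes = filter_high_variance_genes(expr_reference, top_n)
    return _run_subtype_pipeline(expr_reference, genes, cfg, seed, prefix)


def _run_subtype_pipeline(
    expr: ExpressionMatrix,
    seed_genes: list[str],
    cfg: PipelineConfig,
    seed: int,
    prefix: str,
) -> SubtypeRun:
    sub = expr.subset_genes(seed_genes)
    genes = filter_low_quality_genes(
        sub, cfg.max_na_or_zero_fraction, cfg.low_mean_quantile
    )
    sub = sub.subset_genes(genes)
    fc = median_center(sub)
    cons = consensus_matrix(
        fc,
        k_range=cfg.k_range,
        iterations=cfg.consensus_iterations,
        resample_fraction=cfg.resample_fraction,
        seed=seed,
    )
    K = determine_k(
        cons,
        n_restarts=cfg.nmf_restarts,
        seed=seed + 1,
        k_max=cfg.k_max,
        tol=cfg.nmf_tol,
        max_iter=cfg.nmf_max_iter,
        prune_fraction=cfg.prune_fraction,
    )
    init = hierarchical_labels(fc, K) if K > 1 else None
    fact, assignments = derive_subtypes(
        sub,
        K,
        n_restarts=cfg.nmf_restarts,
        seed=seed + 2,
        init_labels=init,
        tol=cfg.nmf_tol,
        max_iter=cfg.nmf_max_iter,
        prune_fraction=cfg.prune_fraction,
    )
    model = extract_markers(
        fact,
        sub,
        assignments,
        top_fraction=cfg.marker_top_fraction,
        markers_per_cluster=cfg.markers_per_cluster,
        prefix=prefix,
    )
    return SubtypeRun(genes, cons, K, fact, model)
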