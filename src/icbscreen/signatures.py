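"""SBS96 mutational-signature extraction, labeling and attribution.

Extraction runs the ARD-NMF engine with Poisson divergence and an
exponential prior on the transposed catalog (channels x samples) from many
random initializations, then keeps the modal-rank, maximum-posterior run.
Extracted signatures are labeled by cosine similarity against a reference
set, and each sample's mutation burden is attributed to signatures in
proportion to its normalized exposures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .ardnmf import FactorizationResult, factorize_restarts, select_best_run
from .io import MutationCatalog, SBS96_CHANNELS


@dataclass
class SignatureSet:
    """Named reference signatures, each a distribution over the 96 channels."""

    labels: tuple[str, ...]
    matrix: np.ndarray  # S x 96, row-stochastic

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[1] != 96:
            raise ValueError("signature matrix must be S x 96")
        if (M < 0).any() or not np.allclose(M.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("signatures must be nonnegative and row-stochastic")
        if len(set(self.labels)) != len(self.labels) or len(self.labels) != M.shape[0]:
            raise ValueError("labels must be unique, one per signature")
        self.matrix = M

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels), columns=list(SBS96_CHANNELS))

    @classmethod
    def from_file(cls, path) -> "SignatureSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.columns) != list(SBS96_CHANNELS):
            raise ValueError("signature file must have the 96 canonical channel columns")
        return cls(tuple(df.index.astype(str)), df.to_numpy())

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="signature")


def extract_signatures(
    catalog: MutationCatalog,
    n_restarts: int = 20,
    seed: int = 0,
    k_max: int = 15,
    **nmf_kwargs,
) -> FactorizationResult:
    """Unsupervised extraction: ARD-NMF (Poisson, exponential prior) on the
    channels x samples count matrix from ``n_restarts`` seeded
    initializations; the modal-K maximum-posterior run is returned."""
    if len(catalog.sample_ids) < 10:
        raise ValueError("signature extraction expects at least 10 samples")
    V = catalog.counts.T.astype(float)  # 96 x samples
    runs = factorize_restarts(
        V,
        n_restarts=n_restarts,
        seed=seed,
        prior="exponential",
        divergence="poisson",
        K_max=k_max,
        **nmf_kwargs,
    )
    return select_best_run(runs)


def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between rows of A and rows of B."""
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-12)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-12)
    return An @ Bn.T


def label_signatures(
    W: np.ndarray,
    reference: SignatureSet,
    min_cosine: float = 0.8,
) -> pd.DataFrame:
    """Label extracted signatures (channels x K, columns summing to 1) by
    their best-matching reference; below ``min_cosine`` -> 'unassigned'."""
    W = np.asarray(W, dtype=float)
    if W.shape[0] != 96:
        raise ValueError("extracted signature matrix must have 96 channel rows")
    if not np.allclose(W.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("extracted signature columns must be normalized to sum 1")
    sims = cosine_similarity_matrix(W.T, reference.matrix)  # K x S
    best = np.argmax(sims, axis=1)
    best_sim = sims[np.arange(sims.shape[0]), best]
    labels = [
        reference.labels[j] if s >= min_cosine else "unassigned"
        for j, s in zip(best, best_sim)
    ]
    return pd.DataFrame(
        {
            "extracted": [f"W{k + 1}" for k in range(W.shape[1])],
            "label": labels,
            "cosine": best_sim,
        }
    )


def attribute_burden(fact: FactorizationResult, catalog: MutationCatalog) -> pd.DataFrame:
    """Per-sample signature-attributable counts.

    Each sample's normalized exposure proportions (its H column) are scaled
    by its total mutation count, so attribution conserves totals exactly;
    a zero-mutation sample gets an all-zero row.
    """
    H = fact.H_active  # K x samples
    if H.shape[1] != len(catalog.sample_ids):
        raise ValueError("factorization does not match catalog samples")
    totals = catalog.totals.astype(float)
    colsum = H.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(colsum > 0, H / np.maximum(colsum, 1e-300), 0.0)
    attributed = (props * totals[None, :]).T  # samples x K
    return pd.DataFrame(
        attributed,
        index=list(catalog.sample_ids),
        columns=[f"W{k + 1}" for k in range(H.shape[0])],
    )


def match_signatures(W: np.ndarray, reference: SignatureSet) -> dict[int, int]:
    """Optimal one-to-one matching of extracted columns to reference rows by
    Hungarian assignment on cosine similarity (used for recovery checks)."""
    sims = cosine_similarity_matrix(np.asarray(W).T, reference.matrix)
    rows, cols = linear_sum_assignment(-sims)
    return dict(zip(rows.tolist(), cols.tolist()))
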