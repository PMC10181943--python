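"""Domain containers and TSV readers/writers shared by every pipeline stage.

All on-disk formats are plain TSV. Expression values are log2(TPM+1);
raw-TPM input is supported behind an explicit flag on :func:`read_expression`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


# --- SBS96 channel convention -------------------------------------------------

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")


def sbs96_channels() -> list[str]:
    """Canonical SBS96 channel labels, e.g. ``A[C>A]A``.

    Order follows the COSMIC lexicographic convention: the six pyrimidine
    substitutions in alphabetical order, each expanded over the sixteen
    5'/3' flanking-base contexts in alphabetical order.
    """
    return [
        f"{five}[{sub}]{three}"
        for sub in _SUBSTITUTIONS
        for five, three in itertools.product(_BASES, _BASES)
    ]


SBS96_CHANNELS: tuple[str, ...] = tuple(sbs96_channels())


# --- Containers ---------------------------------------------------------------


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ParseError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2(TPM+1) values; NaN marks missing."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ParseError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and finite.min() < 0:
            raise ParseError("expression values must be >= 0 (log2(TPM+1) scale)")

    @classmethod
    def unchecked(cls, gene_ids, sample_ids, values) -> "ExpressionMatrix":
        """Construct without the nonnegativity check (fold-change matrices)."""
        obj = cls.__new__(cls)
        obj.gene_ids = list(gene_ids)
        obj.sample_ids = list(sample_ids)
        obj.values = np.asarray(values, dtype=float)
        _check_unique(obj.gene_ids, "gene")
        _check_unique(obj.sample_ids, "sample")
        return obj

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])


@dataclass
class MutationCatalog:
    """Samples x 96 SBS trinucleotide-context mutation counts."""

    sample_ids: list[str]
    counts: np.ndarray
    channel_labels: tuple[str, ...] = SBS96_CHANNELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.channel_labels) != 96:
            raise ParseError("mutation catalog must have exactly 96 channels")
        if self.counts.shape != (len(self.sample_ids), 96):
            raise ParseError(
                f"catalog shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x 96 channels"
            )
        if np.any(self.counts < 0):
            raise ParseError("mutation counts must be >= 0")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ParseError("mutation counts must be integral")
        self.counts = np.round(self.counts).astype(np.int64)
        _check_unique(self.sample_ids, "sample")

    @property
    def totals(self) -> np.ndarray:
        """Per-sample total SBS count."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=list(self.channel_labels)
        )


VARIANT_CLASSES = ("nonsynonymous_snv", "dnv", "indel", "other")
VARIANT_COLUMNS = ("sample_id", "gene", "variant_class", "ccf_cluster_id", "cluster_ccf")

BOR_CATEGORIES = ("CR", "PR", "SD", "PD")
RESPONDER_BOR = frozenset({"CR", "PR"})

CLINICAL_COLUMNS = ("sample_id", "bor", "response", "pfs_time", "pfs_event", "pdl1_tps")

RANK_COLUMNS = ("sample_id", "variant_id", "allele", "percentile_rank")


def validate_variants(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a MAF-lite variant table with CCF cluster assignments."""
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"variant table missing columns: {missing}")
    bad = set(df["variant_class"]) - set(VARIANT_CLASSES)
    if bad:
        raise ParseError(f"unknown variant_class values: {sorted(bad)}")
    ccf = df["cluster_ccf"].to_numpy(dtype=float)
    if np.any((ccf < 0) | (ccf > 1)):
        raise ParseError("cluster_ccf must lie in [0, 1]")
    return df


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"clinical table missing columns: {missing}")
    bad = set(df["bor"]) - set(BOR_CATEGORIES)
    if bad:
        raise ParseError(f"unknown BOR categories: {sorted(bad)}")
    expected = df["bor"].isin(RESPONDER_BOR).astype(int)
    if not (df["response"].astype(int) == expected).all():
        raise ParseError("response column inconsistent with BOR binning (CR/PR=1, SD/PD=0)")
    if (df["pfs_time"].to_numpy(dtype=float) < 0).any():
        raise ParseError("pfs_time must be >= 0")
    tps = df["pdl1_tps"].to_numpy(dtype=float)
    ok = np.isnan(tps) | ((tps >= 0) & (tps <= 100))
    if not ok.all():
        raise ParseError("pdl1_tps must be in [0, 100] or missing")
    _check_unique(df["sample_id"], "sample")
    return df


def validate_ranks(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RANK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"rank table missing columns: {missing}")
    if (df["percentile_rank"].to_numpy(dtype=float) < 0).any():
        raise ParseError("percentile_rank must be >= 0")
    if df.duplicated(subset=["sample_id", "variant_id", "allele"]).any():
        raise ParseError("(sample, variant, allele) rows must be unique")
    return df


@dataclass
class GeneSet:
    name: str
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        members = tuple(self.members)
        if not members:
            raise ParseError(f"gene set {self.name!r} is empty")
        if len(set(members)) != len(members):
            raise ParseError(f"gene set {self.name!r} has duplicate members")
        self.members = members

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


# --- Readers / writers --------------------------------------------------------


def read_expression(path, *, raw_tpm: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene symbols, header samples).

    With ``raw_tpm=True`` the body is interpreted as TPM and transformed to
    log2(TPM+1) on read.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate gene identifier: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"duplicate sample identifier: {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ParseError(
                    f"non-numeric expression value at gene {row!r}, sample {col!r}"
                ) from exc
        raise ParseError(f"could not parse expression matrix: {exc}") from exc
    if raw_tpm:
        if np.nanmin(values) < 0:
            raise ParseError("raw TPM values must be >= 0")
        values = np.log2(values + 1.0)
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_expression(expr: ExpressionMatrix, path) -> None:
    # %.17g preserves doubles exactly, so read(write(x)) is bit-identical
    expr.to_frame().to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_mutation_catalog(path) -> MutationCatalog:
    """Read a samples x 96 TSV with canonical SBS96 channel headers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(SBS96_CHANNELS):
        raise ParseError(
            "mutation catalog header must list the 96 SBS channels in canonical order"
        )
    return MutationCatalog(list(df.index.astype(str)), df.to_numpy())


def write_mutation_catalog(catalog: MutationCatalog, path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index_label="sample")


def read_variants(path) -> pd.DataFrame:
    return validate_variants(pd.read_csv(path, sep="\t"))


def read_clinical(path) -> pd.DataFrame:
    return validate_clinical(pd.read_csv(path, sep="\t"))


def read_ranks(path) -> pd.DataFrame:
    return validate_ranks(pd.read_csv(path, sep="\t"))


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, members; tab-separated)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line {lineno}: expected name, description and >=1 member"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"GMT line {lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name, tuple(members)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.members]) + "\n")
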