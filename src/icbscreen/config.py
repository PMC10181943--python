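"""Pipeline configuration with validated defaults, plus deterministic seeding.

A single master seed is split per named stage with ``numpy.random.SeedSequence``
so the whole pipeline is reproducible from one integer while stages stay
statistically independent.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis, with their default values.

    Defaults follow the published procedure where it states them
    (DE cutoffs, consensus K range and iteration count, CCF clonality cut,
    neoantigen rank cut, prevalence filter, FDR tiers) and documented
    conventions elsewhere (exome territory, resampling fraction, marker count).
    """

    seed: int = 0
    # differential-expression gene selection
    de_p_threshold: float = 0.05
    de_lfc_threshold: float = 0.5
    # low-quality gene filter
    max_na_or_zero_fraction: float = 0.10
    low_mean_quantile: float = 0.10
    # consensus clustering
    k_min: int = 2
    k_max: int = 10
    consensus_iterations: int = 500
    resample_fraction: float = 0.8
    # B-NMF
    nmf_restarts: int = 10
    nmf_max_iter: int = 100_000
    nmf_tol: float = 1e-7
    prune_fraction: float = 0.01
    # subtype markers
    marker_top_fraction: float = 0.5
    markers_per_cluster: int = 50
    variance_top_n: int = 2000
    min_marker_coverage: float = 0.5
    # mutational signatures
    signature_restarts: int = 20
    min_label_cosine: float = 0.8
    # genomic features
    territory_mb: float = 33.0
    ccf_clonal_threshold: float = 0.85
    binder_rank_threshold: float = 2.0
    # association screen
    min_expressed_log2tpm: float = 0.5
    min_expressed_fraction: float = 0.30
    min_prevalence: float = 0.05
    fdr_significant: float = 0.1
    fdr_near_significant: float = 0.25

    def __post_init__(self) -> None:
        if self.k_min > self.k_max:
            raise ValueError(f"empty K range ({self.k_min}, {self.k_max})")
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if not 0 < self.resample_fraction <= 1:
            raise ValueError("resample_fraction must be in (0, 1]")
        for name in (
            "de_p_threshold",
            "max_na_or_zero_fraction",
            "low_mean_quantile",
            "min_prevalence",
            "fdr_significant",
            "fdr_near_significant",
            "ccf_clonal_threshold",
            "marker_top_fraction",
            "min_marker_coverage",
            "min_expressed_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.territory_mb <= 0:
            raise ValueError("territory_mb must be > 0")
        for name in ("consensus_iterations", "nmf_restarts", "signature_restarts",
                     "markers_per_cluster", "variance_top_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    """Load a YAML/JSON config file; unknown keys are rejected.

    An empty file yields the documented defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


@dataclass
class SeedSplitter:
    """Deterministic per-stage seed derivation from one master seed."""

    master_seed: int
    _cache: dict = field(default_factory=dict, repr=False)

    def seed_for(self, stage: str) -> int:
        """A stable 31-bit seed for a named stage."""
        if stage not in self._cache:
            digest = hashlib.sha256(stage.encode()).digest()
            ss = np.random.SeedSequence(
                self.master_seed, spawn_key=(int.from_bytes(digest[:4], "little"),)
            )
            self._cache[stage] = int(ss.generate_state(1)[0] % (2**31))
        return self._cache[stage]

    def rng_for(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self.seed_for(stage))


def stage_seed(master_seed: int, stage: str) -> int:
    return SeedSplitter(master_seed).seed_for(stage)
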