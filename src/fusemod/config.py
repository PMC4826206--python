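"""Pipeline configuration and stage-level seeding.

All tunable knobs of the pipeline live in :class:`PipelineConfig` so that a
run is fully described by one YAML file plus a seed.  Every stochastic stage
derives its own seed from ``rng_seed`` through :func:`stage_seed`, which keeps
stages independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "stage_seed"]

_STAGE_OFFSETS = {
    "simulate": 11,
    "survival": 13,
    "network": 17,
    "fuse": 19,
    "cluster": 23,
    "score": 29,
    "modules": 31,
    "local_null": 37,
    "global_null": 41,
    "downstream": 43,
}


def stage_seed(rng_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the run seed.

    Distinct stages get decorrelated streams; the mapping is fixed so a run
    log can record every seed actually used.
    """
    if stage not in _STAGE_OFFSETS:
        raise ValueError(f"unknown stage {stage!r}; known: {sorted(_STAGE_OFFSETS)}")
    return (int(rng_seed) * 1_000_003 + _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class PipelineConfig:
    """All pipeline parameters with their defaults.

    Parameters
    ----------
    snf_mu:
        Bandwidth hyperparameter mu of the scaled exponential affinity kernel.
    snf_k:
        Neighborhood size for the local kernel and the scaling term; ``None``
        means the data-dependent default ceil(n/10) clipped to [10, 30].
    snf_iters:
        Number of cross-diffusion fusion iterations T.
    cluster_range:
        Candidate numbers of subtypes scanned by survival-guided selection.
    score_threshold:
        Inclusive cutoff on the normalized per-gene alteration score p0.
    linker_alpha:
        Benjamini-Hochberg adjusted-p cutoff for admitting linker genes.
    path_threshold:
        Number of altered genes a candidate linker must directly connect
        (path length 2 between altered pairs through one intermediate).
    null_iters:
        Iterations for both the rewiring and the random-gene-set null models.
    rng_seed:
        Master seed; every stage derives its own via :func:`stage_seed`.
    fold_change_cutoff, de_p_cutoff:
        Strict cutoffs of the up-regulated-miRNA filter.
    expression_log2:
        If true, differential fold changes are computed as 2**(mean2-mean1).
    """

    snf_mu: float = 0.5
    snf_k: int | None = None
    snf_iters: int = 20
    cluster_range: tuple[int, ...] = (2, 3, 4, 5)
    score_threshold: float = 2e-4
    linker_alpha: float = 0.05
    path_threshold: int = 2
    null_iters: int = 1000
    rng_seed: int = 0
    fold_change_cutoff: float = 1.2
    de_p_cutoff: float = 0.01
    expression_log2: bool = False

    def __post_init__(self) -> None:
        if not self.snf_mu > 0:
            raise ValueError(f"snf_mu must be positive, got {self.snf_mu}")
        if self.snf_k is not None and (int(self.snf_k) != self.snf_k or self.snf_k < 1):
            raise ValueError(f"snf_k must be a positive integer or None, got {self.snf_k}")
        if int(self.snf_iters) != self.snf_iters or self.snf_iters < 1:
            raise ValueError(f"snf_iters must be a positive integer, got {self.snf_iters}")
        self.cluster_range = tuple(sorted(set(int(c) for c in self.cluster_range)))
        if not self.cluster_range:
            raise ValueError("cluster_range must be non-empty")
        if any(c < 2 for c in self.cluster_range):
            raise ValueError(f"cluster_range values must be >= 2, got {self.cluster_range}")
        if self.score_threshold < 0:
            raise ValueError(f"score_threshold must be nonnegative, got {self.score_threshold}")
        if not 0 < self.linker_alpha <= 1:
            raise ValueError(f"linker_alpha must be in (0, 1], got {self.linker_alpha}")
        if int(self.path_threshold) != self.path_threshold or self.path_threshold < 1:
            raise ValueError(f"path_threshold must be a positive integer, got {self.path_threshold}")
        if int(self.null_iters) != self.null_iters or self.null_iters < 1:
            raise ValueError(f"null_iters must be a positive integer, got {self.null_iters}")
        if int(self.rng_seed) != self.rng_seed:
            raise ValueError(f"rng_seed must be an integer, got {self.rng_seed}")
        if not self.fold_change_cutoff > 0:
            raise ValueError(f"fold_change_cutoff must be positive, got {self.fold_change_cutoff}")
        if not 0 < self.de_p_cutoff < 1:
            raise ValueError(f"de_p_cutoff must be in (0, 1), got {self.de_p_cutoff}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "cluster_range" in raw:
            raw["cluster_range"] = tuple(raw["cluster_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["cluster_range"] = list(self.cluster_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
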