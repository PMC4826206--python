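"""High-level drivers wiring the pipeline stages together."""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .alterations import filter_altered_genes, gene_alteration_scores
from .config import PipelineConfig, stage_seed
from .modules import (
    ModulePartition,
    SubtypeNetwork,
    build_subtype_network,
    detect_modules,
)
from .snf import FusedNetwork, fuse_feature_views
from .subtypes import SubtypeAssignment, select_cluster_number, spectral_clusters

__all__ = ["fuse_and_cluster", "subtype_cohort", "discover_subtype_modules"]


def fuse_and_cluster(
    views: list[pd.DataFrame],
    C: int,
    mu: float = 0.5,
    k: int | None = None,
    iters: int = 20,
    seed: int = 0,
) -> tuple[FusedNetwork, SubtypeAssignment]:
    """Fuse the views and cluster the fused network at a fixed C."""
    fused = fuse_feature_views(views, mu=mu, k=k, iters=iters)
    assign = spectral_clusters(fused, C, seed=seed)
    return fused, assign


def subtype_cohort(
    views: list[pd.DataFrame],
    clinical: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> tuple[FusedNetwork, int, SubtypeAssignment, pd.DataFrame]:
    """Full subtyping stage: fuse, scan candidate C, pick the partition with
    the smallest log-rank p on overall survival."""
    cfg = config or PipelineConfig()
    fused = fuse_feature_views(views, mu=cfg.snf_mu, k=cfg.snf_k, iters=cfg.snf_iters)
    best_C, assign, scan = select_cluster_number(
        fused, clinical, cfg.cluster_range, seed=stage_seed(cfg.rng_seed, "cluster")
    )
    return fused, best_C, assign, scan


def discover_subtype_modules(
    net: nx.Graph,
    alterations: pd.DataFrame,
    subtype_samples: list[str],
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, SubtypeNetwork, ModulePartition]:
    """Score alterations within one subtype, threshold into an altered gene
    set, build the subtype network and partition it into modules."""
    cfg = config or PipelineConfig()
    scores = gene_alteration_scores(alterations, subtype_samples)
    altered = filter_altered_genes(scores, tau=cfg.score_threshold)
    subnet = build_subtype_network(
        net, altered.genes, alpha=cfg.linker_alpha, path_threshold=cfg.path_threshold
    )
    partition = detect_modules(subnet)
    return scores, subnet, partition
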