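"""Altered-module detection on a curated interaction network.

Given a subtype's altered gene set, the subtype network keeps direct
altered-altered interactions and admits *linker* genes: unaltered nodes
whose direct neighborhoods are enriched for altered genes (one-sided
hypergeometric test, Benjamini-Hochberg corrected).  The induced graph on
altered + linker genes is partitioned into modules by greedy
modularity-maximizing agglomeration with deterministic tie-breaking.

Two null models judge the result.  The *local* null rewires the subtype
network degree-preservingly (double-edge swaps) and re-detects modules,
yielding a modularity null distribution and a scaled modularity z-score.
The *global* null redraws equally many random "altered" genes from the full
network and rebuilds the subtype network, asking whether the observed
largest connected component is bigger than chance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "CandidateLinkers",
    "SubtypeNetwork",
    "ModulePartition",
    "NullDistribution",
    "extract_subnetwork",
    "linker_significance",
    "bh_adjust",
    "build_subtype_network",
    "modularity",
    "detect_modules",
    "local_null_modularity",
    "scaled_modularity",
    "global_null_connectivity",
]


@dataclass
class CandidateLinkers:
    """Altered genes present in the network plus nominated linker candidates."""

    altered: set
    candidates: set
    dropped_altered: int = 0


@dataclass
class SubtypeNetwork:
    graph: nx.Graph
    altered_nodes: set
    linker_nodes: set
    linker_table: pd.DataFrame


@dataclass
class ModulePartition:
    modules: list[set]
    Q: float


@dataclass
class NullDistribution:
    samples: np.ndarray
    n_iter: int
    seed: int
    observed: float | None = None
    p_upper: float | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1)) if len(self.samples) > 1 else 0.0


def extract_subnetwork(
    net: nx.Graph, altered: set | frozenset, path_threshold: int = 2
) -> CandidateLinkers:
    """Nominate linker candidates: unaltered nodes directly adjacent to at
    least ``path_threshold`` altered genes (a path of length 2 between
    altered pairs through one intermediate).  Altered genes absent from the
    network are dropped with a logged count."""
    altered = set(getattr(altered, "genes", altered))
    if not altered:
        raise ValueError("altered gene set is empty")
    present = altered & set(net.nodes())
    dropped = len(altered) - len(present)
    if dropped:
        log.info("extract_subnetwork: %d altered gene(s) not in network", dropped)
    if not present:
        raise ValueError("no altered genes present in the network")
    candidates = set()
    for v in net.nodes():
        if v in present:
            continue
        n_alt = sum(1 for u in net[v] if u in present)
        if n_alt >= path_threshold:
            candidates.add(v)
    return CandidateLinkers(altered=present, candidates=candidates, dropped_altered=dropped)


def _hypergeom_pvalues(
    net: nx.Graph, altered: set, candidates: list
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-sided enrichment p for each candidate's neighborhood."""
    N = net.number_of_nodes()
    K = len(altered)
    degrees = np.array([net.degree(v) for v in candidates], dtype=int)
    hits = np.array([sum(1 for u in net[v] if u in altered) for v in candidates], dtype=int)
    pvals = hypergeom.sf(hits - 1, N - 1, K, degrees)
    return np.clip(pvals, 0.0, 1.0), degrees, hits


def linker_significance(net: nx.Graph, altered: set | frozenset, candidate) -> float:
    """Probability of >= observed altered genes among the candidate's
    neighbors when its d neighbors are drawn from the N-1 other nodes, of
    which K are altered (hypergeometric upper tail)."""
    altered = set(getattr(altered, "genes", altered))
    if candidate in altered:
        raise ValueError(f"candidate {candidate!r} is itself altered")
    if net.degree(candidate) == 0:
        raise ValueError(f"candidate {candidate!r} has degree 0")
    p, _, _ = _hypergeom_pvalues(net, altered & set(net.nodes()), [candidate])
    return float(min(max(p[0], 0.0), 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_subtype_network(
    net: nx.Graph,
    altered: set | frozenset,
    alpha: float,
    path_threshold: int = 2,
) -> SubtypeNetwork:
    """Admit linkers at BH-adjusted p <= alpha and induce the subtype graph
    on altered + linker genes, keeping only nodes with at least one edge."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    cand = extract_subnetwork(net, altered, path_threshold=path_threshold)
    candidates = sorted(cand.candidates)
    if candidates:
        raw, degrees, hits = _hypergeom_pvalues(net, cand.altered, candidates)
        adj = bh_adjust(raw)
        linkers = {c for c, p in zip(candidates, adj) if p <= alpha}
        table = pd.DataFrame(
            {
                "gene": candidates,
                "degree": degrees,
                "altered_connections": hits,
                "p_raw": raw,
                "p_adj": adj,
            }
        )
        table["linker"] = table["gene"].isin(linkers)
    else:
        linkers = set()
        table = pd.DataFrame(
            columns=["gene", "degree", "altered_connections", "p_raw", "p_adj", "linker"]
        )
    nodes = cand.altered | linkers
    sub = nx.Graph(net.subgraph(nodes))
    sub.remove_nodes_from([v for v in list(sub.nodes()) if sub.degree(v) == 0])
    kept = set(sub.nodes())
    return SubtypeNetwork(
        graph=sub,
        altered_nodes=cand.altered & kept,
        linker_nodes=linkers & kept,
        linker_table=table,
    )


def modularity(G: nx.Graph, partition: list[set]) -> float:
    """Newman modularity Q = sum_c [e_c/E - (d_c/2E)^2] of a partition of the
    non-isolated nodes."""
    E = G.number_of_edges()
    if E == 0:
        raise ValueError("modularity undefined on an empty edge set")
    non_isolated = {v for v in G.nodes() if G.degree(v) > 0}
    seen: set = set()
    for c in partition:
        overlap = seen & set(c)
        if overlap:
            raise ValueError(f"partition blocks overlap on {sorted(overlap)[:3]}")
        seen |= set(c)
    if seen != non_isolated:
        raise ValueError("partition must cover exactly the non-isolated nodes")
    Q = 0.0
    for c in partition:
        cset = set(c)
        e_c = sum(1 for u, v in G.edges(cset) if u in cset and v in cset)
        d_c = sum(G.degree(v) for v in cset)
        Q += e_c / E - (d_c / (2.0 * E)) ** 2
    return Q


def detect_modules(subnet: SubtypeNetwork | nx.Graph) -> ModulePartition:
    """Greedy modularity-maximizing agglomeration (CNM-style).

    Starts from singletons and repeatedly merges the connected community
    pair with the largest modularity gain, with ties broken by the
    lexicographically smallest (min-node, min-node) pair; only communities
    joined by at least one edge may merge, so connected components are never
    merged across.  The best partition along the merge path is returned,
    modules sorted by decreasing size then smallest member."""
    G = subnet.graph if isinstance(subnet, SubtypeNetwork) else subnet
    E = G.number_of_edges()
    if E == 0:
        raise ValueError("cannot detect modules in an edgeless network")
    nodes = [v for v in G.nodes() if G.degree(v) > 0]

    comm_of = {v: i for i, v in enumerate(nodes)}
    members: dict[int, set] = {i: {v} for i, v in enumerate(nodes)}
    degsum = {i: float(G.degree(v)) for i, v in enumerate(nodes)}
    min_node = {i: v for i, v in enumerate(nodes)}
    between: dict[frozenset, int] = {}
    for u, v in G.edges():
        cu, cv = comm_of[u], comm_of[v]
        if cu != cv:
            key = frozenset((cu, cv))
            between[key] = between.get(key, 0) + 1

    two_E = 2.0 * E
    Q = -sum((d / two_E) ** 2 for d in degsum.values())
    best_Q = Q
    best_partition = [set(s) for s in members.values()]

    while between:
        best_pair = None
        best_dq = -np.inf
        best_key = None
        for pair, e12 in between.items():
            i, j = tuple(pair)
            dq = e12 / E - 2.0 * degsum[i] * degsum[j] / (two_E**2)
            key = tuple(sorted((str(min_node[i]), str(min_node[j]))))
            if dq > best_dq or (dq == best_dq and key < best_key):
                best_dq, best_pair, best_key = dq, pair, key
        i, j = tuple(best_pair)
        if len(members[i]) < len(members[j]) or (
            len(members[i]) == len(members[j]) and str(min_node[i]) > str(min_node[j])
        ):
            i, j = j, i  # absorb the smaller community into the larger
        members[i] |= members[j]
        degsum[i] += degsum[j]
        min_node[i] = min(min_node[i], min_node[j], key=str)
        for v in members[j]:
            comm_of[v] = i
        # fold j's between-community edge counts into i
        for pair in [p for p in between if j in p]:
            e = between.pop(pair)
            other = next(iter(pair - {j}))
            if other == i:
                continue
            key = frozenset((i, other))
            between[key] = between.get(key, 0) + e
        del members[j], degsum[j], min_node[j]
        Q += best_dq
        if Q > best_Q + 1e-12:
            best_Q = Q
            best_partition = [set(s) for s in members.values()]

    best_partition, best_Q = _refine_partition(G, best_partition, best_Q)
    # a second deterministic start from singletons escapes agglomeration
    # traps on small graphs; keep whichever refined partition scores higher
    singletons = [{v} for v in nodes]
    q_singl = -sum((G.degree(v) / two_E) ** 2 for v in nodes)
    alt_partition, alt_Q = _refine_partition(G, singletons, q_singl)
    if alt_Q > best_Q + 1e-12:
        best_partition, best_Q = alt_partition, alt_Q
    modules = sorted(best_partition, key=lambda s: (-len(s), min(map(str, s))))
    return ModulePartition(modules=modules, Q=float(best_Q))


def _refine_partition(
    G: nx.Graph, partition: list[set], Q: float
) -> tuple[list[set], float]:
    """Deterministic single-node local moves polishing the greedy partition.

    Each sweep visits nodes in sorted order and applies the best strictly
    positive modularity gain among moving the node to an adjacent module
    (or isolating it); sweeps repeat until none improves.  Keeps every
    module within its connected component since only adjacent moves are
    considered."""
    E = G.number_of_edges()
    two_E = 2.0 * E
    comm_of = {}
    comms: dict[int, set] = {}
    degsum: dict[int, float] = {}
    for cid, block in enumerate(partition):
        comms[cid] = set(block)
        degsum[cid] = float(sum(G.degree(v) for v in block))
        for v in block:
            comm_of[v] = cid
    next_id = len(partition)
    nodes = sorted(comm_of, key=str)
    improved = True
    while improved:
        improved = False
        for v in nodes:
            home = comm_of[v]
            d_v = float(G.degree(v))
            links: dict[int, int] = {}
            for u in G[v]:
                links[comm_of[u]] = links.get(comm_of[u], 0) + 1
            e_home = links.get(home, 0)
            # gain of removing v from its module
            remove_gain = -e_home / E + 2.0 * d_v * (degsum[home] - d_v) / (two_E**2)
            best_gain, best_target = 0.0, None
            for cid in sorted(links):
                if cid == home:
                    continue
                gain = remove_gain + links[cid] / E - 2.0 * d_v * degsum[cid] / (two_E**2)
                if gain > best_gain + 1e-12:
                    best_gain, best_target = gain, cid
            if len(comms[home]) > 1 and remove_gain > max(best_gain, 0.0) + 1e-12:
                best_gain, best_target = remove_gain, -1  # isolate v
            if best_target is None:
                continue
            comms[home].discard(v)
            degsum[home] -= d_v
            if not comms[home]:
                del comms[home], degsum[home]
            if best_target == -1:
                cid = next_id
                next_id += 1
                comms[cid] = {v}
                degsum[cid] = d_v
                comm_of[v] = cid
            else:
                comms[best_target].add(v)
                degsum[best_target] += d_v
                comm_of[v] = best_target
            Q += best_gain
            improved = True
    return [set(s) for s in comms.values()], Q


def local_null_modularity(
    subnet: SubtypeNetwork | nx.Graph, n_iter: int = 1000, seed: int = 0
) -> NullDistribution:
    """Modularity null: degree-preserving double-edge-swap rewirings of the
    subtype network, each re-partitioned from scratch."""
    G = subnet.graph if isinstance(subnet, SubtypeNetwork) else subnet
    E = G.number_of_edges()
    if E < 2:
        raise ValueError("rewiring null needs >= 2 edges")
    rng = np.random.default_rng(seed)
    samples = np.empty(n_iter)
    n_swaps = 10 * E
    for it in range(n_iter):
        H = G.copy()
        try:
            nx.double_edge_swap(
                H, nswap=n_swaps, max_tries=100 * n_swaps, seed=int(rng.integers(2**31))
            )
        except nx.NetworkXError:
            # graph too small/constrained to swap: score the original graph
            warnings.warn("degree-preserving swap impossible; recording original Q")
            H = G
        except nx.NetworkXAlgorithmError:
            pass  # max_tries hit: H is partially rewired, still degree-preserving
        samples[it] = detect_modules(H).Q
    return NullDistribution(samples=samples, n_iter=n_iter, seed=seed)


def scaled_modularity(q_obs: float, null: NullDistribution) -> float:
    """z-score of the observed modularity against the rewiring null."""
    sd = null.sd
    if sd <= 0:
        raise ValueError("null distribution has zero standard deviation")
    return (q_obs - null.mean) / sd


def global_null_connectivity(
    net: nx.Graph,
    n_altered: int,
    alpha: float,
    path_threshold: int = 2,
    n_iter: int = 1000,
    seed: int = 0,
    observed_size: int | None = None,
) -> NullDistribution:
    """Connectivity null: redraw ``n_altered`` random genes, rebuild the
    subtype network with the same cutoffs, and record the largest connected
    component size.  If ``observed_size`` is given, attaches the empirical
    upper-tail p-value (add-one rule)."""
    nodes = sorted(net.nodes(), key=str)
    if n_altered > len(nodes):
        raise ValueError(f"n_altered = {n_altered} exceeds network size {len(nodes)}")
    rng = np.random.default_rng(seed)
    sizes = np.empty(n_iter)
    for it in range(n_iter):
        draw = set(rng.choice(len(nodes), size=n_altered, replace=False).tolist())
        altered = {nodes[i] for i in draw}
        sub = build_subtype_network(net, altered, alpha=alpha, path_threshold=path_threshold)
        if sub.graph.number_of_nodes() == 0:
            sizes[it] = 0
        else:
            sizes[it] = max(len(c) for c in nx.connected_components(sub.graph))
    null = NullDistribution(samples=sizes, n_iter=n_iter, seed=seed)
    if observed_size is not None:
        null.observed = float(observed_size)
        null.p_upper = float((1 + np.sum(sizes >= observed_size)) / (n_iter + 1))
    return null
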