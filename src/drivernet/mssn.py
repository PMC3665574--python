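"""Mutation-seeded subnetworks (MSSN) and shortest-path significance.

An MSSN is the union of shortest paths in the PPI network from one mutated
gene (the seed) to the differentially expressed genes of one direction
(the targets). Its per-target shortest distances form a sample that is
compared against background random networks — replicates that draw one
random source and the same number of random distinct destinations — by the
Welch unequal-variance t statistic

    t = (x̄1 − x̄2) / sqrt(s1²/n1 + s2²/n2)

where sample 1 is the pooled background distances and sample 2 the MSSN
distances, with unbiased (n−1) variances. A positive t means the seed
reaches its targets by shorter-than-random paths. Two companion measures
are reported: a z-score of the observed mean distance against the
distribution of background replicate means, and an empirical p — the
fraction of background replicate means that are ≤ the observed mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .io import PPINetwork

UNREACHABLE = math.inf


@dataclass
class MSSN:
    """One seed gene's subnetwork toward the DE targets of one direction."""

    seed: str
    direction: str
    targets: set[str]
    distances: dict[str, float]
    unreachable: set[str]
    nodes: set[str]
    edges: set[frozenset]

    @property
    def distance_sample(self) -> np.ndarray:
        return np.array(sorted(self.distances.values()), dtype=float)

    @property
    def n_unreachable(self) -> int:
        return len(self.unreachable)


@dataclass
class PathStatistics:
    """Welch comparison of MSSN distances (sample 2) vs background (sample 1)."""

    mean_background: float  # x̄1
    mean_observed: float    # x̄2
    var_background: float   # s1² (unbiased)
    var_observed: float     # s2²
    n_background: int
    n_observed: int
    t: float
    z: float = math.nan
    empirical_p: float = math.nan
    degenerate: bool = False


@dataclass
class BackgroundSample:
    """Pooled background distances plus per-replicate mean distances."""

    pooled: np.ndarray
    replicate_means: np.ndarray
    n_targets: int
    n_replicates: int

    @property
    def median(self) -> float:
        return float(np.median(self.pooled))


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------


def shortest_distances(
    net: PPINetwork, source: str, destinations: Iterable[str]
) -> dict[str, float]:
    """Exact single-source Dijkstra distances to the given destinations.

    Unreachable destinations map to ``math.inf`` rather than erroring.
    """
    if source not in net.graph:
        raise ValueError(f"source gene not in network: {source}")
    lengths = nx.single_source_dijkstra_path_length(net.graph, source, weight="weight")
    return {d: lengths.get(d, UNREACHABLE) for d in destinations}


def _lex_shortest_path(graph: nx.Graph, source: str, target: str,
                       dist_to_target: Mapping[str, float]) -> list[str]:
    """Lexicographically smallest node sequence among all shortest paths.

    Greedy walk from the source: at each node pick the smallest-id
    neighbour that stays on some shortest path to the target (its residual
    distance drops by exactly the edge weight). Choosing the smallest
    feasible successor at every step yields the lexicographic minimum,
    because any feasible successor extends to a complete shortest path.
    """
    total = dist_to_target[source]
    tol = 1e-9 * max(1.0, total)
    path = [source]
    u = source
    while u != target:
        residual = dist_to_target[u]
        nxt = None
        for v in sorted(graph.neighbors(u)):
            w = graph[u][v]["weight"]
            dv = dist_to_target.get(v, UNREACHABLE)
            if abs(residual - w - dv) <= tol:
                nxt = v
                break
        if nxt is None:  # pragma: no cover - guarded by reachability
            raise RuntimeError(f"path reconstruction failed at {u}")
        path.append(nxt)
        u = nxt
    return path


def build_mssn(net: PPINetwork, seed: str, de_set: Iterable[str], direction: str) -> MSSN:
    """Union of one retained shortest path per reachable target.

    Targets are the DE genes of the stated direction intersected with the
    network (the seed itself is excluded if differentially expressed). Ties
    among equal-cost paths break to the lexicographically smallest node
    sequence, so the subnetwork is deterministic. Unreachable targets are
    excluded from the distance sample but counted.
    """
    if seed not in net.graph:
        raise ValueError(f"seed gene not in network: {seed}")
    targets = (set(de_set) & set(net.graph.nodes)) - {seed}
    if not targets:
        raise ValueError(f"no {direction}-regulated genes present in the network")

    dist = shortest_distances(net, seed, targets)
    reachable = {t: d for t, d in dist.items() if math.isfinite(d)}
    unreachable = set(dist) - set(reachable)

    nodes: set[str] = {seed}
    edges: set[frozenset] = set()
    for t in sorted(reachable):
        d_to_t = nx.single_source_dijkstra_path_length(net.graph, t, weight="weight")
        path = _lex_shortest_path(net.graph, seed, t, d_to_t)
        nodes.update(path)
        edges.update(frozenset(e) for e in zip(path, path[1:]))
    return MSSN(seed=seed, direction=direction, targets=targets,
                distances=reachable, unreachable=unreachable, nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Background random networks
# ---------------------------------------------------------------------------


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def background_distances(
    net: PPINetwork,
    n_targets: int,
    n_replicates: int = 1000,
    rng: int | np.random.Generator | None = 0,
) -> BackgroundSample:
    """Shortest-distance sample from random source/destination draws.

    Each replicate picks one source uniformly and ``n_targets`` distinct
    destinations uniformly without replacement (excluding the source) and
    collects the reachable shortest distances. Distances come from the
    same Dijkstra algorithm as the observed subnetworks, run vectorized
    over the sampled sources. Reproducible from ``rng``.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    node_list = sorted(net.graph.nodes)
    n = len(node_list)
    if n <= n_targets + 1:
        raise ValueError(f"network has {n} nodes; need > n_targets + 1 = {n_targets + 1}")
    rng = _as_rng(rng)

    sources = rng.integers(0, n, size=n_replicates)
    dests = np.empty((n_replicates, n_targets), dtype=np.int64)
    for i, s in enumerate(sources):
        pick = rng.choice(n - 1, size=n_targets, replace=False)
        pick[pick >= s] += 1  # skip the source index
        dests[i] = pick

    adj = nx.to_scipy_sparse_array(net.graph, nodelist=node_list, weight="weight", format="csr")
    adj = sp.csr_matrix(adj)
    uniq = np.unique(sources)
    dmat = _csgraph_dijkstra(adj, directed=False, indices=uniq)
    row_of = {s: i for i, s in enumerate(uniq)}

    pooled: list[float] = []
    means = np.full(n_replicates, np.nan)
    for i, s in enumerate(sources):
        d = dmat[row_of[s], dests[i]]
        finite = d[np.isfinite(d)]
        pooled.extend(finite.tolist())
        if finite.size:
            means[i] = finite.mean()
    return BackgroundSample(pooled=np.asarray(pooled, dtype=float),
                            replicate_means=means[np.isfinite(means)],
                            n_targets=n_targets, n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# Welch statistic
# ---------------------------------------------------------------------------


def welch_t(sample1, sample2, replicate_means=None) -> PathStatistics:
    """Welch unequal-variance t of background (1) vs MSSN (2) distances.

    ``sample1`` may be a :class:`BackgroundSample`, in which case its
    pooled distances and replicate means are used. Sign convention: t > 0
    means the MSSN paths are shorter than background on average. The
    empirical p is the fraction of background replicate means ≤ the
    observed mean.
    """
    if isinstance(sample1, BackgroundSample):
        if replicate_means is None:
            replicate_means = sample1.replicate_means
        sample1 = sample1.pooled
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    if x2.size == 0:
        return PathStatistics(math.nan, math.nan, math.nan, math.nan,
                              int(x1.size), 0, math.nan, degenerate=True)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("both samples need size >= 2")
    m1, m2 = x1.mean(), x2.mean()
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    se = math.sqrt(v1 / x1.size + v2 / x2.size)
    degenerate = se == 0.0
    t = math.nan if degenerate else (m1 - m2) / se

    z = math.nan
    p_emp = math.nan
    if replicate_means is not None and len(replicate_means) >= 2:
        rm = np.asarray(replicate_means, dtype=float)
        sd = rm.std(ddof=1)
        if sd > 0:
            z = (rm.mean() - m2) / sd
        p_emp = float(np.mean(rm <= m2))
    return PathStatistics(mean_background=float(m1), mean_observed=float(m2),
                          var_background=float(v1), var_observed=float(v2),
                          n_background=int(x1.size), n_observed=int(x2.size),
                          t=t, z=z, empirical_p=p_emp, degenerate=degenerate)


def prune_targets(mssn: MSSN, background_median: float) -> MSSN:
    """Optional per-target pruning: drop targets farther than the background median."""
    kept = {t: d for t, d in mssn.distances.items() if d <= background_median}
    dropped = set(mssn.distances) - set(kept)
    return MSSN(seed=mssn.seed, direction=mssn.direction,
                targets=mssn.targets - dropped, distances=kept,
                unreachable=mssn.unreachable, nodes=mssn.nodes, edges=mssn.edges)


def evaluate_seed(
    net: PPINetwork,
    seed: str,
    de_sets: Mapping[str, Iterable[str]],
    n_replicates: int = 1000,
    rng: int | np.random.Generator | None = 0,
    prune: bool = False,
) -> dict[str, tuple[MSSN | None, PathStatistics | None]]:
    """Build and score the up- and down-direction MSSNs for one seed.

    ``de_sets`` maps direction ("up"/"down") to its DE gene set. The
    background is redrawn per seed and per direction, with the destination
    count matched to the observed target count. Directions whose DE set
    does not intersect the network yield (None, None).
    """
    rng = _as_rng(rng)
    out: dict[str, tuple[MSSN | None, PathStatistics | None]] = {}
    for direction in ("up", "down"):
        de = set(de_sets.get(direction, ()))
        try:
            subnet = build_mssn(net, seed, de, direction)
        except ValueError:
            out[direction] = (None, None)
            continue
        n_targets = len(subnet.distances) + len(subnet.unreachable)
        bg = background_distances(net, n_targets, n_replicates, rng)
        if prune:
            subnet = prune_targets(subnet, bg.median)
        stats = welch_t(bg, subnet.distance_sample)
        out[direction] = (subnet, stats)
    return out
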