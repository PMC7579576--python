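"""The complexity-indicator suite computed from a binary brain graph.

Eleven network-level indicators are reported per subject: global clustering
coefficient, number of triangles, modularity, characteristic path length,
mean path length, SD of path length, complexity, small-worldness, mean
degree, Dunn index and degree entropy.  All graph formulas operate on the
binary adjacency matrix a_ij; the Dunn index is the one indicator computed
from the weighted correlation matrix instead (clusters of ROIs on the
distance 1 - r).

Conventions for awkward inputs are explicit and recorded in diagnostics:
nodes with degree < 2 contribute a local clustering of 0; path lengths
average finite distances only (unreachable pairs are excluded, and the
count of isolated nodes is reported); the SD of path length uses the n-1
denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import squareform

from .connectivity import BrainGraph, ConnectivityMatrix
from .errors import (
    DegenerateGraphError,
    ParameterError,
    PartitionError,
    UndefinedRatioError,
)

__all__ = [
    "INDICATORS",
    "INDICATOR_DISPLAY",
    "ComplexityProfile",
    "NodeMetrics",
    "NullEnsemble",
    "PathLengthStats",
    "Partition",
    "complexity_index",
    "compute_profile",
    "degree_entropy",
    "detect_partition",
    "dunn_index",
    "dunn_index_from_distances",
    "global_clustering",
    "modularity_q",
    "node_degrees",
    "node_triangles",
    "path_length_stats",
    "random_null_ensemble",
    "shortest_paths",
    "small_worldness",
]

#: Column order of a serialized profile (field name -> display name).
INDICATOR_DISPLAY = {
    "global_clustering": "Global Clustering Coefficient",
    "n_triangles": "Number of Triangles",
    "modularity": "Modularity",
    "char_path_length": "Characteristic Path Length",
    "mean_path_length": "Mean Path Length",
    "sd_path_length": "SD Path Length",
    "complexity": "Complexity",
    "small_worldness": "Small-Worldness",
    "mean_degree": "Degree",
    "dunn_index": "Dunn Index",
    "entropy": "Entropy",
}
INDICATORS = tuple(INDICATOR_DISPLAY)


def node_degrees(g: BrainGraph) -> np.ndarray:
    """Degree k_i of every node (row sums of the adjacency matrix)."""
    return g.adjacency.sum(axis=1).astype(np.int64)


def node_triangles(g: BrainGraph) -> np.ndarray:
    """Number of triangles t_i around every node.

    t_i = (1/2) sum_{j,h} a_ij a_ih a_jh, i.e. half the i-th diagonal entry
    of A^3.
    """
    a = g.adjacency.astype(np.int64)
    return np.einsum("ij,jh,hi->i", a, a, a) // 2


def local_clustering(g: BrainGraph) -> np.ndarray:
    """Local clustering C_i = 2 t_i / (k_i (k_i - 1)); 0 when k_i < 2."""
    k = node_degrees(g).astype(float)
    t = node_triangles(g).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(k >= 2, 2.0 * t / (k * (k - 1.0)), 0.0)
    return c


def global_clustering(g: BrainGraph) -> float:
    """Mean of the local clustering coefficients over all nodes."""
    if g.n == 0:
        raise DegenerateGraphError("clustering of an empty node set")
    return float(local_clustering(g).mean())


def shortest_paths(g: BrainGraph) -> np.ndarray:
    """All-pairs unweighted shortest-path matrix (np.inf = unreachable)."""
    return shortest_path(
        g.adjacency.astype(float), method="D", unweighted=True, directed=False
    )


@dataclass
class PathLengthStats:
    """Node path lengths L_i and their network summaries.

    ``char_path_length`` is the mean of the L_i (the characteristic path
    length L); ``mean_path_length`` averages finite distances over
    unordered node pairs (identical to L on connected graphs);
    ``sd_path_length`` is the sample (n-1) standard deviation of the L_i.
    ``n_isolated`` diagnoses how many nodes had no reachable partner and
    were excluded.
    """

    per_node: np.ndarray
    char_path_length: float
    mean_path_length: float
    sd_path_length: float
    n_isolated: int


def path_length_stats(g: BrainGraph) -> PathLengthStats:
    """Per-node average shortest-path lengths and their summaries.

    L_i averages the finite distances from node i to every other node it
    can reach; nodes that reach nobody are excluded from the summaries and
    counted in ``n_isolated``.
    """
    if g.n_edges == 0:
        raise DegenerateGraphError("path lengths of an edgeless graph")
    d = shortest_paths(g)
    np.fill_diagonal(d, np.nan)
    finite = np.isfinite(d)
    with np.errstate(invalid="ignore"):
        per_node = np.where(
            finite.any(axis=1),
            np.nansum(np.where(finite, d, 0.0), axis=1)
            / np.maximum(finite.sum(axis=1), 1),
            np.nan,
        )
    reachable = per_node[np.isfinite(per_node)]
    iu, ju = np.triu_indices(g.n, 1)
    pair_d = d[iu, ju]
    pair_d = pair_d[np.isfinite(pair_d)]
    sd = float(np.std(reachable, ddof=1)) if reachable.size > 1 else 0.0
    return PathLengthStats(
        per_node=per_node,
        char_path_length=float(reachable.mean()),
        mean_path_length=float(pair_d.mean()),
        sd_path_length=sd,
        n_isolated=int(g.n - reachable.size),
    )


@dataclass
class Partition:
    """Non-overlapping assignment of nodes to modules.

    ``e`` is the symmetric matrix of link proportions: e_uu is the fraction
    of edges inside module u, and for u != v each of e_uv and e_vu carries
    half the fraction of edges between u and v, so the whole matrix sums
    to 1.
    """

    modules: dict[int, int]
    e: np.ndarray = field(default=None)  # type: ignore[assignment]

    def module_ids(self) -> list[int]:
        return sorted(set(self.modules.values()))


def _edge_fraction_matrix(g: BrainGraph, modules: Mapping[int, int]) -> np.ndarray:
    ids = sorted(set(modules.values()))
    pos = {m: i for i, m in enumerate(ids)}
    labels = np.array([pos[modules[i]] for i in range(g.n)])
    m2 = float(g.adjacency.sum())  # 2 * number of edges
    if m2 == 0:
        raise DegenerateGraphError("modularity of an edgeless graph")
    k = len(ids)
    e = np.zeros((k, k))
    for u in range(k):
        for v in range(k):
            e[u, v] = g.adjacency[np.ix_(labels == u, labels == v)].sum() / m2
    return e


def modularity_q(g: BrainGraph, p: Partition | Mapping[int, int]) -> float:
    """Newman modularity Q = sum_u [e_uu - (sum_v e_uv)^2]."""
    modules = p.modules if isinstance(p, Partition) else dict(p)
    missing = [i for i in range(g.n) if i not in modules]
    if missing:
        raise PartitionError(f"nodes without a module: {missing[:5]}")
    e = _edge_fraction_matrix(g, modules)
    row = e.sum(axis=1)
    return float(np.sum(np.diag(e) - row**2))


def _refine_partition(
    adj: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
    max_rounds: int = 40,
) -> np.ndarray:
    """Seeded local-move + community-merge refinement of a labeling.

    Alternates two phases until neither improves Q: (1) sweep nodes in a
    seeded random order, moving each to the community with the largest
    strictly positive modularity gain (an empty community is always a
    candidate, so splits are possible); (2) greedily merge the community
    pair with the largest positive gain.  Every accepted step strictly
    increases Q, so the procedure terminates.
    """
    k = adj.sum(axis=1).astype(float)
    m = k.sum() / 2.0
    labels = labels.copy()
    n = len(labels)
    for _ in range(max_rounds):
        improved = False
        # phase 1: single-node moves
        for _ in range(n * 4):
            moved = False
            for i in rng.permutation(n):
                a = labels[i]
                n_comm = labels.max() + 2  # one spare empty community
                links = np.bincount(
                    labels[adj[i] > 0], minlength=n_comm
                ).astype(float)
                degs = np.bincount(
                    labels, weights=k, minlength=n_comm
                )
                gains = (links - links[a]) / m - k[i] * (
                    degs - (degs[a] - k[i])
                ) / (2.0 * m**2)
                gains[a] = 0.0
                c = int(np.argmax(gains))
                if gains[c] > 1e-12:
                    labels[i] = c
                    moved = improved = True
            if not moved:
                break
        # phase 2: best community merge
        ids = np.unique(labels)
        best_gain, best_pair = 0.0, None
        for x in range(len(ids)):
            ix = labels == ids[x]
            for y in range(x + 1, len(ids)):
                iy = labels == ids[y]
                l_xy = float(adj[np.ix_(ix, iy)].sum())
                gain = l_xy / m - k[ix].sum() * k[iy].sum() / (2.0 * m**2)
                if gain > best_gain + 1e-12:
                    best_gain, best_pair = gain, (ids[x], ids[y])
        if best_pair is not None:
            labels[labels == best_pair[1]] = best_pair[0]
            improved = True
        if not improved:
            break
    return labels


def detect_partition(
    g: BrainGraph, seed: int = 0, n_restarts: int = 4
) -> Partition:
    """Search for a high-modularity partition.

    Candidates come from greedy agglomerative modularity maximization and
    ``n_restarts`` seeded restarts of a local-move/merge refinement (plus
    the trivial single module); the candidate with the highest Q under
    :func:`modularity_q` wins, with the earliest candidate kept on ties,
    so the result is deterministic given the seed.
    """
    if g.n_edges == 0:
        raise DegenerateGraphError("cannot partition an edgeless graph")
    adj = g.adjacency.astype(np.int64)
    rng = np.random.default_rng(seed)
    labelings: list[np.ndarray] = [np.zeros(g.n, dtype=np.int64)]
    cnm = nx.community.greedy_modularity_communities(g.to_networkx())
    cnm_labels = np.zeros(g.n, dtype=np.int64)
    for idx, com in enumerate(cnm):
        cnm_labels[list(com)] = idx
    labelings.append(cnm_labels)
    labelings.append(_refine_partition(adj, cnm_labels, rng))
    start = np.arange(g.n, dtype=np.int64)  # singletons
    labelings.append(_refine_partition(adj, start, rng))
    for _ in range(n_restarts):
        # random coarse initialization: escapes local optima that the
        # strictly-greedy refinement cannot cross from singletons
        k_init = int(rng.integers(2, min(6, g.n) + 1))
        coarse = rng.integers(0, k_init, size=g.n).astype(np.int64)
        labelings.append(_refine_partition(adj, coarse, rng))
    best: tuple[float, Partition] | None = None
    for labels in labelings:
        ids = {c: i for i, c in enumerate(np.unique(labels))}
        modules = {node: ids[labels[node]] for node in range(g.n)}
        q = modularity_q(g, modules)
        if best is None or q > best[0] + 1e-12:
            part = Partition(
                modules=modules, e=_edge_fraction_matrix(g, modules)
            )
            best = (q, part)
    assert best is not None
    return best[1]


@dataclass
class NullEnsemble:
    """Degree-preserving random reference graphs summarised by C and L.

    ``degenerate`` flags sources whose degree sequence admits no rewiring
    (e.g. complete graphs); the ensemble then consists of the source graph
    itself.
    """

    c_rand: float
    l_rand: float
    n_null: int
    seed: int
    degenerate: bool = False


def _double_edge_swap(
    adj: np.ndarray, n_swaps: int, max_tries: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Rewire by double-edge swaps; returns (new adjacency, swaps done).

    A swap picks two edges (u,v) and (x,y) and replaces them with (u,x)
    and (v,y); rejected if that would create a self-loop or a multi-edge.
    The degree of every node is invariant under accepted swaps.
    """
    n = adj.shape[0]
    neighbors = [set(np.nonzero(adj[i])[0].tolist()) for i in range(n)]
    iu, ju = np.nonzero(np.triu(adj, 1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    m = len(edges)
    picks = rng.integers(0, m, size=(max_tries, 2)).tolist()
    flips = rng.integers(0, 2, size=max_tries).tolist()
    swaps = 0
    for t in range(max_tries):
        if swaps >= n_swaps:
            break
        e1, e2 = picks[t]
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flips[t]:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if x in neighbors[u] or y in neighbors[v]:
            continue
        neighbors[u].remove(v); neighbors[v].remove(u)
        neighbors[x].remove(y); neighbors[y].remove(x)
        neighbors[u].add(x); neighbors[x].add(u)
        neighbors[v].add(y); neighbors[y].add(v)
        edges[e1] = (u, x) if u < x else (x, u)
        edges[e2] = (v, y) if v < y else (y, v)
        swaps += 1
    out = np.zeros((n, n), dtype=np.int8)
    for i, nb in enumerate(neighbors):
        out[i, list(nb)] = 1
    return out, swaps


def random_null_ensemble(
    g: BrainGraph, n_null: int = 100, seed: int = 0
) -> NullEnsemble:
    """Mean clustering/path length over degree-preserving rewired graphs.

    Each null graph starts from the source and undergoes 10 |E| double-edge
    swap attempts (swaps that would create self-loops or multi-edges are
    rejected), so every null preserves the exact degree sequence.  Sources
    that admit no swap at all (e.g. complete graphs) yield the source
    itself ``n_null`` times with the ``degenerate`` flag set.
    """
    if g.n_edges < 2:
        raise DegenerateGraphError("null ensemble needs at least 2 edges")
    if n_null < 1:
        raise ParameterError("n_null must be >= 1")
    m = g.n_edges
    complete = m == g.n * (g.n - 1) // 2
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    degenerate = complete
    for _ in range(n_null):
        if complete:
            null = g
        else:
            adj, swaps = _double_edge_swap(g.adjacency, 10 * m, 10 * m, rng)
            if swaps == 0:
                degenerate = True
            null = BrainGraph(adjacency=adj, labels=g.labels)
        cs.append(global_clustering(null))
        ls.append(path_length_stats(null).char_path_length)
    return NullEnsemble(
        c_rand=float(np.mean(cs)),
        l_rand=float(np.mean(ls)),
        n_null=n_null,
        seed=seed,
        degenerate=degenerate,
    )


def small_worldness(g: BrainGraph, ensemble: NullEnsemble) -> float:
    """Small-worldness S = (C / C_rand) / (L / L_rand).

    S > 1 signals the small-world balance of segregation (clustering well
    above random) and integration (path length near random).  A
    triangle-free source has C = 0 and therefore S = 0.
    """
    c = global_clustering(g)
    if c == 0.0:
        return 0.0
    if ensemble.c_rand <= 0:
        raise UndefinedRatioError("C_rand is zero; S undefined")
    stats = path_length_stats(g)
    if stats.char_path_length <= 0 or ensemble.l_rand <= 0:
        raise UndefinedRatioError("path-length ratio undefined")
    return float(
        (c / ensemble.c_rand) / (stats.char_path_length / ensemble.l_rand)
    )


def degree_entropy(g: BrainGraph) -> float:
    """Shannon entropy (bits) of the empirical degree distribution.

    Regular graphs score 0; heterogeneous degree sequences score higher.
    """
    if g.n == 0:
        raise DegenerateGraphError("entropy of an empty node set")
    _, counts = np.unique(node_degrees(g), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def complexity_index(g: BrainGraph) -> float:
    """Normalized density complexity kappa = 4 rho (1 - rho).

    rho = 2|E| / (n(n-1)) is the edge density; kappa lives in [0, 1], is 0
    for both empty and complete graphs and maximal at half density, so it
    scores the coexistence of structure and alternative paths.
    """
    if g.n < 2:
        raise DegenerateGraphError("complexity needs at least 2 nodes")
    rho = 2.0 * g.n_edges / (g.n * (g.n - 1))
    return float(4.0 * rho * (1.0 - rho))


def dunn_index_from_distances(
    distances: np.ndarray, cluster_labels: Sequence[int]
) -> float:
    """Dunn = min between-cluster distance / max within-cluster diameter.

    Returns ``inf`` when every cluster is a singleton (all diameters 0).
    """
    d = np.asarray(distances, dtype=float)
    labels = np.asarray(cluster_labels)
    ids = np.unique(labels)
    if ids.size < 2:
        raise ParameterError("Dunn index needs at least 2 clusters")
    max_diam = 0.0
    for cid in ids:
        idx = np.nonzero(labels == cid)[0]
        if idx.size > 1:
            max_diam = max(max_diam, float(d[np.ix_(idx, idx)].max()))
    min_between = math.inf
    for a in range(ids.size):
        ia = np.nonzero(labels == ids[a])[0]
        for b in range(a + 1, ids.size):
            ib = np.nonzero(labels == ids[b])[0]
            min_between = min(min_between, float(d[np.ix_(ia, ib)].min()))
    if max_diam == 0.0:
        return math.inf
    return min_between / max_diam


def dunn_index(
    conn: ConnectivityMatrix,
    k: int = 3,
    seed: int = 0,
    use_absolute: bool = False,
) -> float:
    """Cluster-validity Dunn index of the ROI correlation structure.

    ROIs are clustered by average-linkage hierarchical clustering on the
    distance 1 - r (or 1 - |r| when ``use_absolute``), cut at ``k``
    clusters (default 3, mirroring the three DMN subnetworks); the Dunn
    index is the minimum between-cluster distance over the maximum
    within-cluster diameter — higher means better-separated, more compact
    clusters.  ``seed`` is accepted for interface uniformity; the procedure
    is deterministic.
    """
    del seed  # hierarchical clustering is deterministic
    n = conn.n
    if k < 2 or k > n:
        raise ParameterError(f"k must lie in [2, {n}], got {k}")
    r = np.abs(conn.values) if use_absolute else conn.values
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    z = linkage(squareform((d + d.T) / 2.0, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    if np.unique(labels).size < 2:
        # all ROIs merge at distance 0: degenerate, perfectly compact
        return math.inf
    return dunn_index_from_distances(d, labels)


@dataclass
class NodeMetrics:
    """Per-node quantities bundled for inspection."""

    degrees: np.ndarray
    triangles: np.ndarray
    local_clustering: np.ndarray
    distances: np.ndarray

    @classmethod
    def from_graph(cls, g: BrainGraph) -> "NodeMetrics":
        return cls(
            degrees=node_degrees(g),
            triangles=node_triangles(g),
            local_clustering=local_clustering(g),
            distances=shortest_paths(g),
        )


@dataclass
class ComplexityProfile:
    """One subject's vector of the eleven network indicators."""

    subject_id: str
    global_clustering: float
    n_triangles: float
    modularity: float
    char_path_length: float
    mean_path_length: float
    sd_path_length: float
    complexity: float
    small_worldness: float
    mean_degree: float
    dunn_index: float
    entropy: float

    def as_series(self) -> pd.Series:
        return pd.Series(
            {name: getattr(self, name) for name in INDICATORS},
            name=self.subject_id,
        )


def profiles_to_frame(profiles: Sequence[ComplexityProfile]) -> pd.DataFrame:
    """Stack profiles into a subjects x indicators DataFrame."""
    frame = pd.DataFrame([p.as_series() for p in profiles])
    frame.index.name = "subject_id"
    return frame


def compute_profile(
    g: BrainGraph,
    conn: ConnectivityMatrix,
    n_null: int = 100,
    k: int = 3,
    seed: int = 0,
    subject_id: str | None = None,
) -> ComplexityProfile:
    """Compute the full indicator profile for one subject.

    ``g`` must be the binarization of ``conn`` (same ROI set); ``n_null``
    sizes the degree-preserving ensemble behind small-worldness and ``k``
    the cluster count behind the Dunn index.  A single seed drives every
    stochastic component.
    """
    if g.n != conn.n or list(g.labels) != list(conn.roi_labels):
        raise ParameterError("graph and connectivity ROI sets differ")
    k_i = node_degrees(g)
    t_i = node_triangles(g)
    stats = path_length_stats(g)
    part = detect_partition(g, seed=seed)
    ensemble = random_null_ensemble(g, n_null=n_null, seed=seed)
    return ComplexityProfile(
        subject_id=subject_id or "subject",
        global_clustering=global_clustering(g),
        n_triangles=float(t_i.sum() / 3),
        modularity=modularity_q(g, part),
        char_path_length=stats.char_path_length,
        mean_path_length=stats.mean_path_length,
        sd_path_length=stats.sd_path_length,
        complexity=complexity_index(g),
        small_worldness=small_worldness(g, ensemble),
        mean_degree=float(k_i.mean()),
        dunn_index=dunn_index(conn, k=k, seed=seed),
        entropy=degree_entropy(g),
    )
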