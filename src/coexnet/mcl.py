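"""Markov clustering (MCL) of weighted correlation graphs, from scratch.

MCL simulates flow on a graph: the weighted adjacency matrix (plus self
loops) is column-normalised into a stochastic matrix which is alternately
*expanded* (raised to a matrix power, spreading flow along paths) and
*inflated* (raised to an elementwise power and renormalised, strengthening
strong currents and starving weak ones).  The process converges to a
doubly-idempotent matrix whose non-zero pattern encodes "attractor" nodes and
the nodes that flow into them; those basins are the clusters.  The inflation
exponent sets granularity — larger values fragment the graph into more,
smaller clusters.

Two matrix backends share the same update rule: a pruned sparse backend for
large graphs (entries below ``prune_threshold`` are dropped each iteration,
then columns renormalised) and an unpruned dense backend that serves as an
exact reference on small graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse import csgraph

from .graph import ThresholdGraph

logger = logging.getLogger(__name__)


class MclError(ValueError):
    pass


@dataclass(frozen=True)
class MclParams:
    """Tunable parameters of the MCL iteration.

    inflation > 1 (granularity; 1.7 is the conventional choice for gene
    co-expression graphs), expansion >= 2 (matrix-power order),
    self_loop_weight >= 0 (regularisation that guarantees aperiodicity),
    prune_threshold (sparse backend only), convergence_tol on the max
    elementwise change between iterations.
    """

    inflation: float = 1.7
    expansion: int = 2
    self_loop_weight: float = 1.0
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-8
    use_weights: bool = True

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise MclError("inflation must be > 1")
        if self.expansion < 2:
            raise MclError("expansion must be an integer >= 2")
        if self.self_loop_weight < 0:
            raise MclError("self_loop_weight must be >= 0")
        if self.prune_threshold <= 0 or self.convergence_tol <= 0:
            raise MclError("prune_threshold and convergence_tol must be > 0")
        if self.max_iterations < 1:
            raise MclError("max_iterations must be >= 1")


@dataclass
class ClusterSet:
    """Disjoint clusters numbered 1..K by decreasing size.

    Ties in size are broken by the smallest member identifier.  ``unassigned``
    holds nodes that received no attractor flow (empty under default
    parameters).  ``converged`` is False when ``max_iterations`` was hit.
    """

    clusters: list[frozenset] = field(repr=False)
    unassigned: frozenset
    params: MclParams
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        sizes = [len(c) for c in self.clusters]
        if any(s1 < s2 for s1, s2 in zip(sizes, sizes[1:])):
            raise MclError("cluster sizes must be non-increasing")
        all_nodes: set = set()
        for c in self.clusters:
            if all_nodes & c:
                raise MclError("clusters are not disjoint")
            all_nodes |= c
        if all_nodes & self.unassigned:
            raise MclError("unassigned overlaps a cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def nodes(self) -> set:
        out = set(self.unassigned)
        for c in self.clusters:
            out |= c
        return out

    def labels(self) -> dict:
        """node -> 1-based cluster number (unassigned nodes omitted)."""
        return {u: k for k, c in enumerate(self.clusters, start=1) for u in c}


def _order_clusters(raw: list[set]) -> list[frozenset]:
    return [frozenset(c) for c in
            sorted(raw, key=lambda c: (-len(c), min(map(str, c))))]


def _iterate_sparse(m: sp.csc_matrix, params: MclParams) -> tuple[sp.csc_matrix, bool, int]:
    def normalise(a: sp.csc_matrix) -> sp.csc_matrix:
        sums = np.asarray(a.sum(axis=0)).ravel()
        sums[sums == 0] = 1.0
        return (a @ sp.diags(1.0 / sums)).tocsc()

    m = normalise(m)
    for it in range(1, params.max_iterations + 1):
        prev = m.copy()
        power = m
        for _ in range(params.expansion - 1):
            power = (power @ m).tocsc()
        m = power
        m.data = np.power(m.data, params.inflation)
        m = normalise(m)
        m.data[m.data < params.prune_threshold] = 0.0
        m.eliminate_zeros()
        m = normalise(m)
        diff = m - prev
        change = abs(diff).max() if diff.nnz else 0.0
        if change < params.convergence_tol:
            return m, True, it
    return m, False, params.max_iterations


def _iterate_dense(m: np.ndarray, params: MclParams) -> tuple[np.ndarray, bool, int]:
    def normalise(a: np.ndarray) -> np.ndarray:
        sums = a.sum(axis=0)
        sums[sums == 0] = 1.0
        return a / sums

    m = normalise(m)
    for it in range(1, params.max_iterations + 1):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = normalise(np.power(m, params.inflation))
        if np.abs(m - prev).max() < params.convergence_tol:
            return m, True, it
    return m, False, params.max_iterations


def _extract_clusters(support: sp.csr_matrix, nodes: list) -> tuple[list[set], set]:
    """Interpret the converged flow matrix's non-zero pattern.

    Attractors are nodes with self-flow; attractors sharing any basin member
    belong to one attractor system, and every node joins the system(s) it
    flows to.  Nodes reached by several systems (overlap, rare) go to the
    larger cluster, ties to the lower cluster number; nodes reached by none
    are returned as unassigned.
    """
    n = len(nodes)
    diag = support.diagonal().astype(bool)
    attractors = np.where(diag)[0]
    if attractors.size == 0:
        return [], set(nodes)
    # union attractor rows that overlap anywhere: connected components of the
    # bipartite attractor->basin incidence
    rows = support[attractors]
    overlap = ((rows @ rows.T) > 0).astype(np.int8)  # attractor x attractor
    n_sys, sys_of = csgraph.connected_components(overlap, directed=False)
    basins: list[set] = [set() for _ in range(n_sys)]
    member_systems: list[set] = [set() for _ in range(n)]
    for ai, a in enumerate(attractors):
        srow = support.indices[support.indptr[a]:support.indptr[a + 1]]
        for u in srow:
            member_systems[u].add(sys_of[ai])
    provisional: list[set] = [set() for _ in range(n_sys)]
    for u in range(n):
        for s in member_systems[u]:
            provisional[s].add(u)
    overlaps = 0
    final: list[set] = [set() for _ in range(n_sys)]
    unassigned: set = set()
    order = sorted(range(n_sys), key=lambda s: (-len(provisional[s]),
                                                min(provisional[s]) if provisional[s] else 0))
    rank = {s: i for i, s in enumerate(order)}
    for u in range(n):
        systems = member_systems[u]
        if not systems:
            unassigned.add(u)
            continue
        if len(systems) > 1:
            overlaps += 1
        best = min(systems, key=lambda s: (-len(provisional[s]), rank[s]))
        final[best].add(u)
    if overlaps:
        logger.info("MCL: %d node(s) attracted to multiple clusters; "
                    "assigned to the larger (ties: lower number)", overlaps)
    clusters = [{nodes[u] for u in c} for c in final if c]
    return clusters, {nodes[u] for u in unassigned}


def run_mcl(tg: ThresholdGraph, params: MclParams | None = None,
            backend: str = "sparse") -> ClusterSet:
    """Cluster a threshold graph with MCL.

    ``backend="sparse"`` (default) prunes small entries each iteration;
    ``backend="dense"`` runs the exact unpruned iteration and is the
    reference implementation for small graphs.  The algorithm is fully
    deterministic: identical graph and parameters give identical clusters.
    Clusters never span connected components of the input graph.
    """
    if params is None:
        params = MclParams()
    if backend not in ("sparse", "dense"):
        raise MclError(f"unknown backend {backend!r}")
    nodes = sorted(tg.graph.nodes, key=str)
    n = len(nodes)
    if n == 0:
        raise MclError("graph is empty")
    a = nx.to_scipy_sparse_array(tg.graph, nodelist=nodes,
                                 weight="weight" if params.use_weights else None,
                                 format="csc", dtype=float)
    if not params.use_weights:
        a = a.astype(bool).astype(float)
    a = (a + sp.diags([params.self_loop_weight] * n)).tocsc()
    if backend == "sparse":
        m, converged, iters = _iterate_sparse(sp.csc_matrix(a), params)
        support = sp.csr_matrix(m)
        support.data = (support.data >= params.prune_threshold).astype(float)
        support.eliminate_zeros()
    else:
        m, converged, iters = _iterate_dense(a.toarray(), params)
        support = sp.csr_matrix(m >= params.prune_threshold, dtype=float)
        support.eliminate_zeros()
    if not converged:
        logger.warning("MCL did not converge within %d iterations; "
                       "returning current clustering", params.max_iterations)
    raw, unassigned = _extract_clusters(support, nodes)
    clusters = _order_clusters(raw)
    cs = ClusterSet(clusters=clusters, unassigned=frozenset(unassigned),
                    params=params, converged=converged, n_iterations=iters)
    _assert_partition(cs, set(nodes))
    _assert_within_components(cs, tg)
    return cs


def _assert_partition(cs: ClusterSet, nodes: set) -> None:
    if cs.nodes != nodes:
        raise MclError("cluster output is not a partition of the graph nodes")


def _assert_within_components(cs: ClusterSet, tg: ThresholdGraph) -> None:
    comp_of = {}
    for i, comp in enumerate(nx.connected_components(tg.graph)):
        for u in comp:
            comp_of[u] = i
    for c in cs.clusters:
        if len({comp_of[u] for u in c}) > 1:
            raise MclError("a cluster spans connected components")


def filter_clusters(cs: ClusterSet, min_size: int) -> ClusterSet:
    """Drop clusters below ``min_size`` into ``unassigned`` and renumber."""
    if min_size < 1:
        raise MclError("min_size must be >= 1")
    kept = [c for c in cs.clusters if len(c) >= min_size]
    dropped: set = set(cs.unassigned)
    for c in cs.clusters:
        if len(c) < min_size:
            dropped |= c
    return replace(cs, clusters=_order_clusters([set(c) for c in kept]),
                   unassigned=frozenset(dropped))


def write_clusters(cs: ClusterSet, path) -> None:
    """TSV of (node_id, cluster_number); unassigned nodes get cluster 0."""
    import pandas as pd
    rows = [(u, k) for k, c in enumerate(cs.clusters, start=1)
            for u in sorted(c, key=str)]
    rows += [(u, 0) for u in sorted(cs.unassigned, key=str)]
    pd.DataFrame(rows, columns=["node_id", "cluster_number"]).to_csv(
        path, sep="\t", index=False)


def write_gmt(cs: ClusterSet, path, prefix: str = "cluster") -> None:
    with open(path, "w") as fh:
        for k, c in enumerate(cs.clusters, start=1):
            members = "\t".join(sorted(c, key=str))
            fh.write(f"{prefix}_{k}\tsize={len(c)}\t{members}\n")

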