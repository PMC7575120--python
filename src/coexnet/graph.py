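"""Correlation-threshold graphs: construction, threshold scans, components.

A threshold graph keeps an edge between two entities exactly when their
correlation is at least the threshold (inclusive), and keeps only entities
with at least one retained edge — isolated entities drop out, which is why
the node count of a sample network can fall below the sample count as the
threshold rises.  The scan table records (threshold, nodes, edges) over a
grid in a single sorted pass, and the maximum full-inclusion threshold is the
largest grid value at which every entity still has an edge.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix

logger = logging.getLogger(__name__)


class GraphError(ValueError):
    pass


@dataclass
class ThresholdGraph:
    """Undirected correlation graph at a fixed inclusive threshold."""

    graph: nx.Graph
    threshold: float
    method: str

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        for u, v, w in self.graph.edges(data="weight"):
            if u == v:
                raise GraphError("self-loop present")
            if w < self.threshold:
                raise GraphError(f"edge ({u},{v}) weight {w} < threshold")
        for u in self.graph.nodes:
            if self.graph.degree(u) == 0:
                raise GraphError(f"isolated node {u!r} present")


def _offdiag_upper(corr: CorrelationMatrix):
    iu = np.triu_indices(corr.n_entities, k=1)
    return iu, corr.values[iu]


def build_threshold_graph(corr: CorrelationMatrix,
                          r_min: float) -> ThresholdGraph:
    """Graph with an edge wherever off-diagonal r >= ``r_min`` (inclusive).

    Degenerate (zero-variance) entities never appear; entities left without
    any edge are dropped.
    """
    if not 0 <= r_min <= 1:
        raise GraphError(f"r_min must be in [0, 1], got {r_min}")
    iu, vals = _offdiag_upper(corr)
    ok = ~corr.degenerate
    keep = (vals >= r_min) & ok[iu[0]] & ok[iu[1]]
    ids = np.asarray(corr.entity_ids)
    g = nx.Graph()
    g.add_weighted_edges_from(
        zip(ids[iu[0][keep]], ids[iu[1][keep]], vals[keep]))
    tg = ThresholdGraph(graph=g, threshold=r_min, method=corr.method)
    logger.info("threshold graph r>=%.3g: %d nodes, %d edges",
                r_min, tg.n_nodes, tg.n_edges)
    return tg


def threshold_scan(corr: CorrelationMatrix,
                   grid=None) -> pd.DataFrame:
    """(threshold, n_nodes, n_edges) over a grid, from one sorted edge pass.

    A node is present at threshold t iff its maximum off-diagonal correlation
    is >= t, so node and edge counts come from two sorted arrays and a
    searchsorted per grid point; results match :func:`build_threshold_graph`
    at every grid value.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size and (np.diff(grid) <= 0).any():
        raise GraphError("grid must be strictly ascending")
    iu, vals = _offdiag_upper(corr)
    ok = ~corr.degenerate
    keep = ok[iu[0]] & ok[iu[1]]
    vals = np.sort(vals[keep])
    off = corr.values.copy()
    np.fill_diagonal(off, -np.inf)
    off[:, ~ok] = -np.inf
    max_r = off.max(axis=1) if corr.n_entities else np.array([])
    max_r = np.sort(max_r[ok])
    rows = []
    for t in grid:
        n_edges = vals.size - np.searchsorted(vals, t, side="left")
        n_nodes = max_r.size - np.searchsorted(max_r, t, side="left")
        rows.append({"threshold": float(t), "n_nodes": int(n_nodes),
                     "n_edges": int(n_edges)})
    return pd.DataFrame(rows)


def max_full_inclusion_threshold(corr: CorrelationMatrix,
                                 step: float = 0.01) -> float:
    """Largest grid threshold at which every entity keeps >= 1 edge.

    Equals the minimum over entities of their maximum off-diagonal
    correlation, floored to the grid.  Degenerate entities are reported and
    excluded with a warning rather than forcing the threshold to zero.
    """
    ok = ~corr.degenerate
    if ok.sum() < 2:
        raise GraphError("need at least 2 non-degenerate entities")
    if corr.degenerate.any():
        bad = list(np.asarray(corr.entity_ids)[corr.degenerate])
        logger.warning("max_full_inclusion_threshold: excluding %d degenerate "
                       "entit%s: %s", len(bad),
                       "y" if len(bad) == 1 else "ies", bad[:5])
    off = corr.values.copy()
    np.fill_diagonal(off, -np.inf)
    off[:, ~ok] = -np.inf
    weakest = off[ok].max(axis=1).min()
    if weakest < 0:
        return 0.0
    t = math.floor(weakest / step + 1e-9) * step
    return min(round(t, 10), 1.0)


def connected_components(tg: ThresholdGraph) -> list[set]:
    """Maximal connected node sets, largest first (ties by smallest member)."""
    comps = [set(c) for c in nx.connected_components(tg.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def write_edge_list(tg: ThresholdGraph, path) -> None:
    rows = sorted(
        ((u, v, w) for u, v, w in tg.graph.edges(data="weight")),
        key=lambda t: (-t[2], t[0], t[1]))
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def write_graphml(tg: ThresholdGraph, path) -> None:
    nx.write_graphml(tg.graph, path)
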