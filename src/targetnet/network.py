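"""Scored undirected interaction network built from a STRING-style edge list.

Edges are retained when their combined confidence score strictly exceeds a
threshold (0.9 by default).  Files that carry scores on the 0-1000 integer
dialect are detected (any score above 1) and rescaled to 0-1 before
comparison.  Shortest paths are unweighted hop counts: the confidence score
only gates which edges exist.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .errors import EmptyNetworkError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Network:
    """Simple undirected graph over gene symbols with per-edge scores in [0,1]."""

    graph: nx.Graph

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, v: str) -> set:
        return set(self.graph.neighbors(v))

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def edge_rows(self) -> list:
        """Edge list as (a, b, score) rows, deterministically ordered."""
        rows = []
        for a, b, d in self.graph.edges(data=True):
            x, y = sorted((a, b))
            rows.append((x, y, float(d.get("score", 1.0))))
        rows.sort()
        return rows

    def subgraph(self, nodes: Iterable[str]) -> "Network":
        g = self.graph.subgraph(set(nodes)).copy()
        return Network(graph=g)


def build_network(
    edge_rows: Iterable[Sequence],
    score_threshold: float = 0.9,
    restrict_to: Optional[set] = None,
) -> Network:
    """Build the network keeping edges with score strictly above the threshold.

    Parameters
    ----------
    edge_rows : iterable of (a, b, score)
        Malformed rows are logged and skipped.  Duplicate/reversed rows
        collapse to one undirected edge carrying the maximum score.
    score_threshold : float
        Confidence cutoff on the 0-1 scale (strict ``>``).
    restrict_to : set of str, optional
        If given, both endpoints must belong to this set.

    Raises
    ------
    EmptyNetworkError
        If no edge survives filtering.
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError("score_threshold must lie in [0, 1]")
    parsed = []
    skipped = 0
    for row in edge_rows:
        try:
            a, b, s = row[0], row[1], float(row[2])
        except (TypeError, ValueError, IndexError):
            skipped += 1
            continue
        a, b = str(a), str(b)
        if a == b or not math.isfinite(s) or s < 0:
            skipped += 1
            continue
        parsed.append((a, b, s))
    if skipped:
        logger.warning("skipped %d malformed edge row(s)", skipped)
    if parsed and max(s for _, _, s in parsed) > 1.0:
        logger.info("detected 0-1000 score dialect; rescaling by 1/1000")
        parsed = [(a, b, s / 1000.0) for a, b, s in parsed]

    g = nx.Graph()
    for a, b, s in parsed:
        if s <= score_threshold:
            continue
        if restrict_to is not None and (a not in restrict_to or b not in restrict_to):
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], s)
        else:
            g.add_edge(a, b, score=s)
    if g.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"no edge passed score > {score_threshold}"
            + (" within the restriction set" if restrict_to is not None else "")
        )
    return Network(graph=g)


def shortest_paths_from(net: Network, s: str) -> tuple[dict, dict]:
    """BFS distances and shortest-path counts from a single source.

    Returns ``(dist, sigma)`` over every node of the network; unreachable
    nodes get distance ``inf`` and count 0.
    """
    if s not in net.graph:
        raise ValueError(f"source {s!r} not in network")
    dist = {v: math.inf for v in net.graph}
    sigma = {v: 0 for v in net.graph}
    dist[s] = 0
    sigma[s] = 1
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in net.graph.neighbors(v):
            if math.isinf(dist[w]):
                dist[w] = dist[v] + 1
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def read_edge_tsv(path) -> list:
    """Read a STRING-style edge file (space- or tab-separated, optional header)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.replace("\t", " ").split()
            if len(parts) < 3:
                continue
            if i == 0 and not _is_number(parts[2]):
                continue  # header line
            rows.append((parts[0], parts[1], parts[2]))
    return rows


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def write_edge_tsv(net: Network, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, s in net.edge_rows():
            fh.write(f"{a}\t{b}\t{s:.6g}\n")


def write_node_tsv(net: Network, path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tdegree\n")
        for v in sorted(net.graph.nodes):
            fh.write(f"{v}\t{net.graph.degree(v)}\n")
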