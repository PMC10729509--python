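"""Node-importance (Nim) centrality and hub selection.

For node *s* in the unweighted graph,

    Nim(s) = sqrt( B(s) * C(s) )

where ``B(s) = sum over unordered pairs {v,t}, v != s != t, of
sigma_vt(s)/sigma_vt`` is the classic unnormalized betweenness (sigma_vt the
number of shortest v-t paths, sigma_vt(s) those passing through *s*), and
``C(s) = sum over x != s of exp(-d(s, x))`` is an exponentially damped
closeness.  Pairs with no connecting path contribute 0 to B; unreachable
nodes contribute exp(-inf) = 0 to C.  The betweenness term is accumulated
with Brandes' dependency recursion (one BFS per source), which also yields
the distances the closeness term needs, so the whole table costs O(n*m).
"""

from __future__ import annotations

import logging
import math
from collections import deque

import numpy as np
import pandas as pd

from .network import Network

logger = logging.getLogger(__name__)


def compute_nim(net: Network) -> pd.DataFrame:
    """Betweenness term, exponential-closeness term, Nim and dense rank per node.

    Returns a DataFrame indexed by node symbol with columns ``betweenness``,
    ``exp_closeness``, ``nim`` and ``rank`` (1-based dense rank, highest Nim
    first).
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    nodes = sorted(g.nodes)
    betweenness = dict.fromkeys(nodes, 0.0)
    exp_closeness = dict.fromkeys(nodes, 0.0)

    for s in nodes:
        # Brandes single-source stage: BFS with predecessor lists.
        stack: list = []
        preds: dict = {v: [] for v in g}
        sigma = dict.fromkeys(g, 0)
        dist = dict.fromkeys(g, -1)
        sigma[s] = 1
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in g.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        exp_closeness[s] = sum(
            math.exp(-dist[x]) for x in g if x != s and dist[x] >= 0
        )
        # dependency accumulation (each unordered pair ends up counted twice)
        delta = dict.fromkeys(g, 0.0)
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                betweenness[w] += delta[w]

    table = pd.DataFrame(
        {
            "betweenness": [betweenness[v] / 2.0 for v in nodes],
            "exp_closeness": [exp_closeness[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    table["nim"] = np.sqrt(table["betweenness"] * table["exp_closeness"])
    table["rank"] = table["nim"].rank(method="dense", ascending=False).astype(int)
    return table


def select_hubs(table: pd.DataFrame, rule: str = "top_k", k: int = 30) -> set:
    """Pick hub nodes either above the mean Nim or as the top-k by Nim.

    ``above_mean`` uses a strict inequality against the arithmetic mean over
    all nodes (zeros included).  ``top_k`` breaks ties by higher betweenness,
    then lexicographic symbol.
    """
    if table.empty:
        raise ValueError("empty Nim table")
    if rule == "above_mean":
        mean = table["nim"].mean()
        return set(table.index[table["nim"] > mean])
    if rule == "top_k":
        if k <= 0:
            raise ValueError("k must be positive")
        if k > len(table):
            logger.warning(
                "k=%d exceeds node count %d; returning all nodes", k, len(table)
            )
            return set(table.index)
        order = table.iloc[
            np.lexsort(
                (
                    table.index.to_numpy(),
                    -table["betweenness"].to_numpy(),
                    -table["nim"].to_numpy(),
                )
            )
        ]
        return set(order.index[:k])
    raise ValueError(f"unknown hub rule {rule!r}")


def write_nim_tsv(table: pd.DataFrame, path) -> None:
    table.rename_axis("node").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
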