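"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own algorithms: betweenness and path
counts come from exhaustive enumeration of shortest paths (networkx
`all_shortest_paths`), and the hypergeometric tail from exact rational
arithmetic over binomial coefficients.
"""

from fractions import Fraction
from math import comb

import networkx as nx


def enumerate_shortest_paths(g: nx.Graph, v, t) -> list:
    """All shortest v-t paths as node lists; empty if unreachable."""
    if v == t or not nx.has_path(g, v, t):
        return []
    return list(nx.all_shortest_paths(g, v, t))


def sigma_by_enumeration(g: nx.Graph, s) -> dict:
    """Shortest-path counts from s to every node by exhaustive enumeration."""
    out = {}
    for t in g.nodes:
        if t == s:
            out[t] = 1
        else:
            out[t] = len(enumerate_shortest_paths(g, s, t))
    return out


def betweenness_by_enumeration(g: nx.Graph) -> dict:
    """Unnormalized betweenness: sum over unordered pairs of the fraction of
    shortest paths passing through each interior node."""
    bet = dict.fromkeys(g.nodes, 0.0)
    nodes = sorted(g.nodes)
    for i, v in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = enumerate_shortest_paths(g, v, t)
            if not paths:
                continue
            w = 1.0 / len(paths)
            for path in paths:
                for s in path[1:-1]:
                    bet[s] += w
    return bet


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P[X >= k] for the hypergeometric overlap, as an exact rational."""
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(num, comb(N, n))
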