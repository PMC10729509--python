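"""Over-representation analysis (ORA) against a GMT gene-set collection.

A query gene set is tested against every annotated set with the one-sided
hypergeometric tail P[X >= k] (k observed overlap, K set size, n effective
query size, N annotation universe size).  Raw p-values across the testable
sets (overlap >= 1) are Benjamini-Hochberg adjusted; the reported q-value is
that BH-adjusted p, so the screen "p < 0.05 and q < 0.05" reduces to the
adjusted p falling below 0.05.  The universe is the union of all annotated
symbols; query genes outside it are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyResultError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over an annotation universe (GMT-backed)."""

    sets: dict  # set_id -> (description, frozenset of symbols)
    universe: frozenset

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members <= self.universe:
                raise ValueError(f"set {set_id!r} has members outside the universe")

    @classmethod
    def from_sets(cls, sets: dict, universe=None) -> "GeneSetCollection":
        norm = {
            sid: (desc, frozenset(members)) for sid, (desc, members) in sets.items()
        }
        if universe is None:
            universe = frozenset().union(*(m for _, m in norm.values())) if norm else frozenset()
        return cls(sets=norm, universe=frozenset(universe))

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets[parts[0]] = (parts[1], frozenset(p for p in parts[2:] if p))
        return cls.from_sets(sets)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for sid in sorted(self.sets):
                desc, members = self.sets[sid]
                fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")

    def __len__(self) -> int:
        return len(self.sets)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    X counts the overlap when drawing ``n`` genes without replacement from a
    universe of ``N`` containing ``K`` marked genes.  Computed via the
    survival function of the hypergeometric distribution (log-space stable).
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving with the input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query,
    collection: GeneSetCollection,
    p_cut: float = 0.05,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """One-row-per-set ORA table, sorted by ascending p-value.

    Only sets overlapping the query (k >= 1) are tested and reported; the BH
    adjustment runs across exactly those tests.
    """
    query = set(query)
    effective = query & collection.universe
    dropped = len(query) - len(effective)
    if dropped:
        logger.info("%d query gene(s) outside the annotation universe dropped", dropped)
    if not effective:
        raise EmptyResultError("query does not intersect the annotation universe")
    N = len(collection.universe)
    n = len(effective)
    rows = []
    for sid in sorted(collection.sets):
        _, members = collection.sets[sid]
        k = len(members & effective)
        if k == 0:
            continue
        rows.append((sid, k, len(members)))
    if not rows:
        raise EmptyResultError("no gene set overlaps the query")
    p = np.array([hypergeom_tail(k, K, n, N) for _, k, K in rows])
    p_adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "set_id": [r[0] for r in rows],
            "k": [r[1] for r in rows],
            "K": [r[2] for r in rows],
            "n": n,
            "N": N,
            "p_value": p,
            "p_adjusted": p_adj,
        }
    )
    out["q_value"] = out["p_adjusted"]
    out["passes"] = (out["p_value"] < p_cut) & (out["q_value"] < q_cut)
    out = out.sort_values(["p_value", "set_id"], kind="stable").reset_index(drop=True)
    return out


def genes_in_set(collection: GeneSetCollection, set_id: str, restrict) -> set:
    """Members of one annotated set intersected with a restriction set."""
    if set_id not in collection.sets:
        raise ValueError(f"unknown set id {set_id!r}")
    _, members = collection.sets[set_id]
    return set(members) & set(restrict)


def write_enrichment_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
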