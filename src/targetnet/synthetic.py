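"""Synthetic study generators with planted, recoverable ground truth.

Every pipeline input can be generated here so the whole analysis is testable
offline: a two-group log2 expression matrix with planted fold-change effects
and i.i.d. Gaussian noise, disease-gene source tables straddling each
database's filter boundary, an Erdos-Renyi background interaction graph with
a planted dense clique (clique edges carry high confidence scores), and a
gene-set collection with one planted over-represented set.  A composite
:func:`simulate_study` wires the four together so that the planted target
genes simultaneously satisfy all three prioritization criteria — membership
in the dense module, a top Nim rank, and membership in the planted pathway —
making end-to-end recovery checkable against :class:`SyntheticTruth`.

All generators are pure functions of their arguments: one integer seed fully
determines the output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .deg import CASE, CONTROL, ExpressionMatrix
from .disease_genes import SourceRecord, SourceTable
from .enrichment import GeneSetCollection
from .network import Network


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for a synthetic study."""

    de_genes: frozenset = frozenset()
    clique_genes: frozenset = frozenset()
    enriched_set_id: Optional[str] = None
    target_genes: frozenset = frozenset()
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "de_genes": sorted(self.de_genes),
                    "clique_genes": sorted(self.clique_genes),
                    "enriched_set_id": self.enriched_set_id,
                    "target_genes": sorted(self.target_genes),
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )


def gene_symbols(n: int, prefix: str = "G") -> list:
    """Synthesized symbols G0001, G0002, ... (no live nomenclature needed)."""
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(
    n_genes: int,
    n_per_group: int,
    n_de: int,
    effect_log2fc: float,
    noise_sd: float,
    seed: int,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-group log2 expression matrix with ``n_de`` planted effects.

    Half of the planted genes are shifted up in the case group and half down
    (odd remainder up) by ``effect_log2fc``; every value is its group mean
    plus i.i.d. Gaussian(0, noise_sd) noise.
    """
    if n_genes <= 0 or n_per_group < 2:
        raise ValueError("need n_genes >= 1 and n_per_group >= 2")
    if not 0 <= n_de <= n_genes:
        raise ValueError("n_de must lie in [0, n_genes]")
    if effect_log2fc <= 0 or noise_sd <= 0:
        raise ValueError("effect_log2fc and noise_sd must be positive")
    rng = np.random.default_rng(seed)
    genes = gene_symbols(n_genes)
    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    n_up = (n_de + 1) // 2
    shift = np.zeros(n_genes)
    shift[de_idx[:n_up]] = effect_log2fc
    shift[de_idx[n_up:]] = -effect_log2fc

    ctrl_mean = baseline[:, None]
    case_mean = (baseline + shift)[:, None]
    noise = rng.normal(0.0, noise_sd, size=(n_genes, 2 * n_per_group))
    values = np.hstack(
        [
            ctrl_mean + noise[:, :n_per_group],
            case_mean + noise[:, n_per_group:],
        ]
    )
    samples = [f"ctrl_{i:02d}" for i in range(1, n_per_group + 1)] + [
        f"case_{i:02d}" for i in range(1, n_per_group + 1)
    ]
    groups = pd.Series(
        [CONTROL] * n_per_group + [CASE] * n_per_group, index=samples, name="group"
    )
    matrix = ExpressionMatrix(
        data=pd.DataFrame(values, index=genes, columns=samples), groups=groups
    )
    truth = SyntheticTruth(
        de_genes=frozenset(genes[i] for i in de_idx), seed=seed
    )
    return matrix, truth


def simulate_ppi(
    n_background: int,
    p_edge: float,
    clique_size: int,
    seed: int,
    symbols: Optional[Sequence[str]] = None,
) -> tuple[Network, SyntheticTruth]:
    """Erdos-Renyi background graph with a planted clique.

    The first ``clique_size`` node labels form the clique; its edges carry
    confidence scores uniform in (0.9, 1.0], background edges uniform in
    (0, 1.0], so the high-confidence filter of the pipeline preserves the
    planted structure while thinning the background.
    """
    if not 0.0 < p_edge < 1.0:
        raise ValueError("p_edge must lie strictly inside (0, 1)")
    if clique_size < 3 or clique_size > n_background:
        raise ValueError("need 3 <= clique_size <= n_background")
    labels = list(symbols) if symbols is not None else gene_symbols(n_background, "N")
    if len(labels) != n_background or len(set(labels)) != n_background:
        raise ValueError("symbols must provide n_background unique labels")
    rng = np.random.default_rng(seed)
    clique = labels[:clique_size]
    g = nx.Graph()
    g.add_nodes_from(labels)
    clique_set = set(clique)
    for a, b in combinations(labels, 2):
        in_clique = a in clique_set and b in clique_set
        if in_clique or rng.random() < p_edge:
            if in_clique:
                score = 0.9 + 0.1 * rng.random()
            else:
                score = rng.uniform(0.0, 1.0)
                if score == 0.0:
                    score = 0.5
            g.add_edge(a, b, score=float(score))
    truth = SyntheticTruth(clique_genes=frozenset(clique), seed=seed)
    return Network(graph=g), truth


def simulate_genesets(
    universe,
    n_sets: int,
    set_size_range: tuple[int, int],
    planted_members,
    seed: int,
    exclude_from_fill=frozenset(),
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Random gene-set collection with one planted set covering ``planted_members``.

    The planted set is topped up with random fill (never drawn from
    ``exclude_from_fill``); the remaining sets are uniform draws from the
    universe.  The collection's universe is the full symbol universe passed
    in, so hypergeometric tests use a fixed N.
    """
    universe = sorted(set(universe))
    planted = sorted(set(planted_members))
    if not set(planted) <= set(universe):
        raise ValueError("planted_members must be a subset of the universe")
    if n_sets < 1:
        raise ValueError("n_sets must be positive")
    lo, hi = set_size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError("invalid set_size_range")
    rng = np.random.default_rng(seed)
    planted_pos = 0  # planted set takes the first id; ids carry no signal
    sets = {}
    ids = [f"S{i:03d}" for i in range(1, n_sets + 1)]
    for i, sid in enumerate(ids):
        if i == planted_pos:
            target_size = max(lo, len(planted))
            if target_size > len(planted):
                pool = sorted(
                    set(universe) - set(planted) - set(exclude_from_fill)
                )
                extra = rng.choice(
                    len(pool), size=min(target_size - len(planted), len(pool)),
                    replace=False,
                )
                members = set(planted) | {pool[j] for j in extra}
            else:
                members = set(planted)
            sets[sid] = ("planted", frozenset(members))
        else:
            size = int(rng.integers(lo, hi + 1))
            idx = rng.choice(len(universe), size=size, replace=False)
            sets[sid] = ("random", frozenset(universe[j] for j in idx))
    collection = GeneSetCollection.from_sets(sets, universe=universe)
    truth = SyntheticTruth(enriched_set_id=ids[planted_pos], seed=seed)
    return collection, truth


def simulate_sources(universe, seed: int, n_per_source: int = 8) -> list:
    """Disease-gene source tables whose records straddle each filter boundary.

    Each of the six databases contributes ``n_per_source`` records drawn from
    the universe; roughly half are constructed to survive that database's
    inclusion rule (scores above the strict cutoffs, admissible evidence
    tags, present Entrez ids) and half to be excluded, including exact
    boundary values.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(set(universe))
    tables = []

    def pick(k: int) -> list:
        idx = rng.choice(len(universe), size=min(k, len(universe)), replace=False)
        return [universe[i] for i in idx]

    ctd_tags = ["marker/mechanism", "marker/mechanism | therapeutic", "therapeutic"]
    ctd_bad = ["", "curated", "inference"]
    recs = []
    for i, s in enumerate(pick(n_per_source)):
        tag = ctd_tags[i % 3] if i % 2 == 0 else ctd_bad[i % 3]
        recs.append(SourceRecord(symbol=s, evidence=tag or None))
    tables.append(SourceTable("CTD", tuple(recs)))

    recs = []
    for i, s in enumerate(pick(n_per_source)):
        # even rows clear the 0.1 cutoff, odd rows sit at or below it
        score = 0.1 if i == 1 else (0.2 + 0.6 * rng.random() if i % 2 == 0 else 0.05)
        recs.append(SourceRecord(symbol=s, score=float(score)))
    tables.append(SourceTable("DisGeNET", tuple(recs)))

    recs = []
    for i, s in enumerate(pick(n_per_source)):
        score = 5.0 if i == 1 else (6.0 + 20.0 * rng.random() if i % 2 == 0 else 2.0)
        recs.append(SourceRecord(symbol=s, score=float(score)))
    tables.append(SourceTable("GeneCards", tuple(recs)))

    recs = []
    for i, s in enumerate(pick(n_per_source)):
        recs.append(
            SourceRecord(
                symbol=s,
                entrez_id=str(1000 + i) if i % 2 == 0 else None,
            )
        )
    tables.append(SourceTable("OMIM", tuple(recs)))

    for name in ("PharmGKB", "TTD"):
        recs = tuple(SourceRecord(symbol=s) for s in pick(max(2, n_per_source // 2)))
        tables.append(SourceTable(name, recs))
    return tables


@dataclass(frozen=True)
class StudyBundle:
    """All generated inputs of one synthetic study plus its planted truth."""

    expression: ExpressionMatrix
    sources: list
    ppi: Network
    collection: GeneSetCollection
    truth: SyntheticTruth


def simulate_study(
    seed: int,
    n_genes: int = 400,
    n_per_group: int = 32,
    n_de: int = 80,
    effect_log2fc: float = 3.0,
    noise_sd: float = 0.5,
    ppi_n: int = 150,
    p_edge: float = 0.05,
    clique_size: int = 12,
    n_targets: int = 5,
    n_target_links: int = 4,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 25),
) -> StudyBundle:
    """Generate a coherent synthetic study in which the planted targets are
    recoverable by the full pipeline.

    The planted clique is drawn from the planted differentially expressed
    genes (so it survives restriction of the network to the disease gene
    set); the planted pathway contains the target genes plus fill drawn away
    from the rest of the clique (so the triple intersection equals the
    targets exactly under strong planting).  Each target additionally
    receives ``n_target_links`` exclusive high-confidence edges to disease
    genes outside the module: targets are planted as *bridging hubs* — the
    role apolipoprotein-like genes play in a real disease network — which is
    what makes the module, centrality and pathway criteria simultaneously
    satisfiable rather than vacuously coincident.
    """
    if not 3 <= n_targets <= clique_size:
        raise ValueError("need 3 <= n_targets <= clique_size")
    if clique_size > n_de:
        raise ValueError("clique must fit inside the planted DE genes")
    if ppi_n > n_genes:
        raise ValueError("ppi_n cannot exceed n_genes")
    rng = np.random.default_rng(seed)

    expression, truth_e = simulate_expression(
        n_genes, n_per_group, n_de, effect_log2fc, noise_sd, seed=int(rng.integers(2**31))
    )
    de = sorted(truth_e.de_genes)
    perm = rng.permutation(len(de))
    clique = [de[i] for i in perm[:clique_size]]
    targets = sorted(clique[:n_targets])
    other_de = [de[i] for i in perm[clique_size:]]

    # network node labels: clique first, then other DE genes, then background
    all_genes = list(expression.data.index)
    non_de = [g for g in all_genes if g not in set(de)]
    rng.shuffle(non_de)
    n_extra_de = min(len(other_de), max(0, ppi_n - clique_size) // 2)
    labels = clique + other_de[:n_extra_de]
    labels += non_de[: ppi_n - len(labels)]
    ppi, truth_p = simulate_ppi(
        len(labels), p_edge, clique_size, seed=int(rng.integers(2**31)), symbols=labels
    )
    # plant the targets as bridging hubs: exclusive high-confidence edges to
    # DE genes outside the clique, so their betweenness (and hence Nim) is
    # high by construction, not by background accident
    anchors = other_de[:n_extra_de]
    if n_targets * n_target_links > len(anchors):
        raise ValueError("not enough non-module DE genes to anchor the targets")
    for i, t in enumerate(targets):
        for j in range(n_target_links):
            a = anchors[i * n_target_links + j]
            ppi.graph.add_edge(t, a, score=0.95 + 0.05 * float(rng.random()))

    # planted pathway: targets + strongly overlapping DE fill, avoiding the
    # rest of the clique so the intersection stays exactly the targets
    pathway_extra = other_de[: max(0, set_size_range[0] + 5 - n_targets)]
    planted_members = set(targets) | set(pathway_extra)
    collection, truth_s = simulate_genesets(
        all_genes,
        n_sets,
        set_size_range,
        planted_members,
        seed=int(rng.integers(2**31)),
        exclude_from_fill=set(clique),
    )

    sources = simulate_sources(all_genes, seed=int(rng.integers(2**31)))
    truth = SyntheticTruth(
        de_genes=truth_e.de_genes,
        clique_genes=truth_p.clique_genes,
        enriched_set_id=truth_s.enriched_set_id,
        target_genes=frozenset(targets),
        seed=seed,
    )
    return StudyBundle(
        expression=expression,
        sources=sources,
        ppi=ppi,
        collection=collection,
        truth=truth,
    )


def write_expression_tsv(matrix: ExpressionMatrix, matrix_path, groups_path) -> None:
    matrix.data.rename_axis("gene").to_csv(matrix_path, sep="\t", float_format="%.6f")
    matrix.groups.rename_axis("sample").to_frame("group").to_csv(groups_path, sep="\t")


def write_source_tsv(table: SourceTable, path) -> None:
    rows = [
        {
            "symbol": r.symbol,
            "score": "" if r.score is None else r.score,
            "evidence": "" if r.evidence is None else r.evidence,
            "entrez_id": "" if r.entrez_id is None else r.entrez_id,
        }
        for r in table.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
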