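"""End-to-end orchestration: screen, assemble, build, rank, cluster, enrich,
intersect.

The final prioritization step intersects three gene sets:

1. members of the top-scoring dense module of the disease interaction network,
2. the top-k (default 30) genes by Nim centrality,
3. members of a chosen pathway restricted to the network's genes,

and reports per-gene provenance for every gene appearing in any of the three.
An empty intersection is a valid, explicitly reported outcome.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import centrality, deg, disease_genes, enrichment, mcode, network, synthetic
from .errors import StageError, TargetNetError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full effective configuration of one pipeline run."""

    # input mode
    synthetic: bool = True
    seed: int = 0
    # synthetic-study parameters (see synthetic.simulate_study)
    n_genes: int = 400
    n_per_group: int = 32
    n_de: int = 80
    effect_log2fc: float = 3.0
    noise_sd: float = 0.5
    ppi_n: int = 150
    p_edge: float = 0.05
    clique_size: int = 12
    n_targets: int = 5
    n_target_links: int = 4
    n_sets: int = 20
    set_size_range: tuple = (10, 25)
    # file inputs (used when synthetic is false)
    matrix_path: Optional[str] = None
    groups_path: Optional[str] = None
    source_paths: tuple = ()  # (path, source_name) pairs
    synonyms_path: Optional[str] = None
    edges_path: Optional[str] = None
    gmt_path: Optional[str] = None
    # analysis parameters
    deg_method: str = "moderated"
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    quantile_normalize: bool = False
    score_threshold: float = 0.9
    hub_rule: str = "top_k"
    hub_k: int = 30
    mcode_params: mcode.McodeParams = field(default_factory=mcode.McodeParams)
    pathway_set_id: Optional[str] = None  # synthetic default: the planted set
    p_cut: float = 0.05
    q_cut: float = 0.05
    outdir: Optional[str] = None

    _SECTIONS = {
        "synthetic_data": {
            "synthetic", "seed", "n_genes", "n_per_group", "n_de", "effect_log2fc",
            "noise_sd", "ppi_n", "p_edge", "clique_size", "n_targets", "n_target_links", "n_sets",
            "set_size_range",
        },
        "deg_screen": {
            "matrix_path", "groups_path", "deg_method", "fc_threshold",
            "p_threshold", "quantile_normalize",
        },
        "disease_gene_assembly": {"source_paths", "synonyms_path"},
        "network_core": {"edges_path", "score_threshold"},
        "nim_centrality": {"hub_rule", "hub_k"},
        "module_detection": {"mcode_params"},
        "enrichment": {"gmt_path", "pathway_set_id", "p_cut", "q_cut"},
        "pipeline": {"outdir", "seed", "synthetic"},
    }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Accept either a flat mapping or sections mirroring the module names."""
        flat: dict = {}
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        for key, value in d.items():
            if key in cls._SECTIONS and isinstance(value, dict):
                for k, v in value.items():
                    if k not in cls._SECTIONS[key]:
                        raise TargetNetError(f"unknown config key {key}.{k}")
                    flat[k] = v
            elif key in known:
                flat[key] = value
            else:
                raise TargetNetError(f"unknown config key {key}")
        if "mcode_params" in flat and isinstance(flat["mcode_params"], dict):
            flat["mcode_params"] = mcode.McodeParams(**flat["mcode_params"])
        if "set_size_range" in flat:
            flat["set_size_range"] = tuple(flat["set_size_range"])
        if "source_paths" in flat:
            flat["source_paths"] = tuple(tuple(p) for p in flat["source_paths"])
        return cls(**flat)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mcode_params"] = dataclasses.asdict(self.mcode_params)
        d["set_size_range"] = list(self.set_size_range)
        d["source_paths"] = [list(p) for p in self.source_paths]
        return d


@dataclass
class PrioritizationReport:
    """The three criterion sets, their intersection, and per-gene provenance."""

    module_genes: set
    nim_top: set
    pathway_genes: set
    intersection: set
    provenance: dict
    config_echo: dict = field(default_factory=dict)
    log: list = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "module_genes": sorted(self.module_genes),
            "nim_top": sorted(self.nim_top),
            "pathway_genes": sorted(self.pathway_genes),
            "intersection": sorted(self.intersection),
            "provenance": {g: self.provenance[g] for g in sorted(self.provenance)},
            "config_echo": self.config_echo,
            "log": list(self.log),
            "details": self.details,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def prioritize(
    module_genes,
    nim_top,
    pathway_genes,
    config_echo: Optional[dict] = None,
    log: Optional[list] = None,
) -> PrioritizationReport:
    """Three-way intersection with per-gene provenance over the union."""
    module_genes, nim_top, pathway_genes = (
        set(module_genes),
        set(nim_top),
        set(pathway_genes),
    )
    intersection = module_genes & nim_top & pathway_genes
    provenance = {
        g: {
            "in_module": g in module_genes,
            "in_nim_top": g in nim_top,
            "in_pathway": g in pathway_genes,
        }
        for g in module_genes | nim_top | pathway_genes
    }
    return PrioritizationReport(
        module_genes=module_genes,
        nim_top=nim_top,
        pathway_genes=pathway_genes,
        intersection=intersection,
        provenance=provenance,
        config_echo=config_echo or {},
        log=list(log) if log else [],
    )


def _load_inputs(config: PipelineConfig, log: list):
    if config.synthetic:
        bundle = synthetic.simulate_study(
            seed=config.seed,
            n_genes=config.n_genes,
            n_per_group=config.n_per_group,
            n_de=config.n_de,
            effect_log2fc=config.effect_log2fc,
            noise_sd=config.noise_sd,
            ppi_n=config.ppi_n,
            p_edge=config.p_edge,
            clique_size=config.clique_size,
            n_targets=config.n_targets,
            n_target_links=config.n_target_links,
            n_sets=config.n_sets,
            set_size_range=config.set_size_range,
        )
        log.append(f"synthetic study generated with seed {config.seed}")
        return (
            bundle.expression,
            bundle.sources,
            bundle.ppi.edge_rows(),
            bundle.collection,
            None,
            bundle.truth,
        )
    if not (config.matrix_path and config.groups_path and config.edges_path and config.gmt_path):
        raise TargetNetError(
            "file mode needs matrix_path, groups_path, edges_path and gmt_path"
        )
    matrix = deg.ExpressionMatrix.from_tsv(config.matrix_path, config.groups_path)
    sources = [
        disease_genes.SourceTable.from_tsv(path, name)
        for path, name in config.source_paths
    ]
    edge_rows = network.read_edge_tsv(config.edges_path)
    collection = enrichment.GeneSetCollection.from_gmt(config.gmt_path)
    universe = (
        disease_genes.GeneUniverse.from_tsv(config.synonyms_path)
        if config.synonyms_path
        else None
    )
    log.append("inputs loaded from files")
    return matrix, sources, edge_rows, collection, universe, None


def run_all(config: PipelineConfig) -> PrioritizationReport:
    """Execute every stage and return the final prioritization report.

    Identical config (and seed, in synthetic mode) yields an identical
    report.  Any stage failure is re-raised as :class:`StageError` carrying
    the stage name.
    """
    log: list = []
    outdir = config.outdir
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, exc) from exc

    matrix, sources, edge_rows, collection, universe, truth = _stage(
        "inputs", lambda: _load_inputs(config, log)
    )
    if config.quantile_normalize:
        matrix = matrix.quantile_normalize()

    def _deg():
        table = deg.test_two_groups(matrix, method=config.deg_method)
        up, down = deg.screen_degs(table, config.fc_threshold, config.p_threshold)
        return table, up, down

    deg_table, up, down = _stage("deg_screen", _deg)
    log.append(f"deg_screen: {len(up)} up, {len(down)} down")

    disease_set = _stage(
        "disease_gene_assembly",
        lambda: disease_genes.assemble_disease_set(up | down, sources, universe),
    )
    log.append(f"disease_gene_assembly: {len(disease_set)} genes")

    net = _stage(
        "network_core",
        lambda: network.build_network(
            edge_rows, config.score_threshold, restrict_to=disease_set
        ),
    )
    log.append(f"network_core: {net.n_nodes} nodes, {net.n_edges} edges")

    nim_table = _stage("nim_centrality", lambda: centrality.compute_nim(net))
    nim_top = _stage(
        "nim_centrality",
        lambda: centrality.select_hubs(nim_table, config.hub_rule, config.hub_k),
    )
    log.append(f"nim_centrality: {len(nim_top)} hub genes ({config.hub_rule})")

    modules = _stage(
        "module_detection", lambda: mcode.find_modules(net, config.mcode_params)
    )
    module_genes = set(modules[0].members) if modules else set()
    log.append(
        f"module_detection: {len(modules)} modules; top size {len(module_genes)}"
    )

    enr = _stage(
        "enrichment",
        lambda: enrichment.enrich(disease_set, collection, config.p_cut, config.q_cut),
    )
    pathway_id = config.pathway_set_id
    if pathway_id is None:
        if truth is not None and truth.enriched_set_id is not None:
            pathway_id = truth.enriched_set_id
        else:
            passing = enr[enr["passes"]]
            if passing.empty:
                raise StageError(
                    "enrichment", TargetNetError("no pathway passes the p/q screen")
                )
            pathway_id = str(passing.iloc[0]["set_id"])
    pathway_genes = _stage(
        "enrichment",
        lambda: enrichment.genes_in_set(collection, pathway_id, restrict=net.nodes),
    )
    log.append(
        f"enrichment: {int(enr['passes'].sum())} sets pass; "
        f"pathway {pathway_id} -> {len(pathway_genes)} network genes"
    )

    report = prioritize(
        module_genes, nim_top, pathway_genes,
        config_echo=config.to_dict(), log=log,
    )
    report.details = {
        "n_up": len(up),
        "n_down": len(down),
        "n_disease_genes": len(disease_set),
        "n_network_nodes": net.n_nodes,
        "n_network_edges": net.n_edges,
        "n_modules": len(modules),
        "top_module_size": len(module_genes),
        "n_enriched_sets_passing": int(enr["passes"].sum()),
        "pathway_set_id": pathway_id,
    }
    if truth is not None:
        report.details["truth"] = {
            "de_genes": sorted(truth.de_genes),
            "clique_genes": sorted(truth.clique_genes),
            "enriched_set_id": truth.enriched_set_id,
            "target_genes": sorted(truth.target_genes),
        }
    log.append(f"prioritize: intersection of size {len(report.intersection)}")

    if outdir:
        deg.write_deg_tsv(
            deg.flag_degs(deg_table, config.fc_threshold, config.p_threshold),
            os.path.join(outdir, "deg_table.tsv"),
        )
        disease_genes.write_gene_list(
            disease_set, os.path.join(outdir, "disease_genes.tsv")
        )
        network.write_edge_tsv(net, os.path.join(outdir, "network_edges.tsv"))
        centrality.write_nim_tsv(nim_table, os.path.join(outdir, "nim_table.tsv"))
        mcode.write_modules_tsv(modules, os.path.join(outdir, "modules.tsv"))
        enrichment.write_enrichment_tsv(enr, os.path.join(outdir, "enrichment.tsv"))
        report.to_json(os.path.join(outdir, "report.json"))
        with open(os.path.join(outdir, "run.log"), "w") as fh:
            fh.write("\n".join(log) + "\n")
    return report
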