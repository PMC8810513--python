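"""End-to-end comorbidity pipeline: gene sets -> enrichment -> cross-talk
-> interactome overlap -> candidate prediction.

``run_all`` reads two disease gene lists (TSV), a pathway collection
(GMT), and an interactome edge list (TSV), applies the standard
thresholds (GDA score > 0.2, FDR < 0.05, cross-talk minimums, candidate
count >= 6), and writes every intermediate table plus a machine-readable
``summary.json`` whose stage counts satisfy the set-algebra identities by
construction.  Identical inputs produce byte-identical outputs: all
tables are deterministically sorted and no timestamps enter data files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import crosstalk as ct
from . import enrichment as en
from . import genesets as gs
from . import network as nw

logger = logging.getLogger(__name__)


class PipelineConfigError(Exception):
    """Configuration problem detected before any computation."""


class PipelineStageError(Exception):
    """A stage failed; the stage name is carried in the message."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    genes_a: str | Path = ""
    genes_b: str | Path = ""
    gmt: str | Path = ""
    ppin: str | Path = ""
    out_dir: str | Path = "comorbnet_out"
    label_a: str = "disease_a"
    label_b: str = "disease_b"
    gda_threshold: float = 0.2
    alpha: float = 0.05
    min_genes: int = 3
    min_shared: int = 2
    min_count: int = 6
    neighborhood_min_count: int = 9
    exclude: tuple[int, ...] = tuple(sorted(nw.UBIQUITIN_GENES))
    extraction_rule: str = "edge_incident"
    restrict_to_disease_genes: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        if "exclude" in raw:
            raw["exclude"] = tuple(int(g) for g in raw["exclude"])
        if "pathway" in raw:
            raise PipelineConfigError("unexpected key 'pathway'")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("genes_a", "genes_b", "gmt", "ppin"):
            value = getattr(self, name)
            if not value:
                raise PipelineConfigError(f"missing required input path {name!r}")
            if not Path(value).is_file():
                raise PipelineConfigError(f"input file for {name!r} not found: {value}")
        if not (0.0 <= self.gda_threshold <= 1.0):
            raise PipelineConfigError("gda_threshold must lie in [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise PipelineConfigError("alpha must lie in (0, 1)")
        if self.min_genes < 1 or self.min_shared < 1 or self.min_count < 1:
            raise PipelineConfigError("minimum counts must be >= 1")
        if self.extraction_rule not in ("edge_incident", "induced"):
            raise PipelineConfigError(f"unknown extraction_rule {self.extraction_rule!r}")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the summary dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    # --- stage: genesets -------------------------------------------------
    try:
        set_a = gs.apply_gda_policy(
            gs.read_gene_list(config.genes_a, config.label_a), config.gda_threshold
        )
        set_b = gs.apply_gda_policy(
            gs.read_gene_list(config.genes_b, config.label_b), config.gda_threshold
        )
        shared = gs.intersect_gene_sets(set_a, set_b, "shared")
        union_genes = gs.merge_gene_sets(set_a, set_b, "all_disease")
        gs.write_gene_list(set_a, out / "genes_a_filtered.tsv")
        gs.write_gene_list(set_b, out / "genes_b_filtered.tsv")
        gs.write_gene_list(shared, out / "shared_genes.tsv")
        summary["genes"] = {
            "n_a": len(set_a),
            "n_b": len(set_b),
            "n_shared": len(shared),
            "n_union": len(union_genes),
        }
    except Exception as exc:  # noqa: BLE001 - stage name must propagate
        raise PipelineStageError("genesets", exc) from exc

    # --- stage: enrichment -----------------------------------------------
    try:
        collection = en.read_gmt(config.gmt)
        results_a = en.run_enrichment(set_a, collection, config.alpha)
        results_b = en.run_enrichment(set_b, collection, config.alpha)
        classification = en.classify_pathways(results_a, results_b, config.alpha)
        en.write_enrichment(results_a, out / "enrichment_a.tsv")
        en.write_enrichment(results_b, out / "enrichment_b.tsv")
        (out / "pathway_classification.json").write_text(
            json.dumps(
                {
                    "shared": sorted(classification.shared),
                    "a_specific": sorted(classification.a_specific),
                    "b_specific": sorted(classification.b_specific),
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        summary["enrichment"] = {
            "n_pathways": len(collection),
            "n_background": len(collection.background),
            "n_significant_a": len(classification.shared) + len(classification.a_specific),
            "n_significant_b": len(classification.shared) + len(classification.b_specific),
            "n_shared_pathways": len(classification.shared),
            "n_a_specific": len(classification.a_specific),
            "n_b_specific": len(classification.b_specific),
        }
    except Exception as exc:
        raise PipelineStageError("enrichment", exc) from exc

    # --- stage: crosstalk ------------------------------------------------
    try:
        basis = union_genes if config.restrict_to_disease_genes else None
        memberships = ct.restrict_memberships(collection, basis or collection.background)

        shared_memberships = [m for m in memberships if m.pathway_id in classification.shared]
        pp_edges = ct.build_crosstalk_network(
            shared_memberships, config.min_genes, config.min_shared,
            use_full_members=not config.restrict_to_disease_genes,
        )
        tripartite = ct.build_tripartite(pp_edges, shared_memberships, shared)
        ct.edges_to_frame(pp_edges).to_csv(out / "crosstalk_edges.tsv", sep="\t", index=False)
        gene_classes = {g: "shared" for g in shared.gene_ids}
        ct.export_network(tripartite, out / "crosstalk_shared.graphml", "graphml", gene_classes)
        ct.export_network(tripartite, out / "crosstalk_shared.sif", "sif")

        specific_ids = classification.a_specific | classification.b_specific
        specific_memberships = [m for m in memberships if m.pathway_id in specific_ids]
        sp_edges = ct.build_crosstalk_network(
            specific_memberships, config.min_genes, config.min_shared,
            use_full_members=not config.restrict_to_disease_genes,
        )
        sp_net = ct.build_tripartite(sp_edges, specific_memberships, union_genes)
        node_classes: dict = {p: "a_specific" for p in classification.a_specific}
        node_classes.update({p: "b_specific" for p in classification.b_specific})
        for g in union_genes.gene_ids:
            if g in shared.gene_ids:
                node_classes[g] = "shared"
            elif g in set_a.gene_ids:
                node_classes[g] = "a"
            else:
                node_classes[g] = "b"
        ct.export_network(sp_net, out / "crosstalk_specific.graphml", "graphml", node_classes)
        summary["crosstalk"] = {
            "shared_net": {
                "n_pathway_nodes": len(tripartite.pathway_nodes),
                "n_gene_nodes": len(tripartite.gene_nodes),
                "n_pp_edges": len(tripartite.pathway_pathway_edges),
                "n_pg_edges": len(tripartite.pathway_gene_edges),
            },
            "specific_net": {
                "n_pathway_nodes": len(sp_net.pathway_nodes),
                "n_gene_nodes": len(sp_net.gene_nodes),
                "n_pp_edges": len(sp_net.pathway_pathway_edges),
                "n_pg_edges": len(sp_net.pathway_gene_edges),
            },
        }
    except Exception as exc:
        raise PipelineStageError("crosstalk", exc) from exc

    # --- stage: network --------------------------------------------------
    try:
        raw_net = nw.read_edge_list(config.ppin)
        ppin = nw.merge_interactomes([raw_net], exclude=frozenset(config.exclude))
        net_a = nw.extract_disease_network(ppin, set_a, config.extraction_rule)
        net_b = nw.extract_disease_network(ppin, set_b, config.extraction_rule)
        union_net = nw.union_networks(net_a, net_b)
        overlap = nw.intersect_networks(net_a, net_b)
        counts = nw.shared_gene_neighbor_count(overlap, shared)
        known = union_genes.gene_ids
        first_neighbors = [
            g for g, c in counts.items() if c >= 1 and g not in known
        ]
        ranking = nw.predict_candidates(counts, union_genes, config.min_count)
        union_degree = union_net.degree()
        symbols = {r.gene_id: r.symbol for r in union_genes.records}
        nw.ranking_to_frame(ranking, union_degree, symbols).to_csv(
            out / "candidate_ranking.tsv", sep="\t", index=False
        )
        nw.write_edge_list(overlap, out / "overlap_network.tsv")
        nw.export_interactome_graphml(overlap, out / "overlap_network.graphml")

        top = [
            e.gene_id
            for e in ranking.novel
            if e.shared_neighbor_count >= config.neighborhood_min_count
        ]
        n_top_nodes = n_top_edges = 0
        if top:
            annot = {
                "shared": shared.gene_ids,
                "a": set_a.gene_ids - shared.gene_ids,
                "b": set_b.gene_ids - shared.gene_ids,
            }
            hood = nw.extract_candidate_neighborhood(union_net, top, annot)
            nw.export_interactome_graphml(
                hood.network, out / "candidate_neighborhood.graphml", hood.node_classes
            )
            n_top_nodes, n_top_edges = hood.network.n_nodes, hood.network.n_edges
        summary["network"] = {
            "interactome_nodes": ppin.n_nodes,
            "interactome_edges": ppin.n_edges,
            "a_net_nodes": net_a.network.n_nodes,
            "a_net_edges": net_a.network.n_edges,
            "b_net_nodes": net_b.network.n_nodes,
            "b_net_edges": net_b.network.n_edges,
            "union_net_nodes": union_net.n_nodes,
            "union_net_edges": union_net.n_edges,
            "overlap_net_nodes": overlap.n_nodes,
            "overlap_net_edges": overlap.n_edges,
            "n_first_neighbors": len(first_neighbors),
            "n_novel_candidates": len(ranking),
            "n_top_candidates": len(top),
            "neighborhood_nodes": n_top_nodes,
            "neighborhood_edges": n_top_edges,
        }
    except Exception as exc:
        raise PipelineStageError("network", exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
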