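"""Pathway cross-talk networks from set-overlap coefficients.

Two pathways "talk" when the disease genes they contain overlap.  Overlap
is scored with the Jaccard coefficient JC = |A∩B| / |A∪B| and the overlap
coefficient OC = |A∩B| / min(|A|, |B|); always JC <= OC, OC = 1 whenever
one set contains the other.  Pathway pairs passing a minimum-membership
and minimum-shared-gene criterion become edges of the cross-talk network,
and attaching each retained pathway's member genes yields a
pathway–pathway–gene tripartite network suitable for Cytoscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .enrichment import PathwayCollection
from .genesets import GeneSet


class EmptySetError(Exception):
    """Overlap coefficients are undefined for empty sets."""


class UnknownFormatError(Exception):
    """Unsupported network export format."""


def jaccard(a: Iterable[int], b: Iterable[int]) -> float:
    """|A∩B| / |A∪B|.  Raises :class:`EmptySetError` when both are empty."""
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        raise EmptySetError("Jaccard coefficient undefined for two empty sets")
    return len(sa & sb) / len(union)


def overlap_coefficient(a: Iterable[int], b: Iterable[int]) -> float:
    """|A∩B| / min(|A|, |B|).  Raises when either set is empty."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise EmptySetError("overlap coefficient undefined for an empty set")
    return len(sa & sb) / min(len(sa), len(sb))


@dataclass(frozen=True)
class PathwayMembership:
    """A pathway's full member set and its disease-gene-restricted subset."""

    pathway_id: str
    restricted: frozenset[int]
    full_members: frozenset[int]

    def __post_init__(self) -> None:
        if not self.restricted <= self.full_members:
            raise ValueError(
                f"restricted members of {self.pathway_id!r} exceed full membership"
            )


@dataclass(frozen=True)
class CrosstalkEdge:
    """Canonical (pathway_a < pathway_b) scored pathway pair."""

    pathway_a: str
    pathway_b: str
    jc: float
    oc: float
    weight: float
    shared_genes: frozenset[int]

    def __post_init__(self) -> None:
        if self.pathway_a >= self.pathway_b:
            raise ValueError("edge must be canonical: pathway_a < pathway_b")
        object.__setattr__(self, "shared_genes", frozenset(self.shared_genes))


@dataclass
class TripartiteNetwork:
    pathway_nodes: set[str] = field(default_factory=set)
    gene_nodes: set[int] = field(default_factory=set)
    pathway_pathway_edges: set[CrosstalkEdge] = field(default_factory=set)
    pathway_gene_edges: set[tuple[str, int]] = field(default_factory=set)

    @property
    def n_nodes(self) -> int:
        return len(self.pathway_nodes) + len(self.gene_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.pathway_pathway_edges) + len(self.pathway_gene_edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TripartiteNetwork):
            return NotImplemented
        return (
            self.pathway_nodes == other.pathway_nodes
            and self.gene_nodes == other.gene_nodes
            and self.pathway_pathway_edges == other.pathway_pathway_edges
            and self.pathway_gene_edges == other.pathway_gene_edges
        )


def restrict_memberships(
    collection: PathwayCollection, disease_genes: GeneSet | Iterable[int]
) -> list[PathwayMembership]:
    """Intersect every pathway's membership with the disease gene set.

    Pathways with an empty restricted membership are carried along (with
    an empty set) so the caller decides whether to drop them.
    """
    ids = (
        disease_genes.gene_ids
        if isinstance(disease_genes, GeneSet)
        else frozenset(disease_genes)
    )
    return [
        PathwayMembership(p.pathway_id, p.members & ids, p.members)
        for p in collection.pathways
    ]


def build_crosstalk_network(
    memberships: Sequence[PathwayMembership],
    min_genes: int = 3,
    min_shared: int = 2,
    use_full_members: bool = False,
) -> set[CrosstalkEdge]:
    """Score every qualifying unordered pathway pair.

    A pair becomes an edge when both pathways hold at least ``min_genes``
    considered genes and share at least ``min_shared`` of them.  With
    ``use_full_members`` the coefficients are computed on full pathway
    memberships instead of the disease-restricted ones.
    """
    if min_genes < 1 or min_shared < 1:
        raise ValueError("min_genes and min_shared must be >= 1")
    sets = {
        m.pathway_id: (m.full_members if use_full_members else m.restricted)
        for m in memberships
    }
    eligible = sorted(pid for pid, s in sets.items() if len(s) >= min_genes)
    edges: set[CrosstalkEdge] = set()
    for i, pa in enumerate(eligible):
        for pb in eligible[i + 1 :]:
            shared = sets[pa] & sets[pb]
            if len(shared) < min_shared:
                continue
            jc = jaccard(sets[pa], sets[pb])
            oc = overlap_coefficient(sets[pa], sets[pb])
            edges.add(
                CrosstalkEdge(pa, pb, jc=jc, oc=oc, weight=(jc + oc) / 2.0, shared_genes=shared)
            )
    return edges


def build_tripartite(
    edges: Iterable[CrosstalkEdge],
    memberships: Sequence[PathwayMembership],
    genes: GeneSet | Iterable[int],
) -> TripartiteNetwork:
    """Attach gene nodes to the pathways retained in the cross-talk network.

    A gene from ``genes`` is linked to every retained pathway whose
    considered (restricted) membership contains it; genes hitting no
    retained pathway are omitted.
    """
    gene_ids = genes.gene_ids if isinstance(genes, GeneSet) else frozenset(genes)
    pp_edges = set(edges)
    retained = {e.pathway_a for e in pp_edges} | {e.pathway_b for e in pp_edges}
    pg_edges: set[tuple[str, int]] = set()
    for m in memberships:
        if m.pathway_id not in retained:
            continue
        for g in m.restricted & gene_ids:
            pg_edges.add((m.pathway_id, g))
    return TripartiteNetwork(
        pathway_nodes=retained,
        gene_nodes={g for _, g in pg_edges},
        pathway_pathway_edges=pp_edges,
        pathway_gene_edges=pg_edges,
    )


def _to_networkx(net: TripartiteNetwork, node_classes: Mapping | None) -> nx.Graph:
    graph = nx.Graph()
    classes = node_classes or {}
    for p in sorted(net.pathway_nodes):
        graph.add_node(p, kind="pathway", node_class=str(classes.get(p, "pathway")))
    for g in sorted(net.gene_nodes):
        graph.add_node(f"gene:{g}", kind="gene", gene_id=int(g),
                       node_class=str(classes.get(g, "gene")))
    for e in sorted(net.pathway_pathway_edges, key=lambda e: (e.pathway_a, e.pathway_b)):
        graph.add_edge(
            e.pathway_a,
            e.pathway_b,
            kind="pathway-pathway",
            jc=e.jc,
            oc=e.oc,
            weight=e.weight,
            n_shared=len(e.shared_genes),
            shared_genes=",".join(str(g) for g in sorted(e.shared_genes)),
        )
    for p, g in sorted(net.pathway_gene_edges):
        graph.add_edge(p, f"gene:{g}", kind="pathway-gene")
    return graph


def export_network(
    net: TripartiteNetwork,
    path: str | Path,
    format: str = "graphml",
    node_classes: Mapping | None = None,
) -> None:
    """Write the tripartite network as GraphML, SIF, or a TSV edge table.

    GraphML keeps all node/edge attributes and round-trips through
    :func:`read_network`; SIF and TSV are Cytoscape-friendly flat exports.
    ``node_classes`` may map pathway ids / gene ids to provenance labels
    (e.g. disease-specific vs shared).
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_to_networkx(net, node_classes), path)
    elif format == "sif":
        with open(path, "w") as fh:
            for e in sorted(net.pathway_pathway_edges, key=lambda e: (e.pathway_a, e.pathway_b)):
                fh.write(f"{e.pathway_a}\tpp\t{e.pathway_b}\n")
            for p, g in sorted(net.pathway_gene_edges):
                fh.write(f"{p}\tpg\tgene:{g}\n")
    elif format == "tsv":
        rows = [
            {
                "kind": "pathway-pathway",
                "source": e.pathway_a,
                "target": e.pathway_b,
                "jc": e.jc,
                "oc": e.oc,
                "weight": e.weight,
                "n_shared_genes": len(e.shared_genes),
                "shared_genes": ",".join(str(g) for g in sorted(e.shared_genes)),
            }
            for e in sorted(net.pathway_pathway_edges, key=lambda e: (e.pathway_a, e.pathway_b))
        ] + [
            {
                "kind": "pathway-gene",
                "source": p,
                "target": str(g),
                "jc": "",
                "oc": "",
                "weight": "",
                "n_shared_genes": "",
                "shared_genes": "",
            }
            for p, g in sorted(net.pathway_gene_edges)
        ]
        pd.DataFrame(
            rows,
            columns=["kind", "source", "target", "jc", "oc", "weight",
                     "n_shared_genes", "shared_genes"],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise UnknownFormatError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> TripartiteNetwork:
    """Reconstruct a :class:`TripartiteNetwork` from a GraphML export."""
    if format != "graphml":
        raise UnknownFormatError("only GraphML files carry enough attributes to re-read")
    graph = nx.read_graphml(Path(path))
    net = TripartiteNetwork()
    for node, data in graph.nodes(data=True):
        if data.get("kind") == "gene":
            net.gene_nodes.add(int(data["gene_id"]))
        else:
            net.pathway_nodes.add(str(node))
    for u, v, data in graph.edges(data=True):
        if data.get("kind") == "pathway-pathway":
            a, b = sorted((str(u), str(v)))
            shared = frozenset(
                int(g) for g in str(data.get("shared_genes", "")).split(",") if g
            )
            net.pathway_pathway_edges.add(
                CrosstalkEdge(a, b, jc=float(data["jc"]), oc=float(data["oc"]),
                              weight=float(data["weight"]), shared_genes=shared)
            )
        else:
            p, g = (u, v) if str(v).startswith("gene:") else (v, u)
            net.pathway_gene_edges.add((str(p), int(graph.nodes[g]["gene_id"])))
    return net


def edges_to_frame(edges: Iterable[CrosstalkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_a": e.pathway_a,
                "pathway_b": e.pathway_b,
                "jc": e.jc,
                "oc": e.oc,
                "weight": e.weight,
                "n_shared_genes": len(e.shared_genes),
            }
            for e in sorted(edges, key=lambda e: (e.pathway_a, e.pathway_b))
        ],
        columns=["pathway_a", "pathway_b", "jc", "oc", "weight", "n_shared_genes"],
    )
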