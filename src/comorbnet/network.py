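"""Interactome handling and guilt-by-association candidate prediction.

A protein–protein interaction network (PPIN) is modelled as an undirected
simple graph over Entrez gene identifiers: self-interactions and
duplicate pairs are removed on construction, and promiscuous ubiquitin
genes (UBC, UBB, UBD) are excluded by default because ubiquitin binds
non-specifically to proteins marked for degradation.

Disease-specific networks are extracted with the edge-incident ("star
expansion") rule: every interaction touching at least one seed gene is
kept.  The edge-set intersection of two disease networks is the overlap
network; for any of its nodes that belongs to neither seed set, every
incident overlap edge must lead to a gene in both seed sets, so the
node's overlap degree equals its number of shared-gene neighbors.  Genes
that are not known disease genes but neighbor many shared genes are
ranked as novel comorbidity candidates (guilt by association).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .genesets import GeneSet

logger = logging.getLogger(__name__)

#: Default exclusion: UBC (7316), UBB (7314), UBD (10537).
UBIQUITIN_GENES: frozenset[int] = frozenset({7316, 7314, 10537})

Edge = tuple[int, int]


class EdgeListError(Exception):
    """Malformed interactome edge list."""


class CandidateNotInNetworkError(Exception):
    """A requested candidate gene is absent from the network."""


def _canonical(u: int, v: int) -> Edge:
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class Interactome:
    """Undirected simple graph: canonical unordered edges, no self-loops.

    Node set is derived from edge endpoints; isolated nodes are never
    retained.
    """

    edges: frozenset[Edge] = frozenset()

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u}")
            if u > v:
                raise ValueError(f"edge ({u}, {v}) is not canonical")

    @classmethod
    def from_edges(cls, pairs: Iterable[tuple[int, int]]) -> "Interactome":
        """Build from raw pairs, silently canonicalizing, dropping
        self-pairs and duplicates (counts are logged)."""
        clean: set[Edge] = set()
        n_self = n_raw = 0
        for u, v in pairs:
            n_raw += 1
            if u == v:
                n_self += 1
                continue
            clean.add(_canonical(int(u), int(v)))
        n_dup = n_raw - n_self - len(clean)
        if n_self or n_dup:
            logger.info("dropped %d self-pairs and %d duplicate pairs", n_self, n_dup)
        return cls(frozenset(clean))

    @property
    def nodes(self) -> frozenset[int]:
        out: set[int] = set()
        for u, v in self.edges:
            out.add(u)
            out.add(v)
        return frozenset(out)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {}
        for u, v in self.edges:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        return adj

    def degree(self) -> dict[int, int]:
        return {node: len(nbrs) for node, nbrs in self.adjacency().items()}

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph()
        graph.add_edges_from(self.edges)
        return graph


@dataclass(frozen=True)
class DiseaseNetwork:
    """Interactome subnetwork anchored on a disease seed gene set."""

    seed_genes: GeneSet
    network: Interactome
    extraction_rule: str = "edge_incident"


def read_edge_list(path: str | Path) -> Interactome:
    """Read a two-column TSV of gene-id pairs; a header row is auto-detected.

    The result is canonicalized and deduplicated with self-pairs dropped.
    An empty file yields an empty interactome.
    """
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise EdgeListError(f"cannot read edge list {path}: {exc}") from exc
    pairs: list[tuple[int, int]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise EdgeListError(f"{path}:{lineno}: fewer than two columns")
        a, b = fields[0].strip(), fields[1].strip()
        try:
            pairs.append((int(a), int(b)))
        except ValueError as exc:
            if lineno == 1:  # header row
                continue
            raise EdgeListError(f"{path}:{lineno}: non-integer gene ID") from exc
    return Interactome.from_edges(pairs)


def write_edge_list(net: Interactome, path: str | Path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("gene_a\tgene_b\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def merge_interactomes(
    nets: Sequence[Interactome], exclude: Iterable[int] = UBIQUITIN_GENES
) -> Interactome:
    """Union of edge sets with the exclusion list applied.

    Every edge touching an excluded gene (default: the ubiquitin genes)
    is removed.
    """
    excluded = frozenset(exclude)
    merged: set[Edge] = set()
    for net in nets:
        merged |= net.edges
    kept = {e for e in merged if e[0] not in excluded and e[1] not in excluded}
    if len(kept) != len(merged):
        logger.info("exclusion list removed %d edges", len(merged) - len(kept))
    return Interactome(frozenset(kept))


def extract_disease_network(
    net: Interactome, seeds: GeneSet, rule: str = "edge_incident"
) -> DiseaseNetwork:
    """Extract the disease-specific subnetwork for a seed gene set.

    ``edge_incident`` (default) keeps every interactome edge with at
    least one endpoint among the seeds; ``induced`` keeps only edges with
    both endpoints among the seeds.  Seeds without any incident edge
    simply contribute nothing (an all-absent seed set yields an empty
    network, logged).
    """
    if len(seeds) == 0:
        raise ValueError("seed gene set is empty")
    seed_ids = seeds.gene_ids
    if rule == "edge_incident":
        kept = {e for e in net.edges if e[0] in seed_ids or e[1] in seed_ids}
    elif rule == "induced":
        kept = {e for e in net.edges if e[0] in seed_ids and e[1] in seed_ids}
    else:
        raise ValueError(f"unknown extraction rule {rule!r}")
    if not kept:
        logger.warning("no seed gene of %r has an edge in the interactome",
                       seeds.disease_label)
    return DiseaseNetwork(seeds, Interactome(frozenset(kept)), extraction_rule=rule)


def union_networks(a: DiseaseNetwork, b: DiseaseNetwork) -> Interactome:
    """Edge-set union of two disease networks (the combined disease network)."""
    return Interactome(a.network.edges | b.network.edges)


def intersect_networks(a: DiseaseNetwork, b: DiseaseNetwork) -> Interactome:
    """Edge-set intersection (the overlap network).

    Nodes are the endpoints of the common edges — NOT the intersection of
    the two node sets, which would be larger.
    """
    return Interactome(a.network.edges & b.network.edges)


def shared_gene_neighbor_count(
    overlap: Interactome, shared: GeneSet | Iterable[int]
) -> dict[int, int]:
    """Per node, the number of distinct neighbors that are shared genes.

    Every node of the overlap network is scored, shared genes included;
    nodes without shared-gene neighbors score 0.
    """
    shared_ids = shared.gene_ids if isinstance(shared, GeneSet) else frozenset(shared)
    return {
        node: len(nbrs & shared_ids) for node, nbrs in overlap.adjacency().items()
    }


@dataclass(frozen=True)
class CandidateEntry:
    gene_id: int
    shared_neighbor_count: int
    is_known_disease_gene: bool


@dataclass
class CandidateRanking:
    """Genes ranked by shared-gene neighbor count.

    ``entries`` holds every gene reaching the threshold (known disease
    genes flagged); ``novel`` is the guilt-by-association call set:
    non-disease genes with at least ``threshold`` shared-gene neighbors.
    """

    entries: list[CandidateEntry] = field(default_factory=list)
    threshold: int = 6

    @property
    def novel(self) -> list[CandidateEntry]:
        return [
            e
            for e in self.entries
            if not e.is_known_disease_gene and e.shared_neighbor_count >= self.threshold
        ]

    @property
    def novel_gene_ids(self) -> list[int]:
        return [e.gene_id for e in self.novel]

    def __len__(self) -> int:
        return len(self.novel)


def predict_candidates(
    counts: Mapping[int, int],
    known: GeneSet | Iterable[int],
    min_count: int = 6,
) -> CandidateRanking:
    """Rank novel candidates: count >= min_count and not a known disease gene.

    The conventional "node degree > 5.0" call corresponds to the default
    integer threshold of 6.  Ordering is count descending, gene_id
    ascending on ties, so the ranking is fully deterministic.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    known_ids = known.gene_ids if isinstance(known, GeneSet) else frozenset(known)
    entries = [
        CandidateEntry(g, c, g in known_ids)
        for g, c in counts.items()
        if c >= min_count
    ]
    entries.sort(key=lambda e: (-e.shared_neighbor_count, e.gene_id))
    return CandidateRanking(entries=entries, threshold=min_count)


def ranking_to_frame(
    ranking: CandidateRanking,
    disease_degree: Mapping[int, int] | None = None,
    symbols: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Candidate table with the union-disease-network degree as a secondary
    column when available."""
    degrees = disease_degree or {}
    syms = symbols or {}
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "symbol": syms.get(e.gene_id, ""),
                "shared_neighbor_count": e.shared_neighbor_count,
                "disease_net_degree": degrees.get(e.gene_id, ""),
                "is_novel": not e.is_known_disease_gene,
            }
            for e in ranking.entries
        ],
        columns=["gene_id", "symbol", "shared_neighbor_count",
                 "disease_net_degree", "is_novel"],
    )


@dataclass
class AnnotatedSubnetwork:
    """Candidate-incident subnetwork with node class labels (Fig-4 style)."""

    network: Interactome
    node_classes: dict[int, str] = field(default_factory=dict)


def extract_candidate_neighborhood(
    disease_net: Interactome,
    candidates: Iterable[int],
    annot: Mapping[str, Iterable[int]] | None = None,
) -> AnnotatedSubnetwork:
    """Subnetwork of edges incident to at least one candidate gene.

    ``annot`` maps class labels (e.g. ``"a"``, ``"b"``, ``"shared"``) to
    gene-id sets; candidates are always labelled ``"candidate"`` and
    unlabelled neighbors ``"other"``.  A candidate with no edge in the
    network raises :class:`CandidateNotInNetworkError`.
    """
    cand = frozenset(candidates)
    missing = cand - disease_net.nodes
    if missing:
        raise CandidateNotInNetworkError(
            f"candidates absent from network: {sorted(missing)}"
        )
    kept = {e for e in disease_net.edges if e[0] in cand or e[1] in cand}
    sub = Interactome(frozenset(kept))
    classes: dict[int, str] = {}
    label_sets = {label: frozenset(ids) for label, ids in (annot or {}).items()}
    for node in sub.nodes:
        if node in cand:
            classes[node] = "candidate"
            continue
        for label, ids in sorted(label_sets.items()):
            if node in ids:
                classes[node] = label
                break
        else:
            classes[node] = "other"
    return AnnotatedSubnetwork(network=sub, node_classes=classes)


def export_interactome_graphml(
    net: Interactome,
    path: str | Path,
    node_classes: Mapping[int, str] | None = None,
) -> None:
    graph = net.to_networkx()
    for node, label in (node_classes or {}).items():
        if node in graph:
            graph.nodes[node]["node_class"] = label
    nx.write_graphml(graph, Path(path))
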